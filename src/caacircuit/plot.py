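"""Optional plotting helpers (thin layer; nothing here affects analysis)."""

from __future__ import annotations

import numpy as np

#: quadrant colors: A-exclusive green, B-exclusive red, double-high yellow,
#: double-low gray
QUADRANT_COLORS = {
    "A_exclusive": "#2ca02c",
    "B_exclusive": "#d62728",
    "double_high": "#e6c700",
    "double_low": "#bbbbbb",
}


def sweep_pies(summaries, ax_size: float = 1.2):
    """Grid of pie charts, one per copy-number combination."""
    import matplotlib.pyplot as plt

    cas = sorted({s.copies_A for s in summaries})
    cbs = sorted({s.copies_B for s in summaries})
    fig, axes = plt.subplots(
        len(cbs), len(cas), figsize=(ax_size * len(cas), ax_size * len(cbs)), squeeze=False
    )
    for s in summaries:
        ax = axes[len(cbs) - 1 - cbs.index(s.copies_B)][cas.index(s.copies_A)]
        fracs = [s.fractions[q] for q in QUADRANT_COLORS]
        ax.pie(fracs, colors=list(QUADRANT_COLORS.values()))
        ax.set_title(f"({s.copies_A},{s.copies_B})", fontsize=7)
    return fig


def profile_density(binned, ax=None, cmap: str = "viridis"):
    """Log-density heat map of one binned profile (GFP x, mCherry y)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(3, 3))
    with np.errstate(divide="ignore"):
        img = np.log10(np.where(binned.grid > 0, binned.grid, np.nan))
    ax.imshow(img.T, origin="lower", cmap=cmap, aspect="equal")
    ax.set_xlabel("GFP bin")
    ax.set_ylabel("mCherry bin")
    return ax
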