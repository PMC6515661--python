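"""Gene-dosage sweeps: endpoint ensembles over a (copies_A, copies_B) grid.

Endpoints are classified into the four expression quadrants — A-exclusive,
B-exclusive, double-high, double-low — against protein thresholds derived
from the mean-field fixed points, and summarized as per-cell quadrant
fractions. This is the computational dosage-to-exclusivity experiment: at
low copy number a side whose few promoters are all repressor-bound is
silenced outright, while many promoter copies average over binding
fluctuations and let both sides stay high.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circuit import CircuitParameters, build_network
from .engine import SimulationError, SystemState, endpoint_ensemble
from .meanfield import find_fixed_points

__all__ = [
    "QUADRANTS",
    "Thresholds",
    "QuadrantSummary",
    "classify_endpoint",
    "default_thresholds",
    "sweep",
    "DEFAULT_GRID",
]

QUADRANTS = ("A_exclusive", "B_exclusive", "double_high", "double_low")

#: default sweep grid: all copy-number combinations from 1 to 5 per side
DEFAULT_GRID = tuple((a, b) for a in range(1, 6) for b in range(1, 6))

PROTEIN_A_INDEX = 4
PROTEIN_B_INDEX = 9


@dataclass(frozen=True)
class Thresholds:
    """Protein-count cutoffs separating 'high' from 'low' per channel."""

    theta_A: float
    theta_B: float

    def __post_init__(self):
        if self.theta_A <= 0 or self.theta_B <= 0:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class QuadrantSummary:
    """Quadrant occupancy of one endpoint ensemble at one copy-number cell."""

    copies_A: int
    copies_B: int
    n_runs: int
    fractions: dict

    def __post_init__(self):
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"fractions sum to {total}, expected 1")
        for q, f in self.fractions.items():
            if f < 0:
                raise ValueError(f"negative fraction for {q}")
            if abs(f * self.n_runs - round(f * self.n_runs)) > 1e-6:
                raise ValueError(f"fraction {f} is not integral at n_runs={self.n_runs}")

    def __getitem__(self, quadrant: str) -> float:
        return self.fractions[quadrant]


def classify_endpoint(
    state: SystemState,
    thresholds: Thresholds,
    protein_indices: tuple = (PROTEIN_A_INDEX, PROTEIN_B_INDEX),
) -> str:
    """Quadrant label of one endpoint; exact threshold equality counts as high."""
    p_a = state.counts[protein_indices[0]]
    p_b = state.counts[protein_indices[1]]
    hi_a = p_a >= thresholds.theta_A
    hi_b = p_b >= thresholds.theta_B
    if hi_a and hi_b:
        return "double_high"
    if hi_a:
        return "A_exclusive"
    if hi_b:
        return "B_exclusive"
    return "double_low"


def default_thresholds(params: CircuitParameters, n_starts: int = 50, seed: int = 0) -> Thresholds:
    """Self-calibrating cutoffs from the mean-field stable states.

    Multistable parameters: theta per channel is the geometric mean of the
    highest and lowest stable fixed-point protein levels on that channel.
    Monostable parameters fall back to ten times the basal protein level,
    alpha_basal*beta/(delta_m*delta_p) * 10.
    """
    stable = [fp for fp in find_fixed_points(params, n_starts=n_starts, seed=seed) if fp.stable]
    if len(stable) >= 2:
        pa = np.array([fp.protein_A for fp in stable])
        pb = np.array([fp.protein_B for fp in stable])
        lo_a, hi_a = max(pa.min(), 1e-3), pa.max()
        lo_b, hi_b = max(pb.min(), 1e-3), pb.max()
        return Thresholds(float(np.sqrt(lo_a * hi_a)), float(np.sqrt(lo_b * hi_b)))
    if params.delta_m == 0 or params.delta_p == 0:
        raise ValueError("fallback threshold undefined for zero degradation rates")
    theta = params.alpha_basal * params.beta / (params.delta_m * params.delta_p) * 10.0
    return Thresholds(theta, theta)


def summarize_endpoints(
    endpoints: list[SystemState],
    thresholds: Thresholds,
    copies_A: int,
    copies_B: int,
) -> QuadrantSummary:
    counts = dict.fromkeys(QUADRANTS, 0)
    for st in endpoints:
        counts[classify_endpoint(st, thresholds)] += 1
    n = len(endpoints)
    return QuadrantSummary(copies_A, copies_B, n, {q: counts[q] / n for q in QUADRANTS})


def sweep(
    params: CircuitParameters,
    copy_grid=DEFAULT_GRID,
    n_runs: int = 1000,
    t_end: float = 16.0,
    base_seed: int = 0,
    thresholds: Thresholds | None = None,
) -> list[QuadrantSummary]:
    """One endpoint ensemble per copy-number cell, classified into quadrants.

    Thresholds default to ``default_thresholds`` of the base parameter set
    (its own copy numbers, typically (1, 1)) and are shared by every grid
    cell so the quadrant definition is common across the sweep. Pass an
    explicit ``thresholds`` to compare sweeps across parameter sets (e.g.
    weak vs strong repression) on one quadrant definition.

    Runs are seeded cell-by-cell as base_seed + cell_index*n_runs + run, so
    the whole sweep is reproducible and cells are independent.
    """
    if n_runs < 100:
        raise ValueError(f"n_runs must be >= 100 for stable fractions, got {n_runs}")
    if thresholds is None:
        thresholds = default_thresholds(params)
    out = []
    for cell_index, (ca, cb) in enumerate(copy_grid):
        cell = params.with_copies(int(ca), int(cb))
        network = build_network(cell)
        try:
            endpoints = endpoint_ensemble(
                network,
                t_end=t_end,
                n_runs=n_runs,
                base_seed=base_seed + cell_index * n_runs,
            )
        except SimulationError as err:
            raise SimulationError(f"grid cell ({ca}, {cb}): {err}") from err
        out.append(summarize_endpoints(endpoints, thresholds, int(ca), int(cb)))
    return out
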