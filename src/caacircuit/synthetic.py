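"""Synthetic data generators for every pipeline input.

The experimental raw data (per-clone flow event tables, dPCR partition
counts) are not deposited anywhere, so the analysis modules are exercised on
synthetic datasets that reproduce their assumed statistical structure:

* clonal flow profiles are mixtures of up to four log-normal populations at
  the canonical quadrant positions in (GFP, mCherry) space — (low, low),
  (high, low), (low, high), (high, high);
* archetype-labelled clone sets pair each clone with the presence/absence
  pattern that generated it, for clustering-recovery benchmarks;
* dPCR partition counts are binomial draws at a known true copy number.

Every generator is deterministic given its seed and emits objects in
exactly the form the pipeline consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dpcr import DigitalPCRMeasurement
from .flow import ResponseProfile

__all__ = [
    "PopulationSpec",
    "CloneSpec",
    "QUADRANT_CENTERS",
    "canonical_patterns",
    "generate_clone_profile",
    "generate_archetype_dataset",
    "generate_dpcr_partitions",
]

#: canonical population centers in log10 fluorescence (gfp, mcherry):
#: low ~ 10^2 a.u., high ~ 10^4 a.u.
QUADRANT_CENTERS = {
    "double_low": (2.0, 2.0),
    "gfp_high": (4.0, 2.0),
    "mcherry_high": (2.0, 4.0),
    "double_high": (4.0, 4.0),
}

#: default within-population spread, log10 units
DEFAULT_SPREAD = 0.15


@dataclass(frozen=True)
class PopulationSpec:
    """One discrete population: log-space center, spread and mixture weight."""

    center: tuple  # (log10 gfp, log10 mcherry)
    spread: tuple = (DEFAULT_SPREAD, DEFAULT_SPREAD)
    weight: float = 1.0

    def __post_init__(self):
        if len(self.center) != 2 or len(self.spread) != 2:
            raise ValueError("center and spread must be 2-vectors (gfp, mcherry)")
        if any(s <= 0 for s in self.spread):
            raise ValueError("spreads must be positive")
        if self.weight < 0:
            raise ValueError("weight must be nonnegative")


@dataclass(frozen=True)
class CloneSpec:
    """Mixture description of one clone's response profile."""

    clone_id: str
    populations: tuple
    n_events: int = 20_000
    seed: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 1 <= len(self.populations) <= 4:
            raise ValueError("a clone carries 1-4 populations")
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        total = sum(p.weight for p in self.populations)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"population weights sum to {total}, expected 1")


def generate_clone_profile(spec: CloneSpec) -> ResponseProfile:
    """Draw a clone's event table: weighted population choice per event, then
    a bivariate log-normal (diagonal covariance) fluorescence draw."""
    rng = np.random.default_rng(spec.seed)
    weights = np.array([p.weight for p in spec.populations])
    choice = rng.choice(len(spec.populations), size=spec.n_events, p=weights)
    centers = np.array([p.center for p in spec.populations])
    spreads = np.array([p.spread for p in spec.populations])
    logs = rng.normal(centers[choice], spreads[choice])
    return ResponseProfile(spec.clone_id, 10.0**logs, dict(spec.metadata))


def canonical_patterns(k: int) -> list:
    """The first k non-empty presence/absence patterns over the four canonical
    populations, ordered by population count then by bit pattern (single-
    population archetypes first — the four 'decided' corners)."""
    names = list(QUADRANT_CENTERS)
    patterns = []
    for size in range(1, 5):
        for bits in range(16):
            if bin(bits).count("1") == size:
                patterns.append(tuple(names[i] for i in range(4) if bits >> i & 1))
    if not 1 <= k <= len(patterns):
        raise ValueError(f"k must lie in 1..{len(patterns)}, got {k}")
    return patterns[:k]


def generate_archetype_dataset(
    k_archetypes: int = 4,
    clones_per_archetype: int = 25,
    n_events: int = 20_000,
    jitter: float = 0.0,
    seed: int = 0,
    spread: float = DEFAULT_SPREAD,
):
    """Clone profiles drawn from k well-separated archetypes, with truth labels.

    Each archetype is a presence/absence pattern over the canonical quadrant
    populations (equal weights over present populations). Per-clone
    population centers are jittered by a normal offset of sd ``jitter``
    (log10 units), emulating clone-to-clone variation in state placement.

    Returns (profiles, labels, archetype_patterns): labels[i] is the index
    of the archetype that generated profiles[i].
    """
    if k_archetypes < 2:
        raise ValueError("k_archetypes must be >= 2")
    if clones_per_archetype < 1:
        raise ValueError("clones_per_archetype must be >= 1")
    rng = np.random.default_rng(seed)
    # 15 non-empty presence patterns; beyond that, archetypes reuse the
    # multi-population patterns with skewed population weights (0.7 on a
    # rotating dominant population), which keeps layouts distinguishable
    base = canonical_patterns(min(k_archetypes, 15))
    multi = [p for p in canonical_patterns(15) if len(p) > 1]
    specs = [(p, None) for p in base]
    extra = 0
    while len(specs) < k_archetypes:
        pattern = multi[extra % len(multi)]
        dominant = (extra // len(multi)) % len(pattern)
        if extra // len(multi) >= len(pattern):
            raise ValueError(f"cannot construct {k_archetypes} distinct archetypes")
        w = np.full(len(pattern), 0.3 / (len(pattern) - 1))
        w[dominant] = 0.7
        specs.append((pattern, tuple(w)))
        extra += 1
    profiles, labels = [], []
    for a, (pattern, weights) in enumerate(specs):
        if weights is None:
            weights = tuple(1.0 / len(pattern) for _ in pattern)
        for c in range(clones_per_archetype):
            pops = []
            for name, w in zip(pattern, weights):
                cx, cy = QUADRANT_CENTERS[name]
                dx, dy = (rng.normal(0.0, jitter, size=2) if jitter > 0 else (0.0, 0.0))
                pops.append(
                    PopulationSpec((cx + dx, cy + dy), (spread, spread), float(w))
                )
            clone_seed = int(rng.integers(0, 2**31 - 1))
            spec = CloneSpec(
                clone_id=f"arch{a:02d}_clone{c:02d}",
                populations=tuple(pops),
                n_events=n_events,
                seed=clone_seed,
                metadata={"archetype": a, "pattern": "+".join(pattern)},
            )
            profiles.append(generate_clone_profile(spec))
            labels.append(a)
    return profiles, np.array(labels), [p for p, _ in specs]


def generate_dpcr_partitions(
    true_copies: float,
    lambda_ref: float = 0.3,
    total_partitions: int = 20_000,
    seed: int = 0,
    target: str = "GFP",
):
    """Simulated (target, reference) partition counts at a known copy number.

    Reference positives ~ Binomial(total, 1 - exp(-lambda_ref)); the target
    is loaded at lambda = true_copies * lambda_ref. Returns the pair
    (target measurement, ALG9 reference measurement).
    """
    if true_copies < 0 or lambda_ref < 0 or total_partitions < 1:
        raise ValueError("true_copies and lambda_ref must be >= 0, total >= 1")
    rng = np.random.default_rng(seed)
    p_ref = 1.0 - np.exp(-lambda_ref)
    p_t = 1.0 - np.exp(-true_copies * lambda_ref)
    ref = DigitalPCRMeasurement("ALG9", int(rng.binomial(total_partitions, p_ref)), total_partitions)
    tgt = DigitalPCRMeasurement(target, int(rng.binomial(total_partitions, p_t)), total_partitions)
    return tgt, ref
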