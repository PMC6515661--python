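"""Response-profile clustering for two-channel (GFP, mCherry) event tables.

One clone's flow-cytometry measurement is its cloud of per-cell (GFP,
mCherry) fluorescence values — its response profile. Profiles are trimmed of
outlier events, binned into an n x n grid on a shared log-fluorescence
range, compared with the Manhattan (L1) distance between grids, clustered
with PAM (k-medoids, BUILD + SWAP, hand-implemented for a deterministic tie
rule), and summarized per cluster as averaged archetype masks. Grid size n
and cluster count k are chosen by scanning silhouette scores.

Defaults mirror common flow practice where the upstream protocol is silent:
log10 transform with a floor clamp at 1 a.u., global axis ranges at the
pooled 0.1th-99.9th percentiles, outlier trim at the 0.5th/99.5th
percentiles per channel (rank-based), n = 10 for clustering and n = 100 for
density plotting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_samples

__all__ = [
    "DegenerateProfileError",
    "ResponseProfile",
    "BinnedProfile",
    "ClusteringResult",
    "ArchetypeMask",
    "trim_outliers",
    "pooled_ranges",
    "bin_profile",
    "manhattan_distance",
    "distance_matrix",
    "pam",
    "mean_silhouette",
    "silhouette_scan",
    "build_masks",
    "enumerate_presence_patterns",
    "cluster_pipeline",
]


class DegenerateProfileError(ValueError):
    pass


@dataclass(frozen=True)
class ResponseProfile:
    """Per-event two-channel fluorescence table for one clone (a.u.)."""

    clone_id: str
    events: np.ndarray  # (n_events, 2): columns gfp, mcherry
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        ev = np.asarray(self.events, dtype=float)
        if ev.ndim != 2 or ev.shape[1] != 2 or ev.shape[0] < 1:
            raise ValueError("events must be a non-empty (n, 2) array of (gfp, mcherry)")
        if not np.all(np.isfinite(ev)):
            raise ValueError("fluorescence values must be finite")
        object.__setattr__(self, "events", ev)

    @property
    def n_events(self) -> int:
        return self.events.shape[0]

    @property
    def gfp(self) -> np.ndarray:
        return self.events[:, 0]

    @property
    def mcherry(self) -> np.ndarray:
        return self.events[:, 1]


@dataclass(frozen=True)
class BinnedProfile:
    """n x n grid histogram of one profile on shared (log-)fluorescence ranges."""

    n: int
    grid: np.ndarray
    ranges: tuple  # ((gfp_lo, gfp_hi), (mch_lo, mch_hi)) in a.u.
    log_transform: bool
    normalized: bool

    def __post_init__(self):
        g = np.asarray(self.grid, dtype=float)
        if g.shape != (self.n, self.n):
            raise ValueError(f"grid shape {g.shape} does not match n={self.n}")
        if np.any(g < 0):
            raise ValueError("grid counts must be nonnegative")
        if self.normalized and abs(g.sum() - 1.0) > 1e-12:
            raise ValueError(f"normalized grid sums to {g.sum()}, expected 1")
        object.__setattr__(self, "grid", g)

    def compatible_with(self, other: "BinnedProfile") -> bool:
        return (
            self.n == other.n
            and self.log_transform == other.log_transform
            and self.normalized == other.normalized
            and np.allclose(np.asarray(self.ranges), np.asarray(other.ranges))
        )


@dataclass(frozen=True)
class ClusteringResult:
    """PAM output: medoids, assignments, cost and silhouette diagnostics."""

    k: int
    medoid_indices: tuple
    assignments: np.ndarray  # profile index -> cluster index (into medoid_indices)
    total_cost: float
    mean_silhouette: float


@dataclass(frozen=True)
class ArchetypeMask:
    """Unweighted average of the normalized binned profiles of one cluster."""

    n: int
    grid: np.ndarray
    cluster: int
    n_members: int

    def __post_init__(self):
        g = np.asarray(self.grid, dtype=float)
        if abs(g.sum() - 1.0) > 1e-12:
            raise ValueError(f"mask grid sums to {g.sum()}, expected 1")
        object.__setattr__(self, "grid", g)


# --------------------------------------------------------------------------
# event-level preprocessing


def trim_outliers(
    profile: ResponseProfile, lower_pct: float = 0.5, upper_pct: float = 99.5
) -> ResponseProfile:
    """Drop per-channel rank outliers; an event must survive both channels.

    Trimming is rank-based: on each channel the lowest floor-like
    ``n*lower_pct/100`` and highest ``n*(100-upper_pct)/100`` ranks are
    discarded (stable ranks, so ties are deterministic). Raises
    DegenerateProfileError when nothing survives.
    """
    if not 0 <= lower_pct < upper_pct <= 100:
        raise ValueError(f"need 0 <= lower < upper <= 100, got ({lower_pct}, {upper_pct})")
    ev = profile.events
    n = ev.shape[0]
    keep = np.ones(n, dtype=bool)
    lo_rank = n * lower_pct / 100.0
    hi_rank = n * upper_pct / 100.0
    for ch in (0, 1):
        ranks = np.empty(n)
        ranks[np.argsort(ev[:, ch], kind="stable")] = np.arange(n)
        keep &= (ranks >= lo_rank) & (ranks < hi_rank)
    if not keep.any():
        raise DegenerateProfileError(
            f"clone {profile.clone_id!r}: all {n} events trimmed at "
            f"({lower_pct}, {upper_pct}) percentiles"
        )
    return ResponseProfile(profile.clone_id, ev[keep], dict(profile.metadata))


def pooled_ranges(
    profiles: list, lower_pct: float = 0.1, upper_pct: float = 99.9
) -> tuple:
    """Global per-channel axis ranges from the pooled event percentiles.

    All profiles must share one grid for distances to be meaningful, so the
    ranges come from the whole dataset, not from individual clones.
    """
    pooled = np.vstack([p.events for p in profiles])
    out = []
    for ch in (0, 1):
        lo, hi = np.percentile(pooled[:, ch], [lower_pct, upper_pct])
        if not lo < hi:
            raise DegenerateProfileError("pooled events have zero spread on a channel")
        out.append((float(lo), float(hi)))
    return tuple(out)


def bin_profile(
    profile: ResponseProfile,
    n: int = 10,
    ranges: tuple | None = None,
    log_transform: bool = True,
    normalize: bool = True,
) -> BinnedProfile:
    """Equal-width n x n histogram of a profile, optionally on log10 axes.

    Bins are half-open [lo, hi) with the last bin closed; out-of-range
    events are clamped into the edge bins. Under the log transform, values
    in (0, 1] a.u. are clamped to 1 a.u. first; nonpositive values are an
    error (they have no log-fluorescence).
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    if ranges is None:
        ranges = pooled_ranges([profile])
    (g_lo, g_hi), (m_lo, m_hi) = ranges
    if not (np.isfinite([g_lo, g_hi, m_lo, m_hi]).all() and g_lo < g_hi and m_lo < m_hi):
        raise ValueError(f"ranges must be finite with min < max, got {ranges}")
    ev = profile.events
    if log_transform:
        n_bad = int(np.sum(ev <= 0))
        if n_bad:
            raise ValueError(
                f"clone {profile.clone_id!r}: {n_bad} nonpositive fluorescence "
                "value(s) cannot be log-transformed"
            )
        ev = np.log10(np.maximum(ev, 1.0))
        g_lo, g_hi = np.log10(max(g_lo, 1.0)), np.log10(max(g_hi, 1.0))
        m_lo, m_hi = np.log10(max(m_lo, 1.0)), np.log10(max(m_hi, 1.0))
        if not (g_lo < g_hi and m_lo < m_hi):
            raise ValueError("ranges collapse under the log transform")
    gi = np.floor((ev[:, 0] - g_lo) / (g_hi - g_lo) * n).astype(int).clip(0, n - 1)
    mi = np.floor((ev[:, 1] - m_lo) / (m_hi - m_lo) * n).astype(int).clip(0, n - 1)
    grid = np.zeros((n, n))
    np.add.at(grid, (gi, mi), 1.0)
    if normalize:
        grid /= grid.sum()
    return BinnedProfile(n, grid, ranges, log_transform, normalize)


# --------------------------------------------------------------------------
# distances and PAM


def manhattan_distance(p: BinnedProfile, q: BinnedProfile) -> float:
    """L1 distance between two binned profiles on the same grid."""
    if not p.compatible_with(q):
        raise ValueError("binned profiles have incompatible grids (n/ranges/normalization)")
    return float(np.abs(p.grid - q.grid).sum())


def distance_matrix(binned: list) -> np.ndarray:
    """Square symmetric Manhattan distance matrix over binned profiles."""
    flat = np.array([b.grid.ravel() for b in binned])
    for b in binned[1:]:
        if not binned[0].compatible_with(b):
            raise ValueError("binned profiles have incompatible grids")
    return np.abs(flat[:, None, :] - flat[None, :, :]).sum(axis=2)


def _validate_distance_matrix(D: np.ndarray):
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.any(D < 0) or not np.allclose(D, D.T) or np.any(np.diag(D) != 0):
        raise ValueError("distance matrix must be symmetric, nonnegative, zero-diagonal")
    return D


def pam(D: np.ndarray, k: int, seed: int = 0) -> ClusteringResult:
    """Partitioning around medoids: greedy BUILD then best-improvement SWAP.

    Fully deterministic: all ties are broken toward the lowest index, so the
    ``seed`` argument is accepted for interface symmetry but never consulted.
    Cost is the summed distance of every point to its nearest medoid.
    """
    D = _validate_distance_matrix(D)
    N = D.shape[0]
    if not 1 <= k <= N:
        raise ValueError(f"k must satisfy 1 <= k <= {N}, got {k}")

    # BUILD: start from the 1-medoid optimum, then greedily add the point
    # giving the largest cost reduction (lowest index on ties)
    medoids = [int(np.argmin(D.sum(axis=1)))]
    nearest = D[medoids[0]].copy()
    while len(medoids) < k:
        gains = np.minimum(D, nearest[None, :]).sum(axis=1)
        gains[medoids] = np.inf
        new = int(np.argmin(gains))
        medoids.append(new)
        nearest = np.minimum(nearest, D[new])

    # SWAP: apply the single most cost-reducing (medoid, candidate) swap
    # until none improves
    medoids = sorted(medoids)
    while True:
        med = np.array(medoids)
        dist_to_meds = D[:, med]
        order = np.argsort(dist_to_meds, axis=1)
        d1 = dist_to_meds[np.arange(N), order[:, 0]]
        best = (0.0, None)
        candidates = [h for h in range(N) if h not in medoids]
        for mi_pos in range(len(medoids)):
            if len(medoids) > 1:
                alt = np.min(np.delete(dist_to_meds, mi_pos, axis=1), axis=1)
            else:
                alt = np.full(N, np.inf)
            for h in candidates:
                new_nearest = np.minimum(np.minimum(alt, D[h]), np.inf)
                delta = new_nearest.sum() - d1.sum()
                if delta < best[0] - 1e-12:
                    best = (delta, (mi_pos, h))
        if best[1] is None:
            break
        mi_pos, h = best[1]
        medoids[mi_pos] = h
        medoids = sorted(medoids)

    med = np.array(sorted(medoids))
    assignments = np.argmin(D[:, med], axis=1)
    # tie rule: a medoid always belongs to its own cluster
    for ci, m in enumerate(med):
        assignments[m] = ci
    total_cost = float(D[np.arange(N), med[assignments]].sum())
    sil, _ = mean_silhouette(D, assignments)
    return ClusteringResult(int(k), tuple(int(m) for m in med), assignments, total_cost, sil)


def mean_silhouette(D: np.ndarray, labels: np.ndarray) -> tuple:
    """Mean silhouette width on a precomputed distance matrix.

    Singleton clusters score 0 (scikit-learn's convention, adopted here).
    Returns (value, degenerate): degenerate is True when all pairwise
    distances vanish (identical profiles) or k is outside 2..N-1, in which
    case the value is 0.0.
    """
    D = _validate_distance_matrix(D)
    labels = np.asarray(labels)
    n_labels = len(np.unique(labels))
    if n_labels < 2 or n_labels > D.shape[0] - 1:
        return 0.0, True
    if np.all(D == 0):
        return 0.0, True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        vals = silhouette_samples(D, labels, metric="precomputed")
    return float(np.nan_to_num(vals, nan=0.0).mean()), False


def silhouette_scan(
    profiles: list,
    n_values=(5, 10, 20),
    k_range=range(2, 21),
    ranges: tuple | None = None,
    log_transform: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean silhouette over a grid of (bins n, clusters k).

    Profiles are re-binned for every n on shared pooled ranges; each k is
    clustered with PAM. The returned frame carries the recommendation
    (argmax silhouette; ties to smaller k, then smaller n) in
    ``df.attrs['recommended']`` and a degenerate-data flag per row.
    """
    if ranges is None:
        ranges = pooled_ranges(profiles)
    N = len(profiles)
    rows = []
    for n in n_values:
        binned = [bin_profile(p, n=n, ranges=ranges, log_transform=log_transform) for p in profiles]
        D = distance_matrix(binned)
        for k in k_range:
            if not 2 <= k <= N - 1:
                raise ValueError(f"k={k} outside the silhouette-defined range 2..{N - 1}")
            result = pam(D, k, seed=seed)
            sil, degen = mean_silhouette(D, result.assignments)
            rows.append(dict(n=n, k=k, mean_silhouette=sil, degenerate=degen))
    df = pd.DataFrame(rows)
    best = df.sort_values(
        ["mean_silhouette", "k", "n"], ascending=[False, True, True], kind="stable"
    ).iloc[0]
    df.attrs["recommended"] = (int(best["n"]), int(best["k"]))
    df.attrs["degenerate"] = bool(df["degenerate"].all())
    return df


def build_masks(result: ClusteringResult, binned: list) -> list:
    """Per-cluster unweighted mean of member grids (each profile one vote).

    Requires normalized profiles so every clone carries the same weight.
    Empty clusters are skipped with a warning.
    """
    for b in binned:
        if not b.normalized:
            raise ValueError("masks require normalized binned profiles")
    masks = []
    for ci in range(result.k):
        members = [binned[i] for i in np.flatnonzero(result.assignments == ci)]
        if not members:
            warnings.warn(f"cluster {ci} is empty; no mask built", stacklevel=2)
            continue
        grid = np.mean([m.grid for m in members], axis=0)
        masks.append(ArchetypeMask(members[0].n, grid, ci, len(members)))
    return masks


def enumerate_presence_patterns(populations: int) -> int:
    """Presence/absence phase portraits over the canonical populations (2^p)."""
    if not isinstance(populations, (int, np.integer)) or populations < 0:
        raise ValueError(f"populations must be a nonnegative integer, got {populations!r}")
    return 2 ** int(populations)


def cluster_pipeline(
    profiles: list,
    n_bins: int = 10,
    k: int = 16,
    trim: tuple = (0.5, 99.5),
    range_percentiles: tuple = (0.1, 99.9),
    log_transform: bool = True,
    seed: int = 0,
):
    """Full analysis chain: trim -> shared ranges -> bin -> L1 -> PAM.

    Returns (ClusteringResult, binned profiles, distance matrix).
    """
    trimmed = [trim_outliers(p, *trim) for p in profiles]
    ranges = pooled_ranges(trimmed, *range_percentiles)
    binned = [
        bin_profile(p, n=n_bins, ranges=ranges, log_transform=log_transform) for p in trimmed
    ]
    D = distance_matrix(binned)
    return pam(D, k, seed=seed), binned, D
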