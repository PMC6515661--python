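"""Combinatorial occupancy model of an m-operator promoter.

A tetO-style promoter carries m tandem operator sites, each of which is
unbound, bound by an activator dimer, or bound by a repressor dimer — three
states per site, 3^m configurations per promoter. Sites are treated as
independent and identical (tandem 19-bp repeats, no cooperativity), so the
joint occupancy (n_act, n_rep) is multinomial in the per-site equilibrium
probabilities

    (p_U, p_A, p_R)  proportional to  (1, act_conc/K_act, rep_conc/K_rep).

The promoter's transcription rate for a configuration is supplied by an
activity function; the default family interpolates between graded repression
(each bound repressor subtracts its share of activity) and dominant
repression (any bound repressor silences) with a dominance weight s:

    activity(n_act, n_rep) = alpha_repressed * n_rep/m
        + [alpha_basal + (alpha_active - alpha_basal) * n_act/m]
          * [(1 - n_rep/m)(1 - s) + s * 1{n_rep = 0}]

At m = 1 this reduces exactly to the three aggregate promoter-state rates
for every s. The default dominance is s = 0.5: with fully dominant
repression (s = 1) a single bound repressor silences all m sites at once,
which removes the configurational averaging that many-operator promoters
are supposed to provide — see docs/methods.md for the analysis behind the
default.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Callable

import numpy as np

__all__ = [
    "OperatorOccupancy",
    "OccupancyDistribution",
    "count_site_states",
    "count_configurations",
    "occupancy_distribution",
    "expected_activity",
    "default_activity",
    "expected_activity_default",
    "activity_variance",
    "response_steepness",
]


@dataclass(frozen=True)
class OperatorOccupancy:
    """One promoter configuration class: m sites, n_act activator- and n_rep
    repressor-bound."""

    m: int
    n_act: int
    n_rep: int

    def __post_init__(self):
        if self.m < 0 or self.n_act < 0 or self.n_rep < 0:
            raise ValueError("site counts must be nonnegative")
        if self.n_act + self.n_rep > self.m:
            raise ValueError(
                f"n_act + n_rep = {self.n_act + self.n_rep} exceeds m = {self.m}"
            )

    @property
    def n_free(self) -> int:
        return self.m - self.n_act - self.n_rep

    @property
    def multiplicity(self) -> int:
        """Number of distinguishable-site configurations in this class."""
        return comb(self.m, self.n_act) * comb(self.m - self.n_act, self.n_rep)


@dataclass(frozen=True)
class OccupancyDistribution:
    """Multinomial occupancy law over (n_act, n_rep) classes for m iid sites."""

    m: int
    p_unbound: float
    p_act: float
    p_rep: float
    probabilities: dict  # (n_act, n_rep) -> probability

    def probability(self, n_act: int, n_rep: int) -> float:
        return self.probabilities.get((n_act, n_rep), 0.0)

    def expectation(self, fn: Callable[[OperatorOccupancy], float]) -> float:
        return sum(
            p * fn(OperatorOccupancy(self.m, na, nr))
            for (na, nr), p in self.probabilities.items()
        )


def count_site_states() -> int:
    """States of a single operator site: unbound, activator-bound, repressor-bound."""
    return 3


def count_configurations(m: int) -> int:
    """Distinguishable-site configurations of an m-operator promoter (3^m)."""
    if not isinstance(m, (int, np.integer)) or m < 0:
        raise ValueError(f"m must be a nonnegative integer, got {m!r}")
    return count_site_states() ** int(m)


def occupancy_distribution(
    m: int, act_conc: float, rep_conc: float, K_act: float, K_rep: float
) -> OccupancyDistribution:
    """Equilibrium occupancy of m independent identical operator sites.

    Per-site statistical weights are (1, act_conc/K_act, rep_conc/K_rep);
    zero dissociation constants with zero concentration are degenerate and
    rejected.
    """
    if m < 0:
        raise ValueError(f"m must be >= 0, got {m}")
    for name, v in (("act_conc", act_conc), ("rep_conc", rep_conc), ("K_act", K_act), ("K_rep", K_rep)):
        if v < 0 or not np.isfinite(v):
            raise ValueError(f"{name} must be finite and nonnegative, got {v}")
    w_act = act_conc / K_act if K_act > 0 else (np.inf if act_conc > 0 else 0.0)
    w_rep = rep_conc / K_rep if K_rep > 0 else (np.inf if rep_conc > 0 else 0.0)
    if not np.isfinite(w_act) or not np.isfinite(w_rep):
        raise ValueError("infinite binding weight: zero K with nonzero concentration")
    Z = 1.0 + w_act + w_rep
    if Z <= 0:
        raise ValueError("all per-site statistical weights vanish")
    pU, pA, pR = 1.0 / Z, w_act / Z, w_rep / Z
    probs = {}
    for na in range(m + 1):
        for nr in range(m - na + 1):
            nu = m - na - nr
            probs[(na, nr)] = (
                comb(m, na) * comb(m - na, nr) * pA**na * pR**nr * pU**nu
            )
    return OccupancyDistribution(m, pU, pA, pR, probs)


def default_activity(
    alpha_active: float = 60.0,
    alpha_basal: float = 6.0,
    alpha_repressed: float = 0.0,
    dominance: float = 0.5,
) -> Callable[[OperatorOccupancy], float]:
    """The winner-take-most activity family (module docstring) as a callable."""
    if not 0.0 <= dominance <= 1.0:
        raise ValueError(f"dominance must lie in [0, 1], got {dominance}")

    def fn(occ: OperatorOccupancy) -> float:
        if occ.m == 0:
            return alpha_basal
        fa = occ.n_act / occ.m
        fr = occ.n_rep / occ.m
        base = alpha_basal + (alpha_active - alpha_basal) * fa
        gate = (1.0 - fr) * (1.0 - dominance) + dominance * (1.0 if occ.n_rep == 0 else 0.0)
        return alpha_repressed * fr + base * gate

    return fn


def expected_activity(
    m: int,
    act_conc: float,
    rep_conc: float,
    K_act: float,
    K_rep: float,
    activity_fn: Callable[[OperatorOccupancy], float] | None = None,
) -> float:
    """Expectation of an activity function under the equilibrium occupancy."""
    dist = occupancy_distribution(m, act_conc, rep_conc, K_act, K_rep)
    if activity_fn is None:
        activity_fn = default_activity()
    return dist.expectation(activity_fn)


def expected_activity_default(
    m: int,
    w_act: float,
    w_rep: float,
    alpha_active: float,
    alpha_basal: float,
    alpha_repressed: float,
    dominance: float,
) -> float:
    """Closed form of E[default activity] given per-site weights w = conc/K.

    Used by the simulation kernel; agrees with the enumeration route of
    :func:`expected_activity` to rounding error.
    """
    if m == 0:
        return alpha_basal
    Z = 1.0 + w_act + w_rep
    pA, pR = w_act / Z, w_rep / Z
    d = alpha_active - alpha_basal
    graded = alpha_basal * (1.0 - pR) + d * pA * (1.0 - (m - 1) * pR / m)
    noR = (1.0 - pR) ** (m - 1)
    dominant = alpha_basal * noR * (1.0 - pR) + d * pA * noR
    return alpha_repressed * pR + (1.0 - dominance) * graded + dominance * dominant


def activity_variance(
    m: int,
    act_conc: float,
    rep_conc: float,
    K_act: float,
    K_rep: float,
    activity_fn: Callable[[OperatorOccupancy], float] | None = None,
) -> float:
    """Normalized variance (var/mean^2) of activity across configurations.

    The operational signature of the averaging effect: configurational
    activity fluctuations shrink as operator sites are added.
    """
    dist = occupancy_distribution(m, act_conc, rep_conc, K_act, K_rep)
    if activity_fn is None:
        activity_fn = default_activity()
    mean = dist.expectation(activity_fn)
    second = dist.expectation(lambda occ: activity_fn(occ) ** 2)
    if mean == 0:
        raise ValueError("mean activity is zero; normalized variance undefined")
    return (second - mean**2) / mean**2


def response_steepness(
    m: int,
    K_act: float = 1.0,
    K_rep: float = 1.0,
    activity_fn: Callable[[OperatorOccupancy], float] | None = None,
    act_occupancy: float = 1.0,
    log_ratio_range: tuple = (-8.0, 8.0),
    n_grid: int = 401,
) -> float:
    """Maximum slope of expected activity against the log concentration ratio.

    The scan fixes the activator at its binding scale (act_conc =
    act_occupancy * K_act) and sweeps the repressor so that
    x = log(act_conc/rep_conc) covers ``log_ratio_range`` — the
    repressor-competition dose-response a circuit side experiences while its
    own activator holds the promoter. Switch-like promoters give a large
    maximum slope, graded ones a small one.
    """
    xs = np.linspace(*log_ratio_range, n_grid)
    act = act_occupancy * K_act
    E = np.array(
        [
            expected_activity(m, act, act * np.exp(-x), K_act, K_rep, activity_fn)
            for x in xs
        ]
    )
    return float(np.max(np.abs(np.gradient(E, xs))))
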