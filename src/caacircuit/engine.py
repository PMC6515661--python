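"""Exact stochastic simulation (Gillespie direct method) of a ReactionNetwork.

The direct method is used without approximation: state spaces here are tiny
(ten species or fewer) and exactness keeps every analytic oracle applicable.
Per-run seeds in ensembles are ``base_seed + i`` so each run is individually
reproducible; the generator is the Mersenne Twister (numba ``np.random``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .circuit import ReactionNetwork

__all__ = ["SimulationError", "SystemState", "Trajectory", "simulate", "endpoint_ensemble"]

#: hard cap on events per run; generously above anything the defaults reach
MAX_EVENTS = 50_000_000


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SystemState:
    """Integer molecule counts aligned to a network's species order, at a time."""

    counts: np.ndarray
    time: float

    def __post_init__(self):
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=np.int64))
        if np.any(self.counts < 0):
            raise ValueError("molecule counts must be nonnegative")
        if self.time < 0:
            raise ValueError("time must be nonnegative")

    def __getitem__(self, k: int) -> int:
        return int(self.counts[k])


@dataclass(frozen=True)
class Trajectory:
    """Event times and states of one SSA run; final state reported at t_end."""

    times: np.ndarray
    states: np.ndarray  # (n_events + 1, n_species); row 0 is the initial state
    rng_seed: int
    t_end: float
    species: tuple

    @property
    def final(self) -> SystemState:
        return SystemState(self.states[-1], self.t_end)

    def state_at(self, t: float) -> SystemState:
        """Piecewise-constant interpolation (last event carried forward)."""
        if t < 0 or t > self.t_end:
            raise ValueError(f"t={t} outside [0, {self.t_end}]")
        k = int(np.searchsorted(self.times, t, side="right")) - 1
        return SystemState(self.states[k], t)

    def time_average(self, species_index: int) -> float:
        """Time-weighted mean count of one species over [0, t_end]."""
        edges = np.append(self.times, self.t_end)
        dt = np.diff(edges)
        return float(np.sum(self.states[:, species_index] * dt) / self.t_end)


def _check_seed(seed: int) -> int:
    seed = int(seed)
    if not 0 <= seed < 2**32:
        raise ValueError(f"seed must lie in [0, 2^32), got {seed}")
    return seed


def _check_initial(network: ReactionNetwork, initial: SystemState) -> np.ndarray:
    x0 = np.asarray(initial.counts, dtype=np.int64)
    if x0.shape != (network.n_species,):
        raise ValueError(
            f"initial state has {x0.shape[0]} species, network expects {network.n_species}"
        )
    if not network.check_conservation(x0):
        raise ValueError("initial state violates promoter-copy conservation or nonnegativity")
    return x0


def _raise_on_status(network, status, info):
    if status == 1:
        raise SimulationError(
            f"non-finite propensity in reaction {network.reactions[info].name!r}"
        )
    if status == 2:
        raise SimulationError(f"event budget of {MAX_EVENTS} exhausted before t_end")


def simulate(
    network: ReactionNetwork,
    initial: SystemState | None = None,
    t_end: float = 16.0,
    seed: int = 0,
) -> Trajectory:
    """Run one exact SSA trajectory on [0, t_end].

    ``initial`` defaults to the network's canonical start (all promoters
    free, no mRNA or protein). Identical arguments give bit-identical output.
    """
    if t_end <= 0:
        raise ValueError(f"t_end must be positive, got {t_end}")
    seed = _check_seed(seed)
    if initial is None:
        initial = SystemState(network.initial_state(), 0.0)
    x0 = _check_initial(network, initial)
    stoich, kinds, si, sj, rates, extra = network.kernel_arrays()
    times, states, status, info = _kernels.ssa_trajectory(
        x0, stoich, kinds, si, sj, rates, extra, float(t_end), seed, MAX_EVENTS
    )
    _raise_on_status(network, status, info)
    # carry the last event state forward to t_end
    times = np.append(times, float(t_end))
    states = np.vstack([states, states[-1]])
    return Trajectory(times, states, seed, float(t_end), network.species)


def endpoint_ensemble(
    network: ReactionNetwork,
    initial: SystemState | None = None,
    t_end: float = 16.0,
    n_runs: int = 1000,
    base_seed: int = 0,
) -> list[SystemState]:
    """Endpoint states of ``n_runs`` independent runs, seeds base_seed..base_seed+n_runs-1.

    The endpoint is the state at t_end, not a time average. A warning is
    emitted when t_end is short relative to the slowest relaxation scale
    (10 / min(delta_m, delta_p)) and the endpoint may retain transients.
    """
    if n_runs < 1:
        raise ValueError(f"n_runs must be >= 1, got {n_runs}")
    if t_end <= 0:
        raise ValueError(f"t_end must be positive, got {t_end}")
    base_seed = _check_seed(base_seed)
    _check_seed(base_seed + n_runs - 1)
    if initial is None:
        initial = SystemState(network.initial_state(), 0.0)
    x0 = _check_initial(network, initial)
    p = network.parameters
    if p is not None and min(p.delta_m, p.delta_p) > 0:
        relax = 10.0 / min(p.delta_m, p.delta_p)
        if t_end < relax:
            warnings.warn(
                f"t_end={t_end} h is below the burn-in guideline {relax:.1f} h; "
                "endpoints may not be stationary",
                stacklevel=2,
            )
    stoich, kinds, si, sj, rates, extra = network.kernel_arrays()
    finals, status, info = _kernels.ssa_ensemble_final(
        x0, stoich, kinds, si, sj, rates, extra, float(t_end), base_seed, int(n_runs), MAX_EVENTS
    )
    for st, inf in zip(status, info):
        _raise_on_status(network, st, inf)
    return [SystemState(finals[i], float(t_end)) for i in range(n_runs)]
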