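"""Reaction-network definition of the CAA (cross-antagonism with autoregulation) circuit.

The circuit couples two transcription factors, A and B. Each factor activates
its own promoter and represses the opposite one. Promoters are modelled as
aggregate three-state counters (free / activator-bound / repressor-bound) so
that gene dosage enters simply as the number of promoter copies per side.
mRNA and protein are tracked separately, which lets slow promoter switching
relative to transcription produce bursty expression.

Both factors are TetR-derived fusions that bind operator DNA as homodimers,
so binding propensities are driven by the dimer pair count P(P-1)/2 rather
than the monomer count. This quadratic dependence is what gives the
mean-field system enough nonlinearity to be tristable under strong
repression.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = [
    "ParameterError",
    "CircuitParameters",
    "Reaction",
    "ReactionNetwork",
    "build_network",
    "default_parameters",
    "SPECIES_ORDER",
    "K_CONST",
    "K_LINEAR",
    "K_BILINEAR",
    "K_PAIR",
    "K_OCCUPANCY",
]


class ParameterError(ValueError):
    """A circuit parameter violates its domain constraints."""


#: species layout produced by :func:`build_network` (aggregate-promoter form)
SPECIES_ORDER = (
    "promoter_free_A",
    "promoter_act_A",
    "promoter_rep_A",
    "mrna_A",
    "protein_A",
    "promoter_free_B",
    "promoter_act_B",
    "promoter_rep_B",
    "mrna_B",
    "protein_B",
)

# propensity kinds understood by the simulation kernel
K_CONST = 0      # rate
K_LINEAR = 1     # rate * x[i]
K_BILINEAR = 2   # rate * x[i] * x[j]
K_PAIR = 3       # rate * x[i] * x[j]*(x[j]-1)/2   (dimer-driven binding)
K_OCCUPANCY = 4  # multi-operator transcription; see promoter.py

_RATE_FIELDS = (
    "k_act_on",
    "k_act_off",
    "k_rep_on",
    "k_rep_off",
    "alpha_active",
    "alpha_basal",
    "alpha_repressed",
    "beta",
    "delta_m",
    "delta_p",
)


@dataclass(frozen=True)
class CircuitParameters:
    """Kinetic rates, repression strength and gene dosage for both circuit sides.

    All rates are per hour; first-order binding constants are per dimer pair
    per hour. ``copies_A``/``copies_B`` are promoter (plasmid) copy numbers,
    ``operator_sites`` the number of tandem operator sites per promoter.

    The shipped defaults are the strong-repression set; use
    :func:`default_parameters` for the documented strong/weak pair.
    """

    copies_A: int = 1
    copies_B: int = 1
    operator_sites: int = 1
    k_act_on: float = 5.0e-4
    k_act_off: float = 1.0
    k_rep_on: float = 1.0e-4
    k_rep_off: float = 1.0
    alpha_active: float = 60.0
    alpha_basal: float = 6.0
    alpha_repressed: float = 0.0
    beta: float = 10.0
    delta_m: float = 3.0
    delta_p: float = 0.7
    repression_mode: str = "strong"
    #: repression dominance of the multi-operator activity model (promoter.py)
    repression_dominance: float = 0.5

    def __post_init__(self) -> None:
        for name in _RATE_FIELDS:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ParameterError(f"{name} must be a finite nonnegative rate, got {v!r}")
        for name in ("copies_A", "copies_B"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ParameterError(f"{name} must be an integer >= 1, got {v!r}")
        if not isinstance(self.operator_sites, (int, np.integer)) or self.operator_sites < 1:
            raise ParameterError(
                f"operator_sites must be an integer >= 1, got {self.operator_sites!r}"
            )
        if not self.alpha_repressed <= self.alpha_basal <= self.alpha_active:
            raise ParameterError(
                "alpha ordering violated: require alpha_repressed <= alpha_basal "
                f"<= alpha_active, got ({self.alpha_repressed}, {self.alpha_basal}, "
                f"{self.alpha_active})"
            )
        if self.repression_mode not in ("strong", "weak"):
            raise ParameterError(
                f"repression_mode must be 'strong' or 'weak', got {self.repression_mode!r}"
            )
        if self.repression_mode == "strong":
            if self.alpha_repressed != 0:
                raise ParameterError(
                    "repression_mode='strong' requires alpha_repressed = 0, "
                    f"got {self.alpha_repressed}"
                )
            if self.k_rep_off > self.k_act_off:
                raise ParameterError(
                    "repression_mode='strong' requires k_rep_off <= k_act_off, "
                    f"got k_rep_off={self.k_rep_off} > k_act_off={self.k_act_off}"
                )
        else:
            if self.alpha_repressed <= 0:
                raise ParameterError(
                    "repression_mode='weak' requires alpha_repressed > 0, "
                    f"got {self.alpha_repressed}"
                )
        if not 0.0 <= self.repression_dominance <= 1.0:
            raise ParameterError(
                f"repression_dominance must lie in [0, 1], got {self.repression_dominance}"
            )

    # -- derived equilibrium constants (pair-count units) ------------------
    @property
    def K_act(self) -> float:
        """Activator dissociation constant, in dimer-pair-count units."""
        if self.k_act_on == 0:
            return np.inf
        return self.k_act_off / self.k_act_on

    @property
    def K_rep(self) -> float:
        """Repressor dissociation constant, in dimer-pair-count units."""
        if self.k_rep_on == 0:
            return np.inf
        return self.k_rep_off / self.k_rep_on

    def with_copies(self, copies_A: int, copies_B: int) -> "CircuitParameters":
        return replace(self, copies_A=copies_A, copies_B=copies_B)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "CircuitParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown parameter field(s): {sorted(unknown)}")
        return cls(**d)


def default_parameters(mode: str = "strong") -> CircuitParameters:
    """Documented symmetric default parameter sets.

    ``strong``: complete silencing by a bound repressor (alpha_repressed = 0)
    and slow repressor unbinding (K_rep = 1e4 pair units). The mean-field
    system is tristable: two exclusive states and a symmetric intermediate.

    ``weak``: steric-occlusion repression with a 30% transcriptional leak
    (alpha_repressed = 0.3 * alpha_basal) and 20-fold weaker binding
    (K_rep = 2e5, faster k_rep_off). The mean-field system is monostable.

    Promoter switching (k_act_off = 1/h, k_rep_off <= 5/h) is slow relative
    to active transcription (60 mRNA/h), which produces transcriptional
    bursting in the stochastic model.
    """
    if mode == "strong":
        return CircuitParameters()
    if mode == "weak":
        return CircuitParameters(
            k_rep_on=2.5e-5,
            k_rep_off=5.0,
            alpha_repressed=1.8,
            repression_mode="weak",
        )
    raise ParameterError(f"mode must be 'strong' or 'weak', got {mode!r}")


def _pair(x: float) -> float:
    return x * (x - 1) / 2.0 if x > 1 else 0.0


@dataclass(frozen=True)
class Reaction:
    """One reaction channel: stoichiometry plus a declaratively-encoded propensity.

    ``kind`` selects the propensity law (K_* constants); ``i``/``j`` are
    species indices used by that law and ``rate`` the rate constant.
    ``extra`` carries the occupancy-model parameters for K_OCCUPANCY channels.
    """

    name: str
    stoichiometry: tuple
    kind: int
    i: int
    j: int
    rate: float
    extra: tuple = ()

    def propensity(self, x: np.ndarray) -> float:
        if self.kind == K_CONST:
            return self.rate
        if self.kind == K_LINEAR:
            return self.rate * x[self.i]
        if self.kind == K_BILINEAR:
            return self.rate * x[self.i] * x[self.j]
        if self.kind == K_PAIR:
            return self.rate * x[self.i] * _pair(x[self.j])
        if self.kind == K_OCCUPANCY:
            from .promoter import expected_activity_default

            m, s, inv_Ka, inv_Kr, aa, ab, ar, copies = self.extra
            act = _pair(x[self.i]) * inv_Ka
            rep = _pair(x[self.j]) * inv_Kr
            return copies * expected_activity_default(int(m), act, rep, aa, ab, ar, s)
        raise ValueError(f"unknown propensity kind {self.kind}")


@dataclass
class ReactionNetwork:
    """Species list plus reaction channels, compiled lazily to kernel arrays."""

    species: tuple
    reactions: tuple
    parameters: CircuitParameters | None = None
    _arrays: dict = field(default_factory=dict, repr=False)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def species_index(self, name: str) -> int:
        return self.species.index(name)

    def stoichiometry_matrix(self) -> np.ndarray:
        return np.array([r.stoichiometry for r in self.reactions], dtype=np.int64)

    def propensities(self, x: np.ndarray) -> np.ndarray:
        return np.array([r.propensity(x) for r in self.reactions], dtype=float)

    def kernel_arrays(self):
        """Pack reactions into flat arrays for the numba kernel (cached)."""
        if not self._arrays:
            n = len(self.reactions)
            stoich = self.stoichiometry_matrix()
            kinds = np.array([r.kind for r in self.reactions], dtype=np.int64)
            si = np.array([r.i for r in self.reactions], dtype=np.int64)
            sj = np.array([r.j for r in self.reactions], dtype=np.int64)
            rates = np.array([r.rate for r in self.reactions], dtype=np.float64)
            extra = np.zeros((n, 8), dtype=np.float64)
            for q, r in enumerate(self.reactions):
                if r.extra:
                    extra[q, : len(r.extra)] = r.extra
            self._arrays = dict(
                stoich=stoich, kinds=kinds, si=si, sj=sj, rates=rates, extra=extra
            )
        a = self._arrays
        return a["stoich"], a["kinds"], a["si"], a["sj"], a["rates"], a["extra"]

    def initial_state(self) -> np.ndarray:
        """All promoters free, zero mRNA and protein."""
        x = np.zeros(self.n_species, dtype=np.int64)
        if self.parameters is not None and "promoter_free_A" in self.species:
            x[self.species_index("promoter_free_A")] = self.parameters.copies_A
            x[self.species_index("promoter_free_B")] = self.parameters.copies_B
        return x

    def check_conservation(self, x: np.ndarray) -> bool:
        """Promoter copies per side are conserved; all counts nonnegative."""
        if np.any(x < 0):
            return False
        if self.parameters is None or "promoter_free_A" in self.species:
            if self.parameters is None:
                return True
            for side, copies in (("A", self.parameters.copies_A), ("B", self.parameters.copies_B)):
                total = sum(
                    x[self.species_index(f"promoter_{st}_{side}")]
                    for st in ("free", "act", "rep")
                )
                if total != copies:
                    return False
        return True


def build_network(params: CircuitParameters) -> ReactionNetwork:
    """Assemble the CAA reaction network from a validated parameter set.

    Per side i (with opposite side j), per aggregate promoter-copy counter:
    activator binding (dimer-pair driven by protein_i), unbinding, repressor
    binding (driven by protein_j), unbinding; transcription from each promoter
    state at its own rate; translation; first-order mRNA and protein decay.
    Channels whose rate constant is exactly 0 are omitted, so a strong-mode
    symmetric network has 18 reactions and a weak-mode one 20.

    Binding is non-sequestering: protein counts are not decremented when a
    dimer occupies an operator (protein >> promoter copies in all regimes of
    interest).
    """
    # raises ParameterError if params were built by bypassing __init__
    params = CircuitParameters.from_dict(params.to_dict())

    idx = {name: k for k, name in enumerate(SPECIES_ORDER)}
    n = len(SPECIES_ORDER)
    reactions = []

    def add(name, changes, kind, i, j, rate):
        if rate == 0:
            return
        st = [0] * n
        for sp, dv in changes.items():
            st[idx[sp]] = dv
        reactions.append(Reaction(name, tuple(st), kind, i, j, rate))

    for side, other in (("A", "B"), ("B", "A")):
        free = f"promoter_free_{side}"
        act = f"promoter_act_{side}"
        rep = f"promoter_rep_{side}"
        m = f"mrna_{side}"
        p = f"protein_{side}"
        p_other = f"protein_{other}"
        add(f"act_bind_{side}", {free: -1, act: +1}, K_PAIR, idx[free], idx[p], params.k_act_on)
        add(f"act_unbind_{side}", {act: -1, free: +1}, K_LINEAR, idx[act], 0, params.k_act_off)
        add(f"rep_bind_{side}", {free: -1, rep: +1}, K_PAIR, idx[free], idx[p_other], params.k_rep_on)
        add(f"rep_unbind_{side}", {rep: -1, free: +1}, K_LINEAR, idx[rep], 0, params.k_rep_off)
        add(f"transcribe_active_{side}", {m: +1}, K_LINEAR, idx[act], 0, params.alpha_active)
        add(f"transcribe_basal_{side}", {m: +1}, K_LINEAR, idx[free], 0, params.alpha_basal)
        add(f"transcribe_repressed_{side}", {m: +1}, K_LINEAR, idx[rep], 0, params.alpha_repressed)
        add(f"translate_{side}", {p: +1}, K_LINEAR, idx[m], 0, params.beta)
        add(f"degrade_mrna_{side}", {m: -1}, K_LINEAR, idx[m], 0, params.delta_m)
        add(f"degrade_protein_{side}", {p: -1}, K_LINEAR, idx[p], 0, params.delta_p)

    return ReactionNetwork(tuple(SPECIES_ORDER), tuple(reactions), parameters=params)


def build_multisite_network(params: CircuitParameters) -> ReactionNetwork:
    """Alternative network in which transcription is driven by the equilibrium
    multi-operator occupancy model of :mod:`caacircuit.promoter`.

    Promoter configurations are treated as equilibrated on the timescale of
    transcription, so the network tracks only mRNA and protein (4 species);
    the transcription propensity per side is ``copies * E[activity]`` under
    the multinomial occupancy of ``operator_sites`` independent sites, with
    the default winner-take-most activity family at dominance
    ``params.repression_dominance``.
    """
    params = CircuitParameters.from_dict(params.to_dict())
    species = ("mrna_A", "protein_A", "mrna_B", "protein_B")
    idx = {name: k for k, name in enumerate(species)}
    inv_Ka = 0.0 if np.isinf(params.K_act) else 1.0 / params.K_act
    inv_Kr = 0.0 if np.isinf(params.K_rep) else 1.0 / params.K_rep
    reactions = []
    for side, other, copies in (("A", "B", params.copies_A), ("B", "A", params.copies_B)):
        m, p, po = idx[f"mrna_{side}"], idx[f"protein_{side}"], idx[f"protein_{other}"]
        st = [0] * 4
        st[m] = +1
        reactions.append(
            Reaction(
                f"transcribe_{side}",
                tuple(st),
                K_OCCUPANCY,
                p,
                po,
                1.0,
                extra=(
                    float(params.operator_sites),
                    params.repression_dominance,
                    inv_Ka,
                    inv_Kr,
                    params.alpha_active,
                    params.alpha_basal,
                    params.alpha_repressed,
                    float(copies),
                ),
            )
        )
        for nm, changes, i, rate in (
            (f"translate_{side}", {f"protein_{side}": +1}, m, params.beta),
            (f"degrade_mrna_{side}", {f"mrna_{side}": -1}, m, params.delta_m),
            (f"degrade_protein_{side}", {f"protein_{side}": -1}, p, params.delta_p),
        ):
            if rate == 0:
                continue
            st = [0] * 4
            for sp, dv in changes.items():
                st[idx[sp]] = dv
            reactions.append(Reaction(nm, tuple(st), K_LINEAR, i, 0, rate))
    return ReactionNetwork(species, tuple(reactions), parameters=params)
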