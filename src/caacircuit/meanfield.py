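"""Mean-field (deterministic) reduction of the CAA circuit and its fixed points.

Promoter occupancies are eliminated by a quasi-steady-state assumption: the
free/activator-bound/repressor-bound fractions of each promoter follow the
instantaneous protein levels through the binding-rate ratios. That leaves a
four-dimensional smooth vector field in (mRNA_A, P_A, mRNA_B, P_B).

The interesting physics lives at the stochastic level; this module exists to
anchor the strong/weak default parameter sets — strong repression must be
tristable (two exclusive states plus a symmetric intermediate), weak
repression monostable — and to supply self-calibrating expression thresholds
for the dosage sweep. At the mean-field level the bursting timescales drop
out; only equilibrium constants K_act = k_act_off/k_act_on and
K_rep = k_rep_off/k_rep_on (dimer-pair units) matter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import root

from .circuit import CircuitParameters, ParameterError, default_parameters

__all__ = [
    "FixedPoint",
    "mean_field_rates",
    "find_fixed_points",
    "count_stable_fixed_points",
    "label_fixed_points",
    "repression_strength_scan",
]

RESIDUAL_TOL = 1e-8
MERGE_RTOL = 1e-6
STABILITY_EIG_TOL = -1e-9


@dataclass(frozen=True)
class FixedPoint:
    """A root of the mean-field rate field, with linear stability."""

    state: np.ndarray  # (mRNA_A, P_A, mRNA_B, P_B)
    stable: bool
    leading_eigenvalue_real_part: float

    @property
    def protein_A(self) -> float:
        return float(self.state[1])

    @property
    def protein_B(self) -> float:
        return float(self.state[3])


def _pair(p: float) -> float:
    # continuum extension of the dimer pair count, clamped below P = 1
    return p * (p - 1.0) / 2.0 if p > 1.0 else 0.0


def mean_field_rates(params: CircuitParameters):
    """Return the mean-field rate field f(x) on x = (mRNA_A, P_A, mRNA_B, P_B).

    Occupancy fractions per side i (opposite j):
        w_act = pair(P_i)/K_act, w_rep = pair(P_j)/K_rep,
        (free, act, rep) = (1, w_act, w_rep) / (1 + w_act + w_rep)
    and transcription is copies_i * (alpha_active*act + alpha_basal*free +
    alpha_repressed*rep), followed by linear translation and decay.
    """
    if (params.k_act_on > 0 and params.k_act_off == 0) or (
        params.k_rep_on > 0 and params.k_rep_off == 0
    ):
        raise ParameterError(
            "mean-field reduction undefined: binding with zero unbinding rate "
            "(promoter occupancies have no equilibrium)"
        )
    inv_Ka = 0.0 if np.isinf(params.K_act) else 1.0 / params.K_act
    inv_Kr = 0.0 if np.isinf(params.K_rep) else 1.0 / params.K_rep
    aa, ab, ar = params.alpha_active, params.alpha_basal, params.alpha_repressed
    dm, dp, beta = params.delta_m, params.delta_p, params.beta
    copies = (params.copies_A, params.copies_B)

    def field(x):
        mA, pA, mB, pB = x
        out = np.empty(4)
        for k, (p_self, p_other, m_self, n) in enumerate(
            ((pA, pB, mA, copies[0]), (pB, pA, mB, copies[1]))
        ):
            wa = _pair(p_self) * inv_Ka
            wr = _pair(p_other) * inv_Kr
            Z = 1.0 + wa + wr
            G = (aa * wa + ab + ar * wr) / Z
            out[2 * k] = n * G - dm * m_self
            out[2 * k + 1] = beta * m_self - dp * p_self
        return out

    return field


def _jacobian(field, x: np.ndarray) -> np.ndarray:
    n = x.size
    J = np.empty((n, n))
    for i in range(n):
        h = 1e-6 * max(abs(x[i]), 1.0)
        e = np.zeros(n)
        e[i] = h
        J[:, i] = (field(x + e) - field(x - e)) / (2 * h)
    return J


def _protein_scale(params: CircuitParameters) -> float:
    if params.delta_m == 0 or params.delta_p == 0:
        return 1e4
    return (
        max(params.copies_A, params.copies_B)
        * params.alpha_active
        * params.beta
        / (params.delta_m * params.delta_p)
    )


def find_fixed_points(
    params: CircuitParameters, n_starts: int = 50, seed: int = 0
) -> list[FixedPoint]:
    """Multi-start root search over log-spaced protein-level initial guesses.

    Roots within relative distance 1e-6 are merged; stability is judged from
    the numerically-differenced Jacobian (stable iff max Re(eig) < -1e-9).
    Results are sorted by P_A. Returns an empty list (with a warning) if no
    start converges.
    """
    if n_starts < 20:
        raise ValueError(f"n_starts must be >= 20 for reliable coverage, got {n_starts}")
    field = mean_field_rates(params)
    p_max = max(_protein_scale(params), 10.0)
    g = int(np.ceil(np.sqrt(n_starts)))
    levels = np.logspace(-1, np.log10(3.0 * p_max), g)
    rng = np.random.default_rng(seed)
    starts = []
    for pa in levels:
        for pb in levels:
            starts.append((pa, pb))
    starts = starts[: max(n_starts, len(starts))]
    # mild multiplicative jitter decorrelates grid artifacts between calls
    jitter = rng.lognormal(0.0, 0.05, size=(len(starts), 2))

    dm = params.delta_m if params.delta_m > 0 else 1.0
    beta = params.beta if params.beta > 0 else 1.0
    dp = params.delta_p

    roots: list[np.ndarray] = []
    for (pa, pb), jit in zip(starts, jitter):
        pa, pb = pa * jit[0], pb * jit[1]
        x0 = np.array([dp * pa / beta, pa, dp * pb / beta, pb])
        sol = root(field, x0, method="hybr")
        x = sol.x
        if not sol.success or np.any(x < -1e-9):
            continue
        x = np.maximum(x, 0.0)
        if np.max(np.abs(field(x))) > RESIDUAL_TOL:
            continue
        if any(np.linalg.norm(x - y) / (1.0 + np.linalg.norm(y)) < MERGE_RTOL for y in roots):
            continue
        roots.append(x)

    if not roots:
        warnings.warn("no mean-field fixed point converged from any start", stacklevel=2)
        return []

    out = []
    for x in roots:
        lead = float(np.max(np.linalg.eigvals(_jacobian(field, x)).real))
        out.append(FixedPoint(x, lead < STABILITY_EIG_TOL, lead))
    out.sort(key=lambda fp: fp.protein_A)
    return out


def count_stable_fixed_points(params: CircuitParameters, n_starts: int = 50, seed: int = 0) -> int:
    """Number of stable mean-field steady states (3 = tristable, 1 = monostable)."""
    return sum(fp.stable for fp in find_fixed_points(params, n_starts=n_starts, seed=seed))


def label_fixed_points(fixed_points: list[FixedPoint]) -> dict[str, FixedPoint]:
    """Name the stable states: 'high_A', 'high_B', and 'intermediate'.

    The intermediate label goes to the stable point minimizing |P_A - P_B|;
    among the rest, highest P_A is 'high_A' and highest P_B is 'high_B'.
    """
    stable = [fp for fp in fixed_points if fp.stable]
    if not stable:
        return {}
    labels: dict[str, FixedPoint] = {}
    if len(stable) == 1:
        labels["intermediate"] = stable[0]
        return labels
    inter = min(stable, key=lambda fp: abs(fp.protein_A - fp.protein_B))
    labels["intermediate"] = inter
    rest = [fp for fp in stable if fp is not inter]
    labels["high_A"] = max(rest, key=lambda fp: fp.protein_A)
    labels["high_B"] = max(rest, key=lambda fp: fp.protein_B)
    return labels


def repression_strength_scan(n_points: int = 11, n_starts: int = 50, seed: int = 0):
    """Stable-state counts along the strong-to-weak default interpolation.

    Interpolates the repression parameters between the strong and weak
    default sets: alpha_repressed linearly in the leak fraction, k_rep_off
    and k_rep_on log-linearly (so K_rep moves log-linearly from 1e4 to 2e5).
    Returns a list of (s, count) with s = 0 the strong set and s = 1 the
    weak set.
    """
    strong = default_parameters("strong")
    weak = default_parameters("weak")
    out = []
    for s in np.linspace(0.0, 1.0, n_points):
        kro = float(np.exp((1 - s) * np.log(strong.k_rep_off) + s * np.log(weak.k_rep_off)))
        krn = float(np.exp((1 - s) * np.log(strong.k_rep_on) + s * np.log(weak.k_rep_on)))
        ar = float(s * weak.alpha_repressed)
        params = CircuitParameters(
            k_rep_on=krn,
            k_rep_off=kro,
            alpha_repressed=ar,
            repression_mode="strong" if ar == 0 else "weak",
        )
        out.append((float(s), count_stable_fixed_points(params, n_starts=n_starts, seed=seed)))
    return out
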