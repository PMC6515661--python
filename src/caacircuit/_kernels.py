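"""Numba-compiled inner loops for the exact (direct-method) Gillespie simulator.

The kernels consume the flat reaction encoding produced by
``ReactionNetwork.kernel_arrays``. Randomness comes from numba's
``np.random`` (Mersenne Twister, same algorithm as legacy NumPy), seeded
explicitly inside each kernel call so that a (network, initial, t_end, seed)
tuple maps to a bit-identical trajectory on every platform.

Status codes: 0 = reached t_end, 1 = non-finite propensity (offending
reaction index in the second return slot), 2 = event budget exhausted.
"""

import numpy as np
from numba import njit

K_CONST = 0
K_LINEAR = 1
K_BILINEAR = 2
K_PAIR = 3
K_OCCUPANCY = 4


@njit(cache=True, inline="always")
def _pair(x):
    return x * (x - 1.0) * 0.5 if x > 1.0 else 0.0


@njit(cache=True, inline="always")
def _occupancy_propensity(xi, xj, ex):
    # closed-form expectation of the default winner-take-most activity family
    # under the multinomial occupancy of m independent identical sites
    m = ex[0]
    s = ex[1]
    wa = _pair(xi) * ex[2]
    wr = _pair(xj) * ex[3]
    aa = ex[4]
    ab = ex[5]
    ar = ex[6]
    copies = ex[7]
    Z = 1.0 + wa + wr
    pA = wa / Z
    pR = wr / Z
    d = aa - ab
    graded = ab * (1.0 - pR) + d * pA * (1.0 - (m - 1.0) * pR / m)
    noR = (1.0 - pR) ** (m - 1.0)
    dominant = ab * noR * (1.0 - pR) + d * pA * noR
    return copies * (ar * pR + (1.0 - s) * graded + s * dominant)


@njit(cache=True, inline="always")
def _propensities(x, kinds, si, sj, rates, extra, a):
    atot = 0.0
    bad = -1
    for r in range(rates.shape[0]):
        k = kinds[r]
        if k == K_CONST:
            v = rates[r]
        elif k == K_LINEAR:
            v = rates[r] * x[si[r]]
        elif k == K_BILINEAR:
            v = rates[r] * x[si[r]] * x[sj[r]]
        elif k == K_PAIR:
            v = rates[r] * x[si[r]] * _pair(float(x[sj[r]]))
        else:
            v = rates[r] * _occupancy_propensity(float(x[si[r]]), float(x[sj[r]]), extra[r])
        if not np.isfinite(v) or v < 0.0:
            bad = r
            v = 0.0
        a[r] = v
        atot += v
    return atot, bad


@njit(cache=True)
def ssa_final(x0, stoich, kinds, si, sj, rates, extra, t_end, seed, max_events):
    """Direct-method SSA returning only the state at t_end."""
    np.random.seed(seed)
    x = x0.copy()
    a = np.empty(rates.shape[0])
    t = 0.0
    n_events = 0
    while True:
        atot, bad = _propensities(x, kinds, si, sj, rates, extra, a)
        if bad >= 0:
            return x, 1, bad
        if atot <= 0.0:
            return x, 0, n_events
        t += np.random.exponential(1.0 / atot)
        if t > t_end:
            return x, 0, n_events
        if n_events >= max_events:
            return x, 2, n_events
        u = np.random.random() * atot
        c = 0.0
        mu = rates.shape[0] - 1
        for r in range(rates.shape[0]):
            c += a[r]
            if u < c:
                mu = r
                break
        for s_ in range(x.shape[0]):
            x[s_] += stoich[mu, s_]
        n_events += 1


@njit(cache=True)
def ssa_trajectory(x0, stoich, kinds, si, sj, rates, extra, t_end, seed, max_events):
    """Direct-method SSA recording every event (times and states)."""
    np.random.seed(seed)
    n_sp = x0.shape[0]
    cap = 4096
    times = np.empty(cap)
    states = np.empty((cap, n_sp), dtype=np.int64)
    x = x0.copy()
    times[0] = 0.0
    states[0] = x
    n = 1
    a = np.empty(rates.shape[0])
    t = 0.0
    while True:
        atot, bad = _propensities(x, kinds, si, sj, rates, extra, a)
        if bad >= 0:
            return times[:n], states[:n], 1, bad
        if atot <= 0.0:
            return times[:n], states[:n], 0, 0
        t += np.random.exponential(1.0 / atot)
        if t > t_end:
            return times[:n], states[:n], 0, 0
        if n - 1 >= max_events:
            return times[:n], states[:n], 2, 0
        u = np.random.random() * atot
        c = 0.0
        mu = rates.shape[0] - 1
        for r in range(rates.shape[0]):
            c += a[r]
            if u < c:
                mu = r
                break
        for s_ in range(n_sp):
            x[s_] += stoich[mu, s_]
        if n == cap:
            cap *= 2
            new_t = np.empty(cap)
            new_s = np.empty((cap, n_sp), dtype=np.int64)
            new_t[:n] = times[:n]
            new_s[:n] = states[:n]
            times = new_t
            states = new_s
        times[n] = t
        states[n] = x
        n += 1


@njit(cache=True)
def ssa_ensemble_final(x0, stoich, kinds, si, sj, rates, extra, t_end, base_seed, n_runs, max_events):
    """n_runs independent endpoint states, run i seeded with base_seed + i."""
    out = np.empty((n_runs, x0.shape[0]), dtype=np.int64)
    status = np.zeros(n_runs, dtype=np.int64)
    info = np.zeros(n_runs, dtype=np.int64)
    for i in range(n_runs):
        x, st, inf = ssa_final(
            x0, stoich, kinds, si, sj, rates, extra, t_end, base_seed + i, max_events
        )
        out[i] = x
        status[i] = st
        info[i] = inf
    return out, status, info
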