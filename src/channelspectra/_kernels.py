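"""Numba-compiled inner loops.

The kernels are deliberately model-agnostic: all voltage-dependent rate
tables are precomputed (vectorized) by the caller, so no gating formulas
live here.  Time is in ms throughout.
"""

import numpy as np
from numba import njit


@njit(cache=False)
def euler_gates(alpha, beta, x0, dt):
    """Forward-Euler for independent first-order gates.

    alpha, beta : (n_steps, G) rate tables in ms^-1, row s applies on
    [t_s, t_s + dt).  x0 : (G,) initial gate values.  Returns
    (n_steps + 1, G) trajectories.
    """
    n_steps, G = alpha.shape
    out = np.empty((n_steps + 1, G))
    x = x0.copy()
    out[0] = x
    for s in range(n_steps):
        for g in range(G):
            x[g] += dt * (alpha[s, g] * (1.0 - x[g]) - beta[s, g] * x[g])
        out[s + 1] = x
    return out


@njit(cache=False)
def euler_affine2(a11, a12, a21, a22, c1, c2, p0, dt):
    """Forward-Euler for dp/dt = A(t) p + c(t), p in R^2.

    Coefficient arrays have length n_steps (row s frozen on its interval).
    Returns (n_steps + 1, 2).
    """
    n_steps = a11.shape[0]
    out = np.empty((n_steps + 1, 2))
    p1 = p0[0]
    p2 = p0[1]
    out[0, 0] = p1
    out[0, 1] = p2
    for s in range(n_steps):
        d1 = a11[s] * p1 + a12[s] * p2 + c1[s]
        d2 = a21[s] * p1 + a22[s] * p2 + c2[s]
        p1 += dt * d1
        p2 += dt * d2
        out[s + 1, 0] = p1
        out[s + 1, 1] = p2
    return out


@njit(cache=False)
def ssa_chain(n0, up, down, dt, seed):
    """Exact Gillespie SSA for a birth-death chain of channel counts.

    n0   : (S,) int64 initial counts per state.
    up   : (n_steps, S-1) per-channel forward rates (state k -> k+1), ms^-1,
           frozen on each dt interval.
    down : (n_steps, S-1) per-channel backward rates (state k+1 -> k).
    Returns (n_steps + 1, S) int64 counts sampled on the dt grid.

    Within an interval the rates are constant, so discarding the pending
    waiting time at each boundary is exact (memorylessness).
    """
    np.random.seed(seed)
    n_steps = up.shape[0]
    S = n0.shape[0]
    counts = np.empty((n_steps + 1, S), dtype=np.int64)
    N = n0.copy()
    counts[0] = N
    a = np.empty(2 * (S - 1))  # propensities: up 0..S-2 then down 0..S-2
    for s in range(n_steps):
        R = 0.0
        for k in range(S - 1):
            a[k] = up[s, k] * N[k]
            a[S - 1 + k] = down[s, k] * N[k + 1]
            R += a[k] + a[S - 1 + k]
        t_local = 0.0
        while R > 0.0:
            u = np.random.random()
            # guard against log(0)
            while u <= 0.0:
                u = np.random.random()
            t_local -= np.log(u) / R
            if t_local >= dt:
                break
            r = np.random.random() * R
            acc = 0.0
            idx = 2 * (S - 1) - 1
            for j in range(2 * (S - 1)):
                acc += a[j]
                if r < acc:
                    idx = j
                    break
            if idx < S - 1:  # up transition idx -> idx+1
                k = idx
                N[k] -= 1
                N[k + 1] += 1
            else:  # down transition k+1 -> k
                k = idx - (S - 1)
                N[k + 1] -= 1
                N[k] += 1
            if N[k] < 0 or N[k + 1] < 0:
                raise RuntimeError("negative channel count (SSA logic error)")
            # refresh the four propensities touched by states k, k+1
            R = 0.0
            for j in range(S - 1):
                a[j] = up[s, j] * N[j]
                a[S - 1 + j] = down[s, j] * N[j + 1]
                R += a[j] + a[S - 1 + j]
        counts[s + 1] = N
    return counts
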