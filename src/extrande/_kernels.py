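"""Compiled (numba) fast paths for ensemble-scale simulation.

The generic simulators in :mod:`extrande.core` and :mod:`extrande.reference`
accept arbitrary propensity callables; these kernels cover the common case
that dominates ensemble runs — a mass-action network (optionally with
input-multiplied channels) driven by a uniform-grid step-function input,
recording the state on a sample grid only.  The dispatchers fall back to the
pure-Python path whenever any of those conditions fails (or numba is
unavailable), so the kernels are an engine choice, not a behaviour change:
both engines sample the same law (with distinct RNG streams).
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is a hard dependency in practice
    HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore
        def deco(f):
            return f

        return deco if not (a and callable(a[0])) else a[0]


# stats vector layout shared by the kernels
ACC, THIN, REJ, EVALS, EXP = 0, 1, 2, 3, 4


@njit(cache=False)
def _props_sum(x, I, rates, orders, iscaled):
    M, n = orders.shape
    total = 0.0
    for j in range(M):
        aj = rates[j]
        if iscaled[j]:
            aj *= I
        for i in range(n):
            k = orders[j, i]
            for q in range(k):
                aj *= x[i] - q
        total += aj
    return total


@njit(cache=False)
def _props_vec(x, I, rates, orders, iscaled, a):
    M, n = orders.shape
    total = 0.0
    for j in range(M):
        aj = rates[j]
        if iscaled[j]:
            aj *= I
        for i in range(n):
            k = orders[j, i]
            for q in range(k):
                aj *= x[i] - q
        a[j] = aj
        total += aj
    return total


@njit(cache=False)
def extrande_ma_kernel(
    S, rates, orders, iscaled, vals, inv_dt, T, L, safety, seed, sgrid, out, stats, x0
):
    """Thinning loop, monotone-sup bound, uniform step-function input.

    Returns 0 on success, -1 on a detected bound violation.  ``stats`` is the
    5-vector [accepted, thinned, rejected, propensity_evals, exp_drawn].
    """
    np.random.seed(seed)
    M, n_s = S.shape
    n_grid = vals.shape[0]
    n_samp = sgrid.shape[0]
    x = x0.copy()
    a = np.empty(M)
    gi = 0
    t = 0.0
    while t < T:
        L_eff = L if L < T - t else T - t
        i0 = int(t * inv_dt)
        i1 = int((t + L_eff) * inv_dt)
        if i0 >= n_grid:
            i0 = n_grid - 1
        if i1 >= n_grid:
            i1 = n_grid - 1
        imax = vals[i0]
        for ii in range(i0 + 1, i1 + 1):
            if vals[ii] > imax:
                imax = vals[ii]
        B = safety * _props_sum(x, imax, rates, orders, iscaled)
        stats[EVALS] += M
        stats[EXP] += 1
        if B <= 0.0:
            stats[REJ] += 1
            t += L_eff
            continue
        tau = np.random.standard_exponential() / B
        if tau > L_eff:
            stats[REJ] += 1
            t += L_eff
            continue
        t += tau
        idx = int(t * inv_dt)
        if idx >= n_grid:
            idx = n_grid - 1
        a0 = _props_vec(x, vals[idx], rates, orders, iscaled, a)
        stats[EVALS] += M
        if a0 > B * (1.0 + 1e-9):
            return -1
        Bu = B * np.random.random()
        if a0 >= Bu:
            j = M - 1
            if Bu <= 0.0:
                for jj in range(M):
                    if a[jj] > 0.0:
                        j = jj
                        break
            else:
                c = 0.0
                for jj in range(M):
                    c += a[jj]
                    if c >= Bu:
                        j = jj
                        break
            while gi < n_samp and sgrid[gi] < t:
                for i in range(n_s):
                    out[gi, i] = x[i]
                gi += 1
            for i in range(n_s):
                x[i] += S[j, i]
            stats[ACC] += 1
        else:
            stats[THIN] += 1
    while gi < n_samp:
        for i in range(n_s):
            out[gi, i] = x[i]
        gi += 1
    return 0


@njit(cache=False)
def sia_ma_kernel(S, rates, orders, iscaled, vals, inv_dt, T, seed, sgrid, out, stats, x0):
    """SSA with the input frozen between firings (stale-input loop).

    Returns 1 if the run trapped (total stale propensity hit zero), else 0.
    """
    np.random.seed(seed)
    M, n_s = S.shape
    n_grid = vals.shape[0]
    n_samp = sgrid.shape[0]
    x = x0.copy()
    a = np.empty(M)
    gi = 0
    t = 0.0
    I_stale = vals[0]
    trapped = 0
    while True:
        a0 = _props_vec(x, I_stale, rates, orders, iscaled, a)
        stats[EVALS] += M
        if a0 <= 0.0:
            trapped = 1
            break
        t += np.random.standard_exponential() / a0
        if t >= T:
            break
        stats[EXP] += 1
        Bu = a0 * np.random.random()
        c = 0.0
        j = M - 1
        for jj in range(M):
            c += a[jj]
            if c >= Bu:
                j = jj
                break
        while gi < n_samp and sgrid[gi] < t:
            for i in range(n_s):
                out[gi, i] = x[i]
            gi += 1
        for i in range(n_s):
            x[i] += S[j, i]
        stats[ACC] += 1
        idx = int(t * inv_dt)
        if idx >= n_grid:
            idx = n_grid - 1
        I_stale = vals[idx]
    while gi < n_samp:
        for i in range(n_s):
            out[gi, i] = x[i]
        gi += 1
    return trapped
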