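"""JIT-compiled SMO-style solver for box-and-simplex quadratic programs.

Solves  min_a  (1/2) a' K a - p' a   s.t.  0 <= a_i <= U,  sum_i a_i = 1,
by maximal-violating-pair coordinate updates (the working-set strategy of
classical SMO implementations).  Both the nu-one-class SVM dual (p = 0,
U = 1/(nu N)) and the SVDD dual (p = diag(K)/2, U = C) are instances.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def solve_box_simplex(K, p, upper, tol, max_iter):
    """Return (alpha, n_iter, kkt_gap).

    K must be symmetric positive semidefinite; a feasible start spreads the
    unit mass over the first ceil(1/U) coordinates.  Terminates when the
    maximal KKT violation (max gradient over movable-down minus min gradient
    over movable-up coordinates) falls below ``tol``.
    """
    n = K.shape[0]
    alpha = np.zeros(n)
    rem = 1.0
    for i in range(n):
        a = upper if upper < rem else rem
        alpha[i] = a
        rem -= a
        if rem <= 0.0:
            break
    g = K @ alpha - p
    eps = 1e-12
    it = 0
    gap = 0.0
    while it < max_iter:
        i_up = -1
        g_up = 1e300
        j_dn = -1
        g_dn = -1e300
        for t in range(n):
            if alpha[t] < upper - eps and g[t] < g_up:
                g_up = g[t]
                i_up = t
            if alpha[t] > eps and g[t] > g_dn:
                g_dn = g[t]
                j_dn = t
        gap = g_dn - g_up
        if i_up < 0 or j_dn < 0 or gap <= tol:
            break
        denom = K[i_up, i_up] + K[j_dn, j_dn] - 2.0 * K[i_up, j_dn]
        if denom <= 1e-15:
            delta = min(upper - alpha[i_up], alpha[j_dn])
        else:
            delta = gap / denom
            lim = upper - alpha[i_up]
            if delta > lim:
                delta = lim
            if delta > alpha[j_dn]:
                delta = alpha[j_dn]
        alpha[i_up] += delta
        alpha[j_dn] -= delta
        for t in range(n):
            g[t] += delta * (K[t, i_up] - K[t, j_dn])
        it += 1
    return alpha, it, gap


@njit(cache=True)
def rbf_gram(X, Y, gamma):
    """exp(-gamma * ||x - y||^2) for all row pairs."""
    n, d = X.shape
    m = Y.shape[0]
    out = np.empty((n, m))
    for i in range(n):
        for j in range(m):
            s = 0.0
            for k in range(d):
                diff = X[i, k] - Y[j, k]
                s += diff * diff
            out[i, j] = np.exp(-gamma * s)
    return out


@njit(cache=True)
def preimage_iterate(SV, alpha, gamma, z0, tol, max_iter):
    """Fixed-point iteration for the RBF preimage of w = sum_i alpha_i phi(x_i).

    Returns (z, converged, n_iter, residual, objective, ok) where ok=False
    signals a restart condition (denominator underflow or a decrease of the
    feature-space objective sum_i alpha_i k(x_i, z)).
    """
    n, d = SV.shape
    z = z0.copy()
    w = np.empty(n)
    obj_prev = -1.0
    converged = False
    residual = 0.0
    it = 0
    ok = True
    while it < max_iter:
        denom = 0.0
        for i in range(n):
            s = 0.0
            for k in range(d):
                diff = z[k] - SV[i, k]
                s += diff * diff
            w[i] = alpha[i] * np.exp(-gamma * s)
            denom += w[i]
        if denom < 1e-300:
            ok = False
            break
        if obj_prev >= 0.0 and denom < obj_prev - 1e-12:
            ok = False
            break
        obj_prev = denom
        residual = 0.0
        for k in range(d):
            zk = 0.0
            for i in range(n):
                zk += w[i] * SV[i, k]
            zk /= denom
            diff = zk - z[k]
            residual += diff * diff
            z[k] = zk
        residual = np.sqrt(residual)
        it += 1
        if residual <= tol:
            converged = True
            break
    # objective at the final iterate
    obj = 0.0
    for i in range(n):
        s = 0.0
        for k in range(d):
            diff = z[k] - SV[i, k]
            s += diff * diff
        obj += alpha[i] * np.exp(-gamma * s)
    return z, converged, it, residual, obj, ok
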