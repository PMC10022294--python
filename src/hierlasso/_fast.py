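"""Compiled Cox kernels.

All kernels operate on arrays pre-sorted ascending by observed time together
with a ``risk_start`` array: ``risk_start[k]`` is the first sorted position
whose time equals the time at position ``k``, so the Breslow risk set of an
event at position ``k`` is ``risk_start[k] .. n-1``.

The pure-numpy routines in :mod:`hierlasso.core_survival` are the readable
reference implementations; the test suite asserts the two paths agree.
"""

from __future__ import annotations

import numpy as np
from numba import njit

COEF_CLAMP = 50.0


@njit(cache=True)
def cox_loglik_sorted(eta, ev, risk_start):
    """Breslow partial log-likelihood from a sorted linear predictor."""
    n = eta.shape[0]
    shift = eta[0]
    for i in range(n):
        if eta[i] > shift:
            shift = eta[i]
    e = np.empty(n)
    for i in range(n):
        e[i] = np.exp(eta[i] - shift)
    s0 = np.empty(n)
    acc = 0.0
    for i in range(n - 1, -1, -1):
        acc += e[i]
        s0[i] = acc
    ll = 0.0
    for k in range(n):
        if ev[k] == 1:
            ll += eta[k] - shift - np.log(s0[risk_start[k]])
    return ll


@njit(cache=True)
def cox_weights_sorted(eta, ev, risk_start, w, g):
    """Per-subject gradient ``g`` and diagonal-Hessian weight ``w`` of the
    Breslow partial log-likelihood; returns the log-likelihood.

    ``g[i] = d_i - exp(eta_i) * H(t_i)`` and
    ``w[i] = exp(eta_i) H(t_i) - exp(2 eta_i) H2(t_i)`` where ``H`` / ``H2``
    accumulate ``1/S`` and ``1/S^2`` over event times at or before ``t_i``.
    """
    n = eta.shape[0]
    shift = eta[0]
    for i in range(n):
        if eta[i] > shift:
            shift = eta[i]
    e = np.empty(n)
    for i in range(n):
        e[i] = np.exp(eta[i] - shift)
    s0 = np.empty(n)
    acc = 0.0
    for i in range(n - 1, -1, -1):
        acc += e[i]
        s0[i] = acc
    inc1 = np.zeros(n)
    inc2 = np.zeros(n)
    ll = 0.0
    for k in range(n):
        if ev[k] == 1:
            rs = risk_start[k]
            s = s0[rs]
            inc1[rs] += 1.0 / s
            inc2[rs] += 1.0 / (s * s)
            ll += eta[k] - shift - np.log(s)
    h1 = 0.0
    h2 = 0.0
    for i in range(n):
        h1 += inc1[i]
        h2 += inc2[i]
        g[i] = ev[i] - e[i] * h1
        wi = e[i] * h1 - e[i] * e[i] * h2
        w[i] = wi if wi > 0.0 else 0.0
    return ll


@njit(cache=True)
def _cd_sweep(V, w, r, beta, colsq, pen1, pen2, cols, n):
    """One coordinate-descent pass over ``cols``.

    Returns the maximum weighted squared coefficient change
    ``colsq_c * delta_c^2`` (the glmnet convergence measure)."""
    max_delta = 0.0
    for idx in range(cols.shape[0]):
        c = cols[idx]
        cs = colsq[c]
        if cs <= 0.0 and pen2[c] <= 0.0:
            continue
        b_old = beta[c]
        acc = 0.0
        for i in range(n):
            acc += w[i] * V[i, c] * r[i]
        num = b_old * cs + acc / n
        # soft threshold
        p1 = pen1[c]
        if num > p1:
            b_new = (num - p1) / (cs + pen2[c])
        elif num < -p1:
            b_new = (num + p1) / (cs + pen2[c])
        else:
            b_new = 0.0
        if b_new != b_old:
            d = b_new - b_old
            for i in range(n):
                r[i] -= d * V[i, c]
            beta[c] = b_new
            dd = cs * d * d
            if dd > max_delta:
                max_delta = dd
    return max_delta


@njit(cache=True)
def fit_penalized_sorted(
    V, ev, risk_start, beta, pen1, pen2, cd_tol, max_updates, max_irls
):
    """IRLS with coordinate-wise soft-thresholding for the weighted
    elastic-net Cox objective ``loglik/n - sum(pen1 |b| + pen2 b^2 / 2)``.

    ``beta`` is updated in place (warm start).  Convergence uses the glmnet
    measure: the maximum weighted squared coefficient change
    ``colsq_c * delta_c^2`` of a pass must fall below ``cd_tol``.  Returns
    ``(loglik, n_irls, n_updates, converged)``.
    """
    n, m = V.shape
    w = np.empty(n)
    g = np.empty(n)
    r = np.empty(n)
    eta = np.empty(n)
    colsq = np.empty(m)
    all_cols = np.arange(m)
    total_updates = 0
    converged = False
    ll = 0.0
    for it in range(max_irls):
        for i in range(n):
            eta[i] = 0.0
        for c in range(m):
            bc = beta[c]
            if bc != 0.0:
                for i in range(n):
                    eta[i] += V[i, c] * bc
        ll = cox_weights_sorted(eta, ev, risk_start, w, g)
        # working residual: r = z - eta = g / w (0 where w == 0)
        for i in range(n):
            r[i] = g[i] / w[i] if w[i] > 1e-12 else 0.0
            if w[i] <= 1e-12:
                w[i] = 0.0
        for c in range(m):
            acc = 0.0
            for i in range(n):
                acc += w[i] * V[i, c] * V[i, c]
            colsq[c] = acc / n
        # full sweep, then active-set cycling, then a confirming full sweep
        irls_delta = _cd_sweep(V, w, r, beta, colsq, pen1, pen2, all_cols, n)
        total_updates += m
        while True:
            active = np.flatnonzero(beta)
            for _ in range(1000):
                d_in = _cd_sweep(V, w, r, beta, colsq, pen1, pen2, active, n)
                total_updates += active.shape[0]
                if d_in < cd_tol or total_updates > max_updates:
                    break
            d_full = _cd_sweep(V, w, r, beta, colsq, pen1, pen2, all_cols, n)
            total_updates += m
            if d_full > irls_delta:
                irls_delta = d_full
            if d_full < cd_tol or total_updates > max_updates:
                break
        if irls_delta < cd_tol:
            converged = True
            break
        if total_updates > max_updates:
            converged = False
            break
    for i in range(n):
        eta[i] = 0.0
    for c in range(m):
        bc = beta[c]
        if bc != 0.0:
            for i in range(n):
                eta[i] += V[i, c] * bc
    ll = cox_loglik_sorted(eta, ev, risk_start)
    return ll, it + 1, total_updates, converged


@njit(cache=True)
def _small_ll_grad_hess(Z, ev, risk_start, beta, grad, hess):
    """Log-likelihood, gradient and observed information for a d-column
    (d <= 3 in practice) sorted design."""
    n, d = Z.shape
    eta = np.empty(n)
    for i in range(n):
        acc = 0.0
        for c in range(d):
            acc += Z[i, c] * beta[c]
        eta[i] = acc
    shift = eta[0]
    for i in range(n):
        if eta[i] > shift:
            shift = eta[i]
    e = np.empty(n)
    for i in range(n):
        e[i] = np.exp(eta[i] - shift)
    # reverse cumulative sums of e, z e, z z' e
    s0 = np.empty(n)
    s1 = np.empty((n, d))
    s2 = np.empty((n, d, d))
    a0 = 0.0
    a1 = np.zeros(d)
    a2 = np.zeros((d, d))
    for i in range(n - 1, -1, -1):
        a0 += e[i]
        for c in range(d):
            a1[c] += Z[i, c] * e[i]
            for f in range(d):
                a2[c, f] += Z[i, c] * Z[i, f] * e[i]
        s0[i] = a0
        for c in range(d):
            s1[i, c] = a1[c]
            for f in range(d):
                s2[i, c, f] = a2[c, f]
    ll = 0.0
    for c in range(d):
        grad[c] = 0.0
        for f in range(d):
            hess[c, f] = 0.0
    for k in range(n):
        if ev[k] == 1:
            rs = risk_start[k]
            s = s0[rs]
            ll += eta[k] - shift - np.log(s)
            for c in range(d):
                zb = s1[rs, c] / s
                grad[c] += Z[k, c] - zb
                for f in range(d):
                    hess[c, f] += s2[rs, c, f] / s - zb * (s1[rs, f] / s)
    return ll


@njit(cache=True)
def newton_small_sorted(Z, ev, risk_start, tol, max_iter):
    """Damped Newton for a small sorted design.

    Returns ``(beta, ll, info, converged)``.  Flat directions leave the
    corresponding coefficient at 0 (singular Hessian -> tiny ridge jitter);
    diverging coefficients are clamped at +-50 and flagged.
    """
    n, d = Z.shape
    beta = np.zeros(d)
    grad = np.empty(d)
    hess = np.empty((d, d))
    ll = _small_ll_grad_hess(Z, ev, risk_start, beta, grad, hess)
    converged = False
    for _ in range(max_iter):
        # regularize singular information
        gnorm = 0.0
        for c in range(d):
            if abs(grad[c]) > gnorm:
                gnorm = abs(grad[c])
        hreg = hess.copy()
        for c in range(d):
            hreg[c, c] += 1e-10 * (1.0 + abs(hess[c, c]))
        step = np.linalg.solve(hreg, grad)
        new_beta = beta + step
        new_ll = _small_ll_grad_hess(Z, ev, risk_start, new_beta, grad, hess)
        halv = 0
        while (np.isnan(new_ll) or new_ll < ll) and halv < 20:
            step = step * 0.5
            new_beta = beta + step
            new_ll = _small_ll_grad_hess(Z, ev, risk_start, new_beta, grad, hess)
            halv += 1
        prev_ll = ll
        beta = new_beta
        ll = new_ll
        clipped = False
        for c in range(d):
            if beta[c] > COEF_CLAMP:
                beta[c] = COEF_CLAMP
                clipped = True
            elif beta[c] < -COEF_CLAMP:
                beta[c] = -COEF_CLAMP
                clipped = True
        if clipped:
            ll = _small_ll_grad_hess(Z, ev, risk_start, beta, grad, hess)
            break
        if abs(ll - prev_ll) < tol * (abs(prev_ll) + 1.0):
            converged = True
            break
    ll = _small_ll_grad_hess(Z, ev, risk_start, beta, grad, hess)
    return beta, ll, hess.copy(), converged


@njit(cache=True)
def sw_wald_batch(X, T, ev, risk_start, tol, max_iter):
    """Per-marker Wald chi-square of the univariable interaction-only model
    ``lambda0(t) exp(gamma_j X_j T)`` (no treatment main effect)."""
    n, p = X.shape
    W = np.zeros(p)
    Z = np.empty((n, 1))
    for j in range(p):
        for i in range(n):
            Z[i, 0] = X[i, j] * T[i]
        # flat column -> statistic 0 (weight capped upstream)
        lo = Z[0, 0]
        hi = Z[0, 0]
        for i in range(n):
            if Z[i, 0] < lo:
                lo = Z[i, 0]
            if Z[i, 0] > hi:
                hi = Z[i, 0]
        if hi - lo < 1e-12:
            W[j] = 0.0
            continue
        beta, ll, info, conv = newton_small_sorted(Z, ev, risk_start, tol, max_iter)
        if info[0, 0] > 0.0:
            W[j] = beta[0] * beta[0] * info[0, 0]
        else:
            W[j] = 0.0
    return W


@njit(cache=True)
def lrt_batch(X, T, ev, risk_start, tol, max_iter):
    """Per-marker likelihood-ratio statistics of M2 vs M0 and M2 vs M1.

    M0: treatment only (fitted once); M1: treatment + X_j;
    M2: treatment + X_j + X_j T.  Returns ``(lam20, lam21)``.
    """
    n, p = X.shape
    Z0 = np.empty((n, 1))
    for i in range(n):
        Z0[i, 0] = T[i]
    b0, ll0, info0, conv0 = newton_small_sorted(Z0, ev, risk_start, tol, max_iter)
    lam20 = np.zeros(p)
    lam21 = np.zeros(p)
    Z1 = np.empty((n, 2))
    Z2 = np.empty((n, 3))
    for j in range(p):
        for i in range(n):
            Z1[i, 0] = T[i]
            Z1[i, 1] = X[i, j]
            Z2[i, 0] = T[i]
            Z2[i, 1] = X[i, j]
            Z2[i, 2] = X[i, j] * T[i]
        b1, ll1, info1, c1 = newton_small_sorted(Z1, ev, risk_start, tol, max_iter)
        b2, ll2, info2, c2 = newton_small_sorted(Z2, ev, risk_start, tol, max_iter)
        l20 = 2.0 * (ll2 - ll0)
        l21 = 2.0 * (ll2 - ll1)
        lam20[j] = l20 if l20 > 0.0 else 0.0
        lam21[j] = l21 if l21 > 0.0 else 0.0
    return lam20, lam21
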