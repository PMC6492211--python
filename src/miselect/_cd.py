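"""Numba kernels: lasso-logistic coordinate descent and a dense Newton solver.

``cd_path`` solves the L1-penalized weighted logistic path by penalized
iteratively reweighted least squares: an outer quadratic approximation of
the weighted log-likelihood with cyclic coordinate descent and soft
thresholding on the inner weighted least-squares problem.  Inner iterations
cycle over the active set and admit violators through periodic full sweeps
(glmnet's scheme).  The kernel operates on the transposed standardized
covariate matrix (column-contiguous) with observation weights normalized to
mean 1; the intercept is unpenalized.  Standardization and
back-transformation live in ``lasso.py``.

``newton_logistic`` is a small dense Newton-Raphson with step halving used
by AIC backward elimination, where thousands of unpenalized fits are
needed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_EPS_MU = 1e-9
_EPS_V = 1e-9


@njit(cache=True, fastmath=True)
def _sweep(XT, v, r, beta, lam, xv, n, active_only, active):
    """One coordinate-descent sweep; returns the largest coefficient change."""
    p = beta.size
    maxdelta = 0.0
    for j in range(p):
        if active_only and not active[j]:
            continue
        xj = XT[j]
        g = 0.0
        for i in range(n):
            g += v[i] * xj[i] * r[i]
        g = g / n + xv[j] * beta[j]
        if g > lam:
            bj = (g - lam) / xv[j]
        elif g < -lam:
            bj = (g + lam) / xv[j]
        else:
            bj = 0.0
        d = bj - beta[j]
        if d != 0.0:
            for i in range(n):
                r[i] -= xj[i] * d
            beta[j] = bj
            active[j] = bj != 0.0
            ad = abs(d)
            if ad > maxdelta:
                maxdelta = ad
        elif bj == 0.0:
            active[j] = False
    return maxdelta


@njit(cache=True, fastmath=True)
def cd_path(XT, y, w, lambdas, tol, max_irls, max_cd):
    """Solve the lasso-logistic path on standardized data with warm starts.

    XT : (p, n) transposed standardized covariates; w : weights, mean 1;
    lambdas : strictly decreasing penalty grid.
    Returns (intercepts, coefs) on the standardized scale.
    """
    p, n = XT.shape
    nl = lambdas.size
    B = np.zeros((nl, p))
    B0 = np.zeros(nl)

    wsum = 0.0
    ybar = 0.0
    for i in range(n):
        wsum += w[i]
        ybar += w[i] * y[i]
    ybar /= wsum
    if ybar < _EPS_MU:
        ybar = _EPS_MU
    elif ybar > 1 - _EPS_MU:
        ybar = 1 - _EPS_MU

    beta = np.zeros(p)
    b0 = np.log(ybar / (1.0 - ybar))
    eta = np.full(n, b0)
    v = np.empty(n)
    z = np.empty(n)
    r = np.empty(n)  # working residual z - eta
    xv = np.empty(p)
    active = np.zeros(p, dtype=np.bool_)

    for li in range(nl):
        lam = lambdas[li]
        for _irls in range(max_irls):
            # quadratic approximation at the current (b0, beta)
            vsum = 0.0
            for i in range(n):
                e = eta[i]
                mu = 1.0 / (1.0 + np.exp(-e))
                if mu < _EPS_MU:
                    mu = _EPS_MU
                elif mu > 1 - _EPS_MU:
                    mu = 1 - _EPS_MU
                vi = w[i] * mu * (1.0 - mu)
                if vi < _EPS_V:
                    vi = _EPS_V
                v[i] = vi
                z[i] = e + w[i] * (y[i] - mu) / vi
                r[i] = z[i] - e
                vsum += vi
            for j in range(p):
                xj = XT[j]
                s = 0.0
                for i in range(n):
                    s += v[i] * xj[i] * xj[i]
                xv[j] = s / n

            outer_move = 0.0
            for _cd in range(max_cd):
                # full sweep admits violators into the active set
                maxdelta = _sweep(XT, v, r, beta, lam, xv, n, False, active)
                if maxdelta > outer_move:
                    outer_move = maxdelta
                g0 = 0.0
                for i in range(n):
                    g0 += v[i] * r[i]
                d0 = g0 / vsum
                if d0 != 0.0:
                    b0 += d0
                    for i in range(n):
                        r[i] -= d0
                    if abs(d0) > maxdelta:
                        maxdelta = abs(d0)
                    if abs(d0) > outer_move:
                        outer_move = abs(d0)
                if maxdelta < tol:
                    break
                # converge on the current active set
                for _a in range(max_cd):
                    md = _sweep(XT, v, r, beta, lam, xv, n, True, active)
                    g0 = 0.0
                    for i in range(n):
                        g0 += v[i] * r[i]
                    d0 = g0 / vsum
                    if d0 != 0.0:
                        b0 += d0
                        for i in range(n):
                            r[i] -= d0
                        if abs(d0) > md:
                            md = abs(d0)
                    if md > outer_move:
                        outer_move = md
                    if md < tol:
                        break
            # recover eta from the cached working response
            for i in range(n):
                eta[i] = z[i] - r[i]
            if outer_move < tol:
                break
        B0[li] = b0
        for j in range(p):
            B[li, j] = beta[j]
    return B0, B


@njit(cache=True, fastmath=True)
def newton_logistic(Z, y, w, max_iter, tol):
    """Weighted logistic Newton-Raphson with step halving.

    Z : (n, k) design including any intercept column.
    Returns (beta, loglik, converged flag, max |linear predictor|).
    """
    n, k = Z.shape
    beta = np.zeros(k)
    # start from the weighted-mean intercept if the first column is constant
    wsum = 0.0
    ybar = 0.0
    for i in range(n):
        wsum += w[i]
        ybar += w[i] * y[i]
    ybar /= wsum
    if ybar < _EPS_MU:
        ybar = _EPS_MU
    elif ybar > 1 - _EPS_MU:
        ybar = 1 - _EPS_MU
    const0 = True
    for i in range(n):
        if Z[i, 0] != 1.0:
            const0 = False
            break
    if const0:
        beta[0] = np.log(ybar / (1.0 - ybar))

    eta = Z @ beta
    ll = 0.0
    for i in range(n):
        e = eta[i]
        if e > 0:
            ll += w[i] * (y[i] * e - e - np.log(1.0 + np.exp(-e)))
        else:
            ll += w[i] * (y[i] * e - np.log(1.0 + np.exp(e)))

    converged = False
    for _it in range(max_iter):
        g = np.zeros(k)
        H = np.zeros((k, k))
        for i in range(n):
            mu = 1.0 / (1.0 + np.exp(-eta[i]))
            vi = w[i] * mu * (1.0 - mu)
            if vi < _EPS_V:
                vi = _EPS_V
            res = w[i] * (y[i] - mu)
            for a in range(k):
                g[a] += Z[i, a] * res
                za = Z[i, a] * vi
                for b in range(a, k):
                    H[a, b] += za * Z[i, b]
        for a in range(k):
            for b in range(a):
                H[a, b] = H[b, a]
        step = np.linalg.solve(H, g)
        t = 1.0
        accepted = False
        for _h in range(25):
            bn = beta + t * step
            etan = Z @ bn
            lln = 0.0
            for i in range(n):
                e = etan[i]
                if e > 0:
                    lln += w[i] * (y[i] * e - e - np.log(1.0 + np.exp(-e)))
                else:
                    lln += w[i] * (y[i] * e - np.log(1.0 + np.exp(e)))
            if lln >= ll - 1e-12:
                accepted = True
                break
            t *= 0.5
        if not accepted:
            break
        delta = 0.0
        for a in range(k):
            d = abs(bn[a] - beta[a])
            if d > delta:
                delta = d
        beta = bn
        eta = etan
        ll = lln
        if delta < tol:
            converged = True
            break

    maxeta = 0.0
    for i in range(n):
        a = abs(eta[i])
        if a > maxeta:
            maxeta = a
    return beta, ll, converged, maxeta
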