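"""Compiled EM kernels for normal and Weibull mixtures.

Each kernel runs EM on one dataset with explicit loops; batch drivers loop
over datasets.  numba JIT-compiles these to machine code (a requirement of
the package: bootstrap-LRT calibration runs hundreds of thousands of fits);
the module still imports without numba, falling back to the same Python
code, so single fits remain correct everywhere.

Conventions shared by all kernels:

* parameters are updated in place; the return is
  ``(loglik, n_iter, converged, degenerate)``;
* convergence: relative log-likelihood change < tol;
* degeneracy: component weight < 1e-4, or variance below the floor, or a
  Weibull shape at the clamp bounds;
* ``trace`` (length >= max_iter) receives the log-likelihood after every
  E-step; entries past ``n_iter`` are garbage.
"""

from __future__ import annotations

import numpy as np

_HALF_LOG_2PI = 0.9189385332046727
_WEIGHT_FLOOR = 1e-4
_SHAPE_LO = 1e-3
_SHAPE_HI = 1e3


def _em_normal(x, w, mu, sg, tol, max_iter, sd_floor, trace, resp):
    n = x.shape[0]
    K = w.shape[0]
    ll_old = -1.0e308
    ll = -1.0e308
    n_iter = 0
    converged = False
    degenerate = False
    var_floor = sd_floor * sd_floor
    for it in range(max_iter):
        # E-step
        ll = 0.0
        for i in range(n):
            m = -1.0e308
            for k in range(K):
                z = (x[i] - mu[k]) / sg[k]
                lp = -0.5 * z * z - np.log(sg[k]) - _HALF_LOG_2PI + np.log(w[k])
                resp[i, k] = lp
                if lp > m:
                    m = lp
            s = 0.0
            for k in range(K):
                s += np.exp(resp[i, k] - m)
            lse = m + np.log(s)
            ll += lse
            for k in range(K):
                resp[i, k] = np.exp(resp[i, k] - lse)
        trace[it] = ll
        n_iter = it + 1
        if not np.isfinite(ll):
            degenerate = True
            break
        if abs(ll - ll_old) < tol * (abs(ll) + 1e-10):
            converged = True
            break
        ll_old = ll
        # M-step
        for k in range(K):
            Nk = 0.0
            s1 = 0.0
            for i in range(n):
                Nk += resp[i, k]
                s1 += resp[i, k] * x[i]
            if Nk <= n * _WEIGHT_FLOOR:
                degenerate = True
                break
            muk = s1 / Nk
            s2 = 0.0
            for i in range(n):
                d = x[i] - muk
                s2 += resp[i, k] * d * d
            var = s2 / Nk
            if var < var_floor:
                degenerate = True
            w[k] = Nk / n
            mu[k] = muk
            sg[k] = np.sqrt(max(var, var_floor))
        if degenerate:
            break
    return ll, n_iter, converged, degenerate


def _weibull_shape_newton(x, lx, resp, k_col, shape0):
    """Weighted-MLE shape for one component; x must be pre-normalized <= 1."""
    n = x.shape[0]
    k = shape0
    for _ in range(60):
        T0 = 0.0
        T1 = 0.0
        T2 = 0.0
        W = 0.0
        L = 0.0
        for i in range(n):
            r = resp[i, k_col]
            xk = np.exp(k * lx[i])
            T0 += r * xk
            T1 += r * xk * lx[i]
            T2 += r * xk * lx[i] * lx[i]
            W += r
            L += r * lx[i]
        if T0 <= 0.0 or W <= 0.0:
            return -1.0, -1.0  # degenerate
        g = T1 / T0 - 1.0 / k - L / W
        dg = (T2 * T0 - T1 * T1) / (T0 * T0) + 1.0 / (k * k)
        if dg <= 0.0 or not np.isfinite(dg) or not np.isfinite(g):
            return -1.0, -1.0  # degenerate
        step = g / dg
        k_new = k - step
        if k_new < _SHAPE_LO:
            k_new = _SHAPE_LO
        elif k_new > _SHAPE_HI:
            k_new = _SHAPE_HI
        done = abs(g) < 1e-11
        k = k_new
        if done:
            break
    # profiled-out scale
    T0 = 0.0
    W = 0.0
    for i in range(n):
        r = resp[i, k_col]
        T0 += r * np.exp(k * lx[i])
        W += r
    scale = (T0 / W) ** (1.0 / k)
    return k, scale


def _em_weibull(x, lx, w, sh, sc, tol, max_iter, sd_floor, trace, resp):
    """EM for a Weibull mixture; x must be pre-normalized by its max."""
    n = x.shape[0]
    K = w.shape[0]
    ll_old = -1.0e308
    ll = -1.0e308
    n_iter = 0
    converged = False
    degenerate = False
    for it in range(max_iter):
        # E-step
        ll = 0.0
        for i in range(n):
            m = -1.0e308
            for k in range(K):
                t = sh[k] * (lx[i] - np.log(sc[k]))
                if t > 700.0:
                    t = 700.0
                lp = (
                    np.log(sh[k])
                    - np.log(sc[k])
                    + (sh[k] - 1.0) * (lx[i] - np.log(sc[k]))
                    - np.exp(t)
                    + np.log(w[k])
                )
                resp[i, k] = lp
                if lp > m:
                    m = lp
            s = 0.0
            for k in range(K):
                s += np.exp(resp[i, k] - m)
            lse = m + np.log(s)
            ll += lse
            for k in range(K):
                resp[i, k] = np.exp(resp[i, k] - lse)
        trace[it] = ll
        n_iter = it + 1
        if not np.isfinite(ll):
            degenerate = True
            break
        if abs(ll - ll_old) < tol * (abs(ll) + 1e-10):
            converged = True
            break
        ll_old = ll
        # M-step: weighted Weibull MLE per component, warm-started Newton
        for k in range(K):
            Nk = 0.0
            mu_k = 0.0
            for i in range(n):
                Nk += resp[i, k]
                mu_k += resp[i, k] * x[i]
            if Nk <= n * _WEIGHT_FLOOR:
                degenerate = True
                break
            mu_k /= Nk
            s2 = 0.0
            for i in range(n):
                d = x[i] - mu_k
                s2 += resp[i, k] * d * d
            sd_k = np.sqrt(s2 / Nk)
            if sd_k < sd_floor:
                degenerate = True
                break
            shape_new, scale_new = _weibull_shape_newton(x, lx, resp, k, sh[k])
            if shape_new < 0.0 or not np.isfinite(scale_new):
                degenerate = True
                break
            if shape_new <= _SHAPE_LO or shape_new >= _SHAPE_HI:
                degenerate = True
            w[k] = Nk / n
            sh[k] = shape_new
            sc[k] = scale_new
        if degenerate:
            break
    return ll, n_iter, converged, degenerate


def _fit1_weibull(x, lx, out):
    """Single-component Weibull MLE (x pre-normalized); fills out=(shape,scale,ll)."""
    n = x.shape[0]
    resp = np.ones((n, 1))
    mu = 0.0
    for i in range(n):
        mu += x[i]
    mu /= n
    s2 = 0.0
    for i in range(n):
        s2 += (x[i] - mu) * (x[i] - mu)
    sd = np.sqrt(s2 / n)
    cv = sd / mu
    k0 = cv**-1.086
    if k0 < 5e-2:
        k0 = 5e-2
    elif k0 > 5e2:
        k0 = 5e2
    shape, scale = _weibull_shape_newton(x, lx, resp, 0, k0)
    ll = 0.0
    lsc = np.log(scale)
    for i in range(n):
        t = shape * (lx[i] - lsc)
        if t > 700.0:
            t = 700.0
        ll += np.log(shape) - lsc + (shape - 1.0) * (lx[i] - lsc) - np.exp(t)
    out[0] = shape
    out[1] = scale
    out[2] = ll


def _em_normal_batch(X, W, MU, SG, tol, max_iter, sd_floors):
    B, n = X.shape
    K = W.shape[1]
    LL = np.empty(B)
    NIT = np.empty(B, dtype=np.int64)
    CONV = np.zeros(B, dtype=np.bool_)
    DEG = np.zeros(B, dtype=np.bool_)
    trace = np.empty(max_iter)
    resp = np.empty((n, K))
    for b in range(B):
        ll, nit, conv, deg = _em_normal(
            X[b], W[b], MU[b], SG[b], tol, max_iter, sd_floors[b], trace, resp
        )
        LL[b] = ll
        NIT[b] = nit
        CONV[b] = conv
        DEG[b] = deg
    return LL, NIT, CONV, DEG


def _em_weibull_batch(X, LX, W, SH, SC, tol, max_iter, sd_floors):
    B, n = X.shape
    K = W.shape[1]
    LL = np.empty(B)
    NIT = np.empty(B, dtype=np.int64)
    CONV = np.zeros(B, dtype=np.bool_)
    DEG = np.zeros(B, dtype=np.bool_)
    trace = np.empty(max_iter)
    resp = np.empty((n, K))
    for b in range(B):
        ll, nit, conv, deg = _em_weibull(
            X[b], LX[b], W[b], SH[b], SC[b], tol, max_iter, sd_floors[b],
            trace, resp,
        )
        LL[b] = ll
        NIT[b] = nit
        CONV[b] = conv
        DEG[b] = deg
    return LL, NIT, CONV, DEG


def _fit1_weibull_batch(X, LX):
    B = X.shape[0]
    OUT = np.empty((B, 3))
    for b in range(B):
        _fit1_weibull(X[b], LX[b], OUT[b])
    return OUT


try:  # pragma: no cover
    from numba import njit

    _weibull_shape_newton = njit(cache=True, error_model="numpy")(_weibull_shape_newton)

    def _rebind(fn):
        # re-evaluate the function body so inner calls resolve to jitted names
        return njit(cache=True, error_model="numpy")(fn)

    em_normal = _rebind(_em_normal)
    em_weibull = _rebind(_em_weibull)
    fit1_weibull = _rebind(_fit1_weibull)

    @njit(cache=True, error_model="numpy")
    def em_normal_batch(X, W, MU, SG, tol, max_iter, sd_floors):
        B, n = X.shape
        K = W.shape[1]
        LL = np.empty(B)
        NIT = np.empty(B, dtype=np.int64)
        CONV = np.zeros(B, dtype=np.bool_)
        DEG = np.zeros(B, dtype=np.bool_)
        trace = np.empty(max_iter)
        resp = np.empty((n, K))
        for b in range(B):
            ll, nit, conv, deg = em_normal(
                X[b], W[b], MU[b], SG[b], tol, max_iter, sd_floors[b], trace, resp
            )
            LL[b] = ll
            NIT[b] = nit
            CONV[b] = conv
            DEG[b] = deg
        return LL, NIT, CONV, DEG

    @njit(cache=True, error_model="numpy")
    def em_weibull_batch(X, LX, W, SH, SC, tol, max_iter, sd_floors):
        B, n = X.shape
        K = W.shape[1]
        LL = np.empty(B)
        NIT = np.empty(B, dtype=np.int64)
        CONV = np.zeros(B, dtype=np.bool_)
        DEG = np.zeros(B, dtype=np.bool_)
        trace = np.empty(max_iter)
        resp = np.empty((n, K))
        for b in range(B):
            ll, nit, conv, deg = em_weibull(
                X[b], LX[b], W[b], SH[b], SC[b], tol, max_iter, sd_floors[b],
                trace, resp,
            )
            LL[b] = ll
            NIT[b] = nit
            CONV[b] = conv
            DEG[b] = deg
        return LL, NIT, CONV, DEG

    @njit(cache=True, error_model="numpy")
    def fit1_weibull_batch(X, LX):
        B = X.shape[0]
        OUT = np.empty((B, 3))
        for b in range(B):
            fit1_weibull(X[b], LX[b], OUT[b])
        return OUT

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    em_normal = _em_normal
    em_weibull = _em_weibull
    fit1_weibull = _fit1_weibull
    em_normal_batch = _em_normal_batch
    em_weibull_batch = _em_weibull_batch
    fit1_weibull_batch = _fit1_weibull_batch
    HAVE_NUMBA = False
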