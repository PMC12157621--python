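"""Hartigan & Hartigan dip statistic.

The dip of an empirical CDF is the smallest sup-norm distance to any unimodal
CDF.  It is computed by the classical iterative algorithm: fit the greatest
convex minorant (GCM) and least concave majorant (LCM) of the ECDF on a
candidate modal interval, locate their largest discrepancy, tighten the
interval, and repeat.  Internally the deviation is tracked in counts (2n x
dip); the modern convention with lower bound 1/(2n) is used.

The inner loop is plain index arithmetic, so it is JIT-compiled with numba
when available (a pure-Python fallback keeps the package importable without
it).
"""

from __future__ import annotations

import numpy as np

__all__ = ["dip_sorted", "dip_batch_sorted", "HAVE_NUMBA"]


def _dip_sorted_impl(xs):
    """Dip of a sorted 1-d float64 sample (modern 1/(2n) convention)."""
    n = xs.shape[0]
    # 1-based work arrays, translated from the published algorithm
    x = np.empty(n + 1, dtype=np.float64)
    x[1:] = xs
    dip = 1.0
    if n < 2 or x[n] == x[1]:
        return dip / (2.0 * n)

    mn = np.empty(n + 1, dtype=np.int64)
    mj = np.empty(n + 1, dtype=np.int64)
    gcm = np.empty(n + 1, dtype=np.int64)
    lcm = np.empty(n + 1, dtype=np.int64)

    mn[1] = 1
    for j in range(2, n + 1):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            mnmnj = mn[mnj]
            if mnj == 1 or (x[j] - x[mnj]) * (mnj - mnmnj) < (
                x[mnj] - x[mnmnj]
            ) * (j - mnj):
                break
            mn[j] = mnmnj
    mj[n] = n
    for k in range(n - 1, 0, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            mjmjk = mj[mjk]
            if mjk == n or (x[k] - x[mjk]) * (mjk - mjmjk) < (
                x[mjk] - x[mjmjk]
            ) * (k - mjk):
                break
            mj[k] = mjmjk

    low = 1
    high = n
    while True:
        # GCM change points from high down to low
        gcm[1] = high
        ic = 1
        while gcm[ic] > low:
            gcm[ic + 1] = mn[gcm[ic]]
            ic += 1
        ig = ic
        l_gcm = ic
        ix = ig - 1
        # LCM change points from low up to high
        lcm[1] = low
        ic = 1
        while lcm[ic] < high:
            lcm[ic + 1] = mj[lcm[ic]]
            ic += 1
        ih = ic
        l_lcm = ic
        iv = 2

        d = 0.0
        if l_gcm != 2 or l_lcm != 2:
            while True:
                gcm_ix = gcm[ix]
                lcm_iv = lcm[iv]
                if gcm_ix > lcm_iv:
                    # the next point along the interval is an LCM vertex
                    gcm_i1 = gcm[ix + 1]
                    dx = (lcm_iv - gcm_i1 + 1) - (x[lcm_iv] - x[gcm_i1]) * (
                        gcm_ix - gcm_i1
                    ) / (x[gcm_ix] - x[gcm_i1])
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    # the next point along the interval is a GCM vertex
                    lcm_i1 = lcm[iv - 1]
                    dx = (x[gcm_ix] - x[lcm_i1]) * (lcm_iv - lcm_i1) / (
                        x[lcm_iv] - x[lcm_i1]
                    ) - (gcm_ix - lcm_i1 - 1)
                    ix -= 1
                    if dx > d:
                        d = dx
                        ig = ix + 1
                        ih = iv
                if ix < 1:
                    ix = 1
                if iv > l_lcm:
                    iv = l_lcm
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0

        if d < dip:
            break

        # largest ECDF deviation below the GCM over [low, gcm[ig]]
        dip_l = 0.0
        for j in range(ig, l_gcm):
            max_t = 1.0
            jb = gcm[j + 1]
            je = gcm[j]
            if je - jb > 1 and x[je] != x[jb]:
                C = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (x[jj] - x[jb]) * C
                    if max_t < t:
                        max_t = t
            if dip_l < max_t:
                dip_l = max_t

        # largest ECDF deviation above the LCM over [lcm[ih], high]
        dip_u = 0.0
        for j in range(ih, l_lcm):
            max_t = 1.0
            jb = lcm[j]
            je = lcm[j + 1]
            if je - jb > 1 and x[je] != x[jb]:
                C = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (x[jj] - x[jb]) * C - (jj - jb - 1)
                    if max_t < t:
                        max_t = t
            if dip_u < max_t:
                dip_u = max_t

        dipnew = dip_u if dip_u > dip_l else dip_l
        if dip < dipnew:
            dip = dipnew

        if low == gcm[ig] and high == lcm[ih]:
            break
        low = gcm[ig]
        high = lcm[ih]

    return dip / (2.0 * n)


def _dip_batch_impl(X):
    """Dip of every row of a row-sorted (B, n) array."""
    B = X.shape[0]
    out = np.empty(B, dtype=np.float64)
    for b in range(B):
        out[b] = _dip_sorted_impl(X[b])
    return out


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    dip_sorted = njit(cache=True)(_dip_sorted_impl)

    @njit(cache=True)
    def _dip_batch_jit(X):
        B = X.shape[0]
        out = np.empty(B, dtype=np.float64)
        for b in range(B):
            out[b] = dip_sorted(X[b])
        return out

    def dip_batch_sorted(X):
        return _dip_batch_jit(np.ascontiguousarray(X, dtype=np.float64))

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    dip_sorted = _dip_sorted_impl
    dip_batch_sorted = _dip_batch_impl
    HAVE_NUMBA = False
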