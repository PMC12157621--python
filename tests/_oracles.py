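"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they validate: pairwise sums instead
of sorted-order identities, sup over pooled breakpoints instead of scipy, an
LP over unimodal piecewise-linear CDFs instead of the iterative dip
algorithm, and a literal step-up loop for Benjamini-Hochberg.
"""

import numpy as np
from scipy.optimize import linprog


def gmd_bruteforce(x):
    """Gini mean difference by explicit O(n^2) pairwise enumeration."""
    x = np.asarray(x, dtype=float)
    n = x.size
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            total += abs(x[i] - x[j])
    return 2.0 * total / (n * (n - 1))


def ks_bruteforce(x, y):
    """Two-sample KS statistic as the sup of |F1-F2| over pooled points."""
    x, y = np.sort(x), np.sort(y)
    pooled = np.concatenate([x, y])
    f1 = np.searchsorted(x, pooled, side="right") / x.size
    f2 = np.searchsorted(y, pooled, side="right") / y.size
    return float(np.max(np.abs(f1 - f2)))


def bh_stepup_byhand(pvals):
    """Benjamini-Hochberg step-up, written as the textbook loop."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        val = p[idx] * m / rank_from_top
        running_min = min(running_min, val)
        adj[idx] = min(running_min, 1.0)
    return adj


def dip_lp_oracle(x):
    """Exact dip via LP: min over unimodal CDFs of sup |ECDF - G|.

    One LP per candidate mode knot; G is piecewise linear on the unique data
    points plus far-away virtual end knots, with an optional atom (jump) at
    the mode — the unimodal class admits one.  Exact for small n; used for
    n <= ~25.
    """
    x = np.sort(np.asarray(x, float))
    n = x.size
    rng_ = np.ptp(x)
    if rng_ == 0:
        return 1.0 / (2.0 * n)
    u, first = np.unique(x, return_index=True)
    last = np.concatenate([first[1:], [n]]) - 1
    m = u.size
    delta = 1e6 * rng_
    pos = np.concatenate([[u[0] - delta], u, [u[-1] + delta]])
    dx = np.diff(pos)

    nv = m + 4  # g_0..g_{m+1}, gR, d
    R, D = m + 2, m + 3
    c = np.zeros(nv)
    c[D] = 1.0
    bounds = [(0.0, 1.0)] * (m + 2) + [(0.0, 1.0), (0.0, 1.0)]

    best = np.inf
    for j in range(1, m + 1):  # mode at knot j
        A, b = [], []

        def lhs(i):
            return R if i == j else i

        def seg_coeff(i):
            row = np.zeros(nv)
            row[lhs(i)] += -1.0 / dx[i]
            row[i + 1] += 1.0 / dx[i]
            return row

        for i in range(1, m + 1):
            lo_rhs = (last[i - 1] + 1) / n
            hi_rhs = first[i - 1] / n
            r = np.zeros(nv)
            r[R if i == j else i] = -1.0
            r[D] = -1.0
            A.append(r)
            b.append(-lo_rhs)
            r = np.zeros(nv)
            r[i] = 1.0
            r[D] = -1.0
            A.append(r)
            b.append(hi_rhs)
        r = np.zeros(nv)
        r[0] = 1.0
        r[D] = -1.0
        A.append(r)
        b.append(0.0)
        r = np.zeros(nv)
        r[m + 1] = -1.0
        r[D] = -1.0
        A.append(r)
        b.append(-1.0)
        for i in range(m + 1):
            if i == j:
                continue
            r = np.zeros(nv)
            r[i] = 1.0
            r[i + 1] = -1.0
            A.append(r)
            b.append(0.0)
        r = np.zeros(nv)
        r[j] = 1.0
        r[R] = -1.0
        A.append(r)
        b.append(0.0)
        r = np.zeros(nv)
        r[R] = 1.0
        r[j + 1] = -1.0
        A.append(r)
        b.append(0.0)
        for i in range(j - 1):
            A.append(seg_coeff(i) - seg_coeff(i + 1))
            b.append(0.0)
        for i in range(j, m):
            A.append(seg_coeff(i + 1) - seg_coeff(i))
            b.append(0.0)
        res = linprog(
            c, A_ub=np.array(A), b_ub=np.array(b), bounds=bounds, method="highs"
        )
        if res.status == 0:
            best = min(best, res.fun)
    return best
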