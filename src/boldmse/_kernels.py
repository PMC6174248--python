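"""Numba-compiled inner loops for sample-entropy template counting.

All kernels count *unordered* template pairs (i < j); callers double the
counts to obtain the ordered-pair convention used throughout the package.
Matching uses the Chebyshev (max-norm) distance with an inclusive boundary:
a componentwise difference exactly equal to the radius counts as a match.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["pair_counts", "pair_counts_map", "pair_counts_grid"]


@njit(cache=True)
def pair_counts(x, m, r):
    """Unordered (A, B) template-match counts for one series.

    Templates start at i = 0 .. n-m-1 for BOTH lengths m and m+1, so the
    two counts range over the same pair set and A <= B by construction.
    """
    n = x.size
    nt = n - m
    a = 0
    b = 0
    for i in range(nt):
        for j in range(i + 1, nt):
            ok = True
            for k in range(m):
                if abs(x[i + k] - x[j + k]) > r:
                    ok = False
                    break
            if ok:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    return a, b


@njit(cache=True)
def pair_counts_map(X, m, r):
    """Row-wise pair_counts over a (n_series, n_samples) matrix."""
    nv = X.shape[0]
    A = np.empty(nv, np.int64)
    B = np.empty(nv, np.int64)
    for v in range(nv):
        a, b = pair_counts(X[v], m, r)
        A[v] = a
        B[v] = b
    return A, B


@njit(cache=True)
def pair_counts_grid(x, rs):
    """Counts for m in {1, 2} across an ascending radius grid, one pass.

    Returns (b1, a1, b2, a2), each of shape (len(rs),): unordered B/A
    counts for m = 1 and m = 2. A single sweep over sample pairs serves
    every (m, r) combination, which matters at n ~ 1e5 where the pair
    loop is O(n^2).
    """
    n = x.size
    nr = rs.size
    rmax = rs[nr - 1]
    hb1 = np.zeros(nr + 1, np.int64)
    ha1 = np.zeros(nr + 1, np.int64)
    hb2 = np.zeros(nr + 1, np.int64)
    ha2 = np.zeros(nr + 1, np.int64)
    last1 = n - 2  # last 0-based template start for m = 1
    last2 = n - 3
    for i in range(last1 + 1):
        xi = x[i]
        for j in range(i + 1, last1 + 1):
            d1 = abs(xi - x[j])
            if d1 > rmax:
                continue
            d2 = abs(x[i + 1] - x[j + 1])
            m2 = d1 if d1 > d2 else d2
            # histogram slot = index of smallest radius >= distance
            t = 0
            while t < nr and rs[t] < d1:
                t += 1
            hb1[t] += 1
            t2 = 0
            while t2 < nr and rs[t2] < m2:
                t2 += 1
            ha1[t2] += 1
            if i <= last2 and j <= last2:
                hb2[t2] += 1
                if m2 <= rmax:
                    d3 = abs(x[i + 2] - x[j + 2])
                    m3 = m2 if m2 > d3 else d3
                    t3 = 0
                    while t3 < nr and rs[t3] < m3:
                        t3 += 1
                    ha2[t3] += 1
    b1 = np.cumsum(hb1[:nr])
    a1 = np.cumsum(ha1[:nr])
    b2 = np.cumsum(hb2[:nr])
    a2 = np.cumsum(ha2[:nr])
    return b1, a1, b2, a2
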