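"""Brute-force dip oracle for small samples.

The dip of an ECDF F_n is the smallest d such that some nondecreasing,
convex-then-concave function G fits inside the band [F_n - d, F_n + d].
At the data points this reduces to g_i in [i/n - d, (i-1)/n + d]; for each
placement of the mode the convexity/concavity pattern is a linear
feasibility problem.  Binary search on d with an LP feasibility check per
mode placement gives the dip to tolerance, independent of the fast
greatest-convex-minorant algorithm it cross-checks.
"""

import numpy as np
from scipy.optimize import linprog


def _collapse(x, lo, hi):
    # a single G value applies at tied x: intersect their bands
    xs, los, his = [], [], []
    i = 0
    while i < x.size:
        j = i
        while j + 1 < x.size and x[j + 1] == x[i]:
            j += 1
        xs.append(x[i]); los.append(lo[i:j+1].max()); his.append(hi[i:j+1].min())
        i = j + 1
    return np.array(xs), np.array(los), np.array(his)


def _feasible(x, d):
    n0 = x.size
    lo = np.maximum(np.arange(1, n0 + 1) / n0 - d, 0.0)
    hi = np.minimum(np.arange(0, n0) / n0 + d, 1.0)
    x, lo, hi = _collapse(x, lo, hi)
    n = x.size
    if np.any(lo > hi + 1e-12):
        return False
    dx = np.diff(x)
    for m in range(0, n + 1):
        # convex on points 1..m, concave on points m+1..n (1-based)
        a_ub, b_ub = [], []
        for i in range(1, n):       # monotone: g_i <= g_{i+1}
            row = np.zeros(n)
            row[i - 1], row[i] = 1.0, -1.0
            a_ub.append(row)
            b_ub.append(0.0)
        for i in range(1, n - 1):   # interior triple (i-1, i, i+1), 0-based
            if dx[i - 1] <= 0 or dx[i] <= 0:
                continue
            row = np.zeros(n)
            # slope_right - slope_left of triple centered at i
            row[i + 1] = 1.0 / dx[i]
            row[i] = -1.0 / dx[i] - 1.0 / dx[i - 1]
            row[i - 1] = 1.0 / dx[i - 1]
            if i + 1 < m:           # triple fully inside convex range
                a_ub.append(-row)   # require >= 0
                b_ub.append(0.0)
            elif i - 1 >= m:        # fully inside concave range (0-based m)
                a_ub.append(row)    # require <= 0
                b_ub.append(0.0)
        res = linprog(np.zeros(n), A_ub=np.array(a_ub), b_ub=np.array(b_ub),
                      bounds=list(zip(lo, hi)), method="highs")
        if res.status == 0:
            return True
    return False


def dip_bruteforce(x, tol=1e-7):
    x = np.sort(np.asarray(x, float))
    n = x.size
    lo, hi = 1.0 / (2 * n) - tol, 0.5
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _feasible(x, mid):
            hi = mid
        else:
            lo = mid
    return hi
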