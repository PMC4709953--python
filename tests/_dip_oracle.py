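"""Exact linear-programming oracle for Hartigan's dip statistic.

Independent of the production implementation: directly encodes the
definition of the dip as the smallest half-width D such that a unimodal
CDF fits in the band ECDF +/- D.  For each candidate mode position the
feasibility of a convex branch (left) and concave branch (right) within
the band, joined monotonically with a jump allowed at the mode, is an LP
in the branch values and D; the dip is the minimum over mode positions.
Only suitable for small n.
"""

import numpy as np
from scipy.optimize import linprog


def dip_lp(x: np.ndarray) -> float:
    x = np.sort(np.asarray(x, dtype=float).ravel())
    n = len(x)
    v, counts = np.unique(x, return_counts=True)
    m = len(v)
    if m == 1:
        return 0.0
    cum = np.cumsum(counts) / n
    loF = cum                  # ECDF at the top of each jump
    hiF = cum - counts / n     # ECDF just below each jump
    best = np.inf
    for s in range(m + 1):
        # variables: branch values g_0..g_{m-1} (convex for j < s, concave
        # for j >= s) and D at index m
        nv = m + 1
        iD = m
        rows, rhs = [], []

        def row(pairs, b):
            r = np.zeros(nv)
            for idx, c in pairs:
                r[idx] = c
            rows.append(r)
            rhs.append(b)

        for j in range(m):
            row([(j, -1.0), (iD, -1.0)], -loF[j])          # g_j >= loF - D
            if j < s:
                row([(j, 1.0), (iD, -1.0)], hiF[j])        # g_j <= hiF + D
            else:
                # first concave point: CDF may jump at the mode itself
                row([(j, 1.0), (iD, -1.0)], loF[j] if j == s else hiF[j])
        for j in range(m - 1):                              # monotone
            row([(j, 1.0), (j + 1, -1.0)], 0.0)
        for j in range(s - 2):                              # convex branch
            d1 = v[j + 1] - v[j]
            d2 = v[j + 2] - v[j + 1]
            row([(j, -1.0 / d1), (j + 1, 1.0 / d1 + 1.0 / d2), (j + 2, -1.0 / d2)], 0.0)
        for j in range(s, m - 2):                           # concave branch
            d1 = v[j + 1] - v[j]
            d2 = v[j + 2] - v[j + 1]
            row([(j, 1.0 / d1), (j + 1, -1.0 / d1 - 1.0 / d2), (j + 2, 1.0 / d2)], 0.0)
        c = np.zeros(nv)
        c[iD] = 1.0
        # branch values are CDF values, hence within [0, 1]
        res = linprog(c, A_ub=np.array(rows), b_ub=np.array(rhs),
                      bounds=[(0, 1)] * m + [(0, None)], method="highs")
        if res.status == 0 and res.fun < best:
            best = res.fun
    return float(best)
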