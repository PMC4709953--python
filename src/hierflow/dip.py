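"""Hartigan's dip statistic and bootstrap test of unimodality.

The dip of an empirical CDF F_n is the smallest half-width D such that some
unimodal CDF G — convex below its mode, concave above, nondecreasing in
[0, 1], with a jump allowed only at the mode — stays within a vertical band
of +/- D around F_n.

The statistic is computed by bisection on D with an exact feasibility check
per level.  For a candidate mode position between order statistics, the
convex branch must fit the band over the left prefix and the concave branch
over the right suffix, and the branch end values must connect monotonically
(the CDF may jump upward at the mode, so the convex end only needs to stay
below the concave start).  Three facts make the check linear-time per
sweep:

* a convex branch fits iff the greatest convex minorant of the upper band
  edge dominates the lower edge (checked incrementally for every prefix);
* the smallest achievable convex-branch end value is
  ``max_j [lo_j + M_j (x_s - x_j)]`` where ``M_j`` is the running maximum
  of pairwise slopes ``(lo_j' - hi_i) / (x_j' - x_i)`` — a tangent query
  against the hull of upper-edge anchors plus a monotone upper envelope of
  lines;
* the concave side is the mirror image (negate and reverse), with the band
  of its first point relaxed because the CDF may jump at the mode itself.

An independent linear-programming oracle for the same definition lives in
the test suite.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = ["dip_statistic", "dip_test"]

_EPS = 1e-12


def _sweep(u, lo_now, lo_later, hi):
    """Prefix feasibility and minimal convex-branch end value.

    Points (u_j, *) with u increasing.  A convex nondecreasing chain g must
    satisfy ``lo_later_j <= g_j <= hi_j`` for interior points while the most
    recently added point only needs ``lo_now_j`` (the CDF may jump at the
    mode, which is the branch end).  Returns ``ok[s]`` (a chain exists for
    the prefix of length s) and ``gmin[s]`` (smallest achievable end value).
    """
    m = u.shape[0]
    ok = np.ones(m + 1, np.bool_)
    gmin = np.zeros(m + 1)
    hull = np.empty(m + 1, np.int64)     # lower convex hull of (u, hi)
    nh = 0
    # monotone upper envelope of lines y = slope*x + icept (slopes nondecr.)
    ls = np.empty(m + 1)
    li = np.empty(m + 1)
    lhead = 0
    ltail = 0
    M = 0.0          # running max of pairwise slope lower bounds
    viol = False
    for i in range(m):
        # the previous point is no longer the branch end: its interior band
        # must hold (hull value at a knot equals hi, so hi is the bound)
        if i > 0 and lo_later[i - 1] > hi[i - 1] + _EPS:
            viol = True
        # tangent query: steepest slope from earlier upper-edge anchors to
        # (u_i, lo_later_i); anchor set is the current hull
        if nh > 0:
            a = 0
            b = nh - 1
            while a < b:
                mid = (a + b) // 2
                p = hull[mid]
                q = hull[mid + 1]
                s1 = (lo_later[i] - hi[p]) / (u[i] - u[p])
                s2 = (lo_later[i] - hi[q]) / (u[i] - u[q])
                if s2 >= s1:
                    a = mid + 1
                else:
                    b = mid
            p = hull[a]
            sl = (lo_later[i] - hi[p]) / (u[i] - u[p])
            if sl > M:
                M = sl
        # newest-point band check
        if lo_now[i] > hi[i] + _EPS:
            viol = True
        # add (u_i, hi_i) to the hull; rescan interior points under the new
        # final segment against their (interior) lower edges
        while nh >= 2:
            a = hull[nh - 2]
            b = hull[nh - 1]
            if (hi[b] - hi[a]) * (u[i] - u[a]) <= (hi[i] - hi[a]) * (u[b] - u[a]) + _EPS:
                break
            nh -= 1
        if nh >= 1 and not viol:
            a = hull[nh - 1]
            if u[i] > u[a]:
                slope = (hi[i] - hi[a]) / (u[i] - u[a])
                for j in range(a + 1, i):
                    g = hi[a] + slope * (u[j] - u[a])
                    if lo_later[j] > g + _EPS:
                        viol = True
                        break
        hull[nh] = i
        nh += 1
        ok[i + 1] = not viol
        # minimal end value: envelope of earlier lines, then own band floor
        best = lo_now[i]
        while lhead + 1 < ltail and (ls[lhead + 1] * u[i] + li[lhead + 1]
                                     >= ls[lhead] * u[i] + li[lhead]):
            lhead += 1
        if lhead < ltail:
            e = ls[lhead] * u[i] + li[lhead]
            if e > best:
                best = e
        gmin[i + 1] = best
        # append this point's line (slope M, passing through (u_i, lo_later_i))
        icept = lo_later[i] - M * u[i]
        push = True
        if ltail - lhead >= 1 and M - ls[ltail - 1] < 1e-15:
            # equal slopes: keep only the higher line
            if li[ltail - 1] >= icept:
                push = False
            else:
                ltail -= 1
        if push:
            while ltail - lhead >= 2:
                # drop the previous line if the new one overtakes it no
                # later than where it overtook its own predecessor
                x1 = (li[ltail - 1] - li[ltail - 2]) / (ls[ltail - 2] - ls[ltail - 1])
                x2 = (icept - li[ltail - 1]) / (ls[ltail - 1] - M)
                if x2 > x1:
                    break
                ltail -= 1
            ls[ltail] = M
            li[ltail] = icept
            ltail += 1
    return ok, gmin


def _feasible(v, loF, hiF, D):
    """Does some unimodal CDF fit within +/- D of the ECDF (v, loF, hiF)?"""
    m = v.shape[0]
    lo = np.maximum(loF - D, 0.0)
    hi = np.minimum(hiF + D, 1.0)
    okL, gmin = _sweep(v, lo, lo, hi)
    # mirrored problem for the concave side: g'(u) = -h(-x)
    ur = (-v)[::-1].copy()
    mhi = (-lo)[::-1].copy()                       # mirrored upper edge
    mlo_later = (-hi)[::-1].copy()                 # mirrored lower edge
    mlo_now = (-np.minimum(loF + D, 1.0))[::-1].copy()   # jump at the mode
    okR, gminR = _sweep(ur, mlo_now, mlo_later, mhi)
    for s in range(m + 1):
        if not okL[s] or not okR[m - s]:
            continue
        if s == m:
            if gmin[m] <= 1.0 + _EPS:
                return True
            continue
        hmax = -gminR[m - s]
        if gmin[s] <= hmax + _EPS:
            return True
    return False


def _dip_band(v, loF, hiF):
    lo = 0.0
    hi = 0.2500000001
    while hi - lo > 1e-11:
        mid = 0.5 * (lo + hi)
        if _feasible(v, loF, hiF, mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


try:  # numba gives a large speedup on the bootstrap loop; python is the fallback
    from numba import njit as _njit

    _sweep = _njit(cache=False)(_sweep)
    _feasible = _njit(cache=False)(_feasible)
    _dip_band = _njit(cache=False)(_dip_band)
except ImportError:  # pragma: no cover - numba is an optional speedup
    pass


def dip_statistic(values: np.ndarray) -> float:
    """Hartigan's dip statistic of a 1-D sample.

    Equals 1/(2n) for n equally spaced points and 0 for a point mass.
    """
    x = np.sort(np.asarray(values, dtype=float).ravel())
    n = x.shape[0]
    if n < 1:
        raise ValueError("dip requires at least one observation")
    v, counts = np.unique(x, return_counts=True)
    if v.shape[0] == 1:
        return 0.0
    cum = np.cumsum(counts) / n
    loF = cum                    # ECDF at the top of each jump
    hiF = cum - counts / n       # ECDF just below each jump
    return float(_dip_band(v, loF, hiF))


@lru_cache(maxsize=64)
def _bootstrap_table(n: int, n_boot: int, seed: int) -> tuple[float, ...]:
    rng = np.random.default_rng(seed)
    return tuple(dip_statistic(rng.random(n)) for _ in range(n_boot))


def dip_test(values: np.ndarray, n_boot: int = 1000,
             rng: np.random.Generator | None = None) -> tuple[float, float]:
    """Dip statistic and bootstrap p-value against the uniform null.

    The null distribution is tabulated from ``n_boot`` uniform samples of
    the same size (cached per size and seed within a process; pass
    ``rng=None`` to reuse the cached default table).  Samples of identical
    values return the minimal dip with p = 1.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.shape[0] < 4:
        raise ValueError("dip test requires n >= 4")
    d = dip_statistic(x)
    seed = 0 if rng is None else int(rng.integers(0, 2**31 - 1))
    boot = np.array(_bootstrap_table(x.shape[0], n_boot, seed))
    p = float(np.mean(boot >= d))
    return d, p
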