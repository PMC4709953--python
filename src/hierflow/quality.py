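"""Quality control of a fitted run and evaluation against reference gatings.

A fitted model is only useful if it passes a battery of checks: MCMC
convergence of scalar parameter traces, separation between latent
components (no confusion between populations), unimodality of the merged
super clusters, and agreement between posterior-predictive draws and the
observed data.  This module also implements the evaluation metrics used to
compare automated gatings against references: the population-size-weighted
F-measure and the l1 distance between population-size vectors within and
between donors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .dip import dip_test
from .merge import MergeResult, bhattacharyya_distance

__all__ = [
    "QcReport",
    "check_separation",
    "check_unimodality",
    "ppc_discrepancy",
    "convergence_diagnostic",
    "f_measure",
    "population_size_distance",
    "quality_report",
]


@dataclass
class QcReport:
    """Scalar outcomes of the quality-control battery."""

    convergence: dict = field(default_factory=dict)
    separation: dict = field(default_factory=dict)
    unimodality: dict = field(default_factory=dict)
    ppc: dict = field(default_factory=dict)
    center_outliers: dict = field(default_factory=dict)
    checks: dict = field(default_factory=dict)   # name -> bool

    @property
    def overall_pass(self) -> bool:
        return all(self.checks.values()) if self.checks else True

    def to_dict(self) -> dict:
        return {
            "convergence": self.convergence,
            "separation": self.separation,
            "unimodality": self.unimodality,
            "ppc": self.ppc,
            "center_outliers": self.center_outliers,
            "checks": self.checks,
            "overall_pass": self.overall_pass,
        }


def check_separation(post_mu: np.ndarray, post_theta: np.ndarray,
                     post_latent_cov: np.ndarray, post_sigma: np.ndarray,
                     active: np.ndarray,
                     partition: np.ndarray) -> dict[tuple[int, int], bool]:
    """No confusion between populations.

    For every active sample component (j, k), its Bhattacharyya and
    Euclidean distances to its own latent component must both be smaller
    than to any latent component outside its super cluster.

    Parameters
    ----------
    post_mu : (J, K, d) posterior mean component centers.
    post_theta : (K, d) posterior mean latent centers.
    post_latent_cov : (K, d, d) posterior mean latent covariances
        (psi / (nu - d - 1)).
    post_sigma : (J, K, d, d) posterior mean component covariances.
    active : (J, K) activation probabilities > 0.5 treated as active.
    partition : (K,) super-cluster id per latent cluster.
    """
    J, K = active.shape
    result: dict[tuple[int, int], bool] = {}
    for j in range(J):
        for k in range(K):
            if not active[j, k]:
                continue
            mu = post_mu[j, k]
            sig = post_sigma[j, k]
            own_b = bhattacharyya_distance(mu, sig, post_theta[k],
                                           post_latent_cov[k])
            own_e = float(np.linalg.norm(mu - post_theta[k]))
            ok = True
            for l in range(K):
                if partition[l] == partition[k]:
                    continue
                other_b = bhattacharyya_distance(mu, sig, post_theta[l],
                                                 post_latent_cov[l])
                other_e = float(np.linalg.norm(mu - post_theta[l]))
                if other_b <= own_b or other_e <= own_e:
                    ok = False
                    break
            result[(j, k)] = ok
    return result


def check_unimodality(events: np.ndarray, weights: np.ndarray,
                      merge_result: MergeResult, alpha: float = 0.28,
                      n_boot: int = 1000,
                      max_events: int = 2000,
                      rng: Optional[np.random.Generator] = None) -> dict:
    """Dip test per coordinate axis for every super cluster.

    Axes with p-value below ``alpha`` (the merge threshold) are flagged for
    visualization.  Events are hard-assigned by maximal soft weight.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    events = np.asarray(events, float)
    weights = np.asarray(weights, float)
    hard = np.argmax(weights, axis=1)
    out: dict = {}
    for sid in np.unique(merge_result.partition):
        members = merge_result.members(sid)
        sel = events[np.isin(hard, members)]
        if sel.shape[0] < 4:
            continue
        if sel.shape[0] > max_events:
            sel = sel[rng.choice(sel.shape[0], max_events, replace=False)]
        for ax in range(events.shape[1]):
            _, p = dip_test(sel[:, ax], n_boot=n_boot, rng=None)
            out[(int(sid), ax)] = {"p": float(p), "flag": bool(p < alpha)}
    return out


def ppc_discrepancy(real: np.ndarray, predictive: np.ndarray,
                    bins: int = 30) -> dict:
    """Total-variation distances between observed and posterior-predictive
    histograms, per marker and per marker pair, on a shared binning."""
    real = np.atleast_2d(np.asarray(real, float))
    predictive = np.atleast_2d(np.asarray(predictive, float))
    if real.shape[0] == 0 or predictive.shape[0] == 0:
        raise ValueError("both event sets must be nonempty")
    d = real.shape[1]
    out: dict = {"marker": {}, "pair": {}}
    edges = []
    for m in range(d):
        lo = min(real[:, m].min(), predictive[:, m].min())
        hi = max(real[:, m].max(), predictive[:, m].max())
        if hi <= lo:
            hi = lo + 1e-9
        edges.append(np.linspace(lo, hi, bins + 1))
    for m in range(d):
        h1, _ = np.histogram(real[:, m], bins=edges[m])
        h2, _ = np.histogram(predictive[:, m], bins=edges[m])
        p = h1 / h1.sum()
        q = h2 / h2.sum()
        out["marker"][m] = float(0.5 * np.abs(p - q).sum())
    for m1 in range(d):
        for m2 in range(m1 + 1, d):
            h1, _, _ = np.histogram2d(real[:, m1], real[:, m2],
                                      bins=[edges[m1], edges[m2]])
            h2, _, _ = np.histogram2d(predictive[:, m1], predictive[:, m2],
                                      bins=[edges[m1], edges[m2]])
            p = h1 / h1.sum()
            q = h2 / h2.sum()
            out["pair"][(m1, m2)] = float(0.5 * np.abs(p - q).sum())
    return out


def convergence_diagnostic(series: np.ndarray, first: float = 0.1,
                           last: float = 0.5) -> float:
    """Geweke-style z-score comparing early and late window means.

    The variance of each window mean is estimated from the spectral density
    at frequency zero (autocovariance-windowed, Newey-West style), so
    autocorrelated chains are not over-flagged.  |z| > 3 indicates
    non-convergence; a zero-variance series returns inf (degenerate, not
    passed).
    """
    x = np.asarray(series, float).ravel()
    n = x.shape[0]
    if n < 100:
        raise ValueError("need at least 100 iterations for the diagnostic")
    a = x[: int(first * n)]
    b = x[-int(last * n):]

    def s0(y):
        y = y - y.mean()
        m = len(y)
        if np.allclose(y, 0):
            return 0.0
        lag = max(1, int(m ** (1 / 3)))
        acov = np.correlate(y, y, mode="full")[m - 1:] / m
        w = 1.0 - np.arange(1, lag + 1) / (lag + 1)
        return float(acov[0] + 2.0 * np.sum(w * acov[1:lag + 1]))

    va = s0(a) / len(a)
    vb = s0(b) / len(b)
    denom = np.sqrt(va + vb)
    if denom == 0:
        return np.inf
    return float((a.mean() - b.mean()) / denom)


def f_measure(reference: np.ndarray, predicted: np.ndarray,
              exclude_unassigned: bool = True,
              unassigned_label: int = -1) -> tuple[float, float, float]:
    """Population-size-weighted F-measure of a predicted clustering.

    For each reference population r and predicted cluster c,
    F(r, c) = 2PR / (P + R) with precision P = |r and c| / |c| and recall
    R = |r and c| / |r|.  The overall score weights each population's best
    F by its share of the scored events; precision and recall are reported
    from the same argmax matches.  Events whose reference label equals
    ``unassigned_label`` are excluded when ``exclude_unassigned``.
    """
    reference = np.asarray(reference).ravel()
    predicted = np.asarray(predicted).ravel()
    if reference.shape != predicted.shape:
        raise ValueError("label vectors must have the same length")
    if exclude_unassigned:
        keep = reference != unassigned_label
        reference = reference[keep]
        predicted = predicted[keep]
    if reference.size == 0:
        raise ValueError("no labeled reference events")
    refs, ref_inv = np.unique(reference, return_inverse=True)
    preds, pred_inv = np.unique(predicted, return_inverse=True)
    conf = np.zeros((len(refs), len(preds)))
    np.add.at(conf, (ref_inv, pred_inv), 1.0)
    n_r = conf.sum(axis=1)
    n_c = conf.sum(axis=0)
    N = conf.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        P = conf / n_c[None, :]
        R = conf / n_r[:, None]
        F = np.where(P + R > 0, 2 * P * R / (P + R), 0.0)
    best = F.argmax(axis=1)
    f_tot = float(np.sum(n_r / N * F[np.arange(len(refs)), best]))
    p_tot = float(np.sum(n_r / N * P[np.arange(len(refs)), best]))
    r_tot = float(np.sum(n_r / N * R[np.arange(len(refs)), best]))
    return f_tot, p_tot, r_tot


def population_size_distance(proportions: np.ndarray,
                             group_ids: Sequence) -> dict:
    """l1 distances between per-sample population-size vectors.

    Distances are split into within-group (same donor) and between-group
    sets; the summary reports whether the two sets overlap (technical
    replicates should be closer than different donors).
    """
    proportions = np.asarray(proportions, float)
    group_ids = np.asarray(group_ids)
    J = proportions.shape[0]
    within, between = [], []
    for i in range(J):
        for j in range(i + 1, J):
            dist = float(np.abs(proportions[i] - proportions[j]).sum())
            (within if group_ids[i] == group_ids[j] else between).append(dist)
    out = {"within": within, "between": between}
    if within and between:
        out["max_within"] = max(within)
        out["min_between"] = min(between)
        out["overlap"] = bool(max(within) >= min(between))
    return out


def quality_report(trace, data, merge_result: MergeResult,
                   dithered_events: Optional[np.ndarray] = None,
                   alpha: float = 0.28,
                   z_threshold: float = 3.0) -> QcReport:
    """Run the full battery on a finished trace and merge result."""
    report = QcReport()
    K = trace.K
    d = trace.theta.shape[2]
    # convergence of latent means
    worst_z = 0.0
    if trace.n_iterations < 100:
        # too few production iterations to assess convergence at all
        report.convergence["error"] = "fewer than 100 production iterations"
        worst_z = np.inf
    else:
        for k in range(K):
            for m in range(d):
                z = convergence_diagnostic(trace.theta[:, k, m])
                report.convergence[f"theta[{k},{m}]"] = z
                if np.isfinite(z):
                    worst_z = max(worst_z, abs(z))
                else:
                    worst_z = np.inf
    report.checks["convergence"] = bool(worst_z <= z_threshold)
    # separation
    post_theta = trace.theta.mean(axis=0)
    latent_cov = np.array([
        (trace.psi[:, k] / (trace.nu[:, k, None, None] - d - 1)).mean(axis=0)
        for k in range(K)])
    act = trace.activation_probability() > 0.5
    post_mu = trace.posterior_mean_mu()
    post_sigma = trace.sigma.mean(axis=0) if trace.sigma is not None else \
        np.tile(latent_cov, (len(data), 1, 1, 1))
    sep = check_separation(post_mu, post_theta, latent_cov, post_sigma,
                           act, merge_result.partition)
    report.separation = {f"{j},{k}": ok for (j, k), ok in sep.items()}
    report.checks["separation"] = all(sep.values()) if sep else True
    # unimodality of super clusters
    events = dithered_events if dithered_events is not None else \
        np.vstack([s.events for s in data])
    weights = trace.soft_clustering()[:, 1:]
    report.unimodality = {f"{sid},{ax}": v for (sid, ax), v in
                          check_unimodality(events, weights, merge_result,
                                            alpha=alpha).items()}
    report.checks["unimodality"] = not any(v["flag"] for v in
                                           report.unimodality.values())
    # posterior-predictive fit (advisory, no auto-fail)
    for j, s in enumerate(data):
        disc = ppc_discrepancy(s.events, trace.ppc[j])
        report.ppc[s.sample_id] = {"max_marker_tv": max(disc["marker"].values()),
                                   "max_pair_tv": max(disc["pair"].values())
                                   if disc["pair"] else 0.0}
    # center outliers (advisory): robust z of component centers per cluster
    for k in range(K):
        centers = post_mu[:, k, :]
        ok_rows = np.all(np.isfinite(centers), axis=1)
        centers = centers[ok_rows]
        if centers.shape[0] < 3:
            continue
        med = np.median(centers, axis=0)
        mad = np.median(np.abs(centers - med), axis=0) + 1e-12
        rz = np.abs(centers - med) / (1.4826 * mad)
        flagged = np.flatnonzero((rz > 5).any(axis=1))
        report.center_outliers[k] = flagged.tolist()
    return report
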