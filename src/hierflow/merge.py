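"""Merging latent clusters into super clusters (cell populations).

Gaussian components give a parsimonious description, but real cell
populations can be skewed or heavy-tailed; such populations are represented
by several latent clusters merged into one super cluster.  Merging uses the
Bhattacharyya distance between moment-matched Gaussians with two
thresholds: pairs closer than ``d1`` always merge; pairs between ``d1`` and
``d2`` merge only if no tested 1-D projection (low-overlap coordinate axes
and Fisher's discriminant coordinate) rejects unimodality under Hartigan's
dip test; pairs beyond ``d2`` never merge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._linalg import InvalidParameterError, spd_cholesky
from .dip import dip_test

__all__ = [
    "MergeResult",
    "bhattacharyya_distance",
    "gaussian_moment_match",
    "fisher_coordinate",
    "merge_latent_clusters",
]


@dataclass
class MergeResult:
    """Partition of latent clusters into super clusters with merge evidence.

    ``partition[k]`` is the super-cluster id of latent cluster k;
    ``merge_log`` records every considered pair as a dict with the pair,
    its Bhattacharyya distance, dip p-values per tested projection and the
    decision taken.
    """

    partition: np.ndarray
    merge_log: list[dict] = field(default_factory=list)
    d1: float = 0.1
    d2: float = 1.0
    dip_alpha: float = 0.28

    @property
    def n_super(self) -> int:
        return len(np.unique(self.partition))

    def members(self, super_id: int) -> np.ndarray:
        return np.flatnonzero(self.partition == super_id)

    def to_dict(self) -> dict:
        return {
            "partition": self.partition.tolist(),
            "d1": self.d1, "d2": self.d2, "dip_alpha": self.dip_alpha,
            "merge_log": self.merge_log,
        }


def bhattacharyya_distance(mu1, sigma1, mu2, sigma2) -> float:
    """Bhattacharyya distance between two Gaussians.

    d = (1/8) (mu1-mu2)^T S^-1 (mu1-mu2) + (1/2) log(|S| / sqrt(|S1||S2|)),
    with S the average covariance; symmetric and zero iff the Gaussians
    coincide.
    """
    mu1 = np.atleast_1d(np.asarray(mu1, float))
    mu2 = np.atleast_1d(np.asarray(mu2, float))
    sigma1 = np.atleast_2d(np.asarray(sigma1, float))
    sigma2 = np.atleast_2d(np.asarray(sigma2, float))
    c1 = spd_cholesky(sigma1)
    c2 = spd_cholesky(sigma2)
    avg = 0.5 * (sigma1 + sigma2)
    ca = spd_cholesky(avg)
    diff = mu1 - mu2
    from scipy.linalg import solve_triangular

    z = solve_triangular(ca, diff, lower=True)
    quad = float(z @ z)
    logdet = (2 * np.sum(np.log(np.diag(ca)))
              - np.sum(np.log(np.diag(c1))) - np.sum(np.log(np.diag(c2))))
    return 0.125 * quad + 0.5 * logdet


def gaussian_moment_match(events: np.ndarray, weights: np.ndarray,
                          cluster_set: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    """Weighted mean and covariance of pooled events for a set of clusters.

    ``weights`` is the (n, K) soft clustering over latent clusters (the
    outlier column excluded); the weight of each event is the sum over the
    clusters in ``cluster_set``.
    """
    events = np.asarray(events, float)
    w = np.asarray(weights, float)[:, list(cluster_set)].sum(axis=1)
    total = w.sum()
    if total <= 1e-12:
        raise InvalidParameterError("total soft weight of the cluster set is ~0")
    mean = (w[:, None] * events).sum(axis=0) / total
    resid = events - mean
    cov = (w[:, None] * resid).T @ resid / total
    return mean, cov


def fisher_coordinate(mu1, sigma1, mu2, sigma2) -> np.ndarray:
    """Fisher's discriminant coordinate between two Gaussians.

    Unit vector proportional to (Sigma1 + Sigma2)^{-1} (mu1 - mu2), with
    the first nonzero entry made positive.  Undefined for equal means.
    """
    mu1 = np.atleast_1d(np.asarray(mu1, float))
    mu2 = np.atleast_1d(np.asarray(mu2, float))
    diff = mu1 - mu2
    if np.allclose(diff, 0):
        raise InvalidParameterError("Fisher coordinate undefined for equal means")
    pooled = np.atleast_2d(np.asarray(sigma1, float)) + np.atleast_2d(np.asarray(sigma2, float))
    chol = spd_cholesky(pooled)
    from scipy.linalg import cho_solve

    w = cho_solve((chol, True), diff)
    w = w / np.linalg.norm(w)
    nz = np.flatnonzero(np.abs(w) > 1e-12)
    if len(nz) and w[nz[0]] < 0:
        w = -w
    return w


def _marginal_bhat(mu1, s1, mu2, s2, axis: int) -> float:
    return bhattacharyya_distance(mu1[axis:axis + 1], s1[axis:axis + 1, axis:axis + 1],
                                  mu2[axis:axis + 1], s2[axis:axis + 1, axis:axis + 1])


def merge_latent_clusters(events: np.ndarray, weights: np.ndarray,
                          d1: float = 0.1, d2: float = 1.0,
                          dip_alpha: float = 0.28,
                          rng: Optional[np.random.Generator] = None,
                          n_boot: int = 1000,
                          max_dip_events: int = 2000) -> MergeResult:
    """Iteratively merge latent clusters into super clusters.

    At each round the super clusters are moment-matched against the pooled
    (dithered) ``events`` using the soft clustering ``weights``.  The closest
    pair by Bhattacharyya distance is merged if below ``d1``; if within
    [d1, d2) it is merged only when no tested projection — coordinate axes
    with marginal Bhattacharyya distance above ``d1``, plus Fisher's
    discriminant coordinate — is declared multimodal (dip p < dip_alpha).
    Events entering a dip test are those hard-assigned (argmax weight) to
    the candidate pair, subsampled to ``max_dip_events``.

    Parameters
    ----------
    events : (n, d) pooled events (use the dithered copy).
    weights : (n, K) soft clustering over latent clusters, outlier column
        excluded (renormalization is not required for moment matching).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if d1 > d2:
        raise ValueError("d1 must not exceed d2")
    events = np.asarray(events, float)
    weights = np.asarray(weights, float)
    return _merge_impl(events, weights, d1, d2, dip_alpha, rng, n_boot,
                       max_dip_events)


def _merge_impl(events, weights, d1, d2, dip_alpha, rng, n_boot,
                max_dip_events) -> MergeResult:
    K = weights.shape[1]
    partition = np.arange(K)
    log: list[dict] = []
    hard = np.argmax(weights, axis=1)

    def super_ids():
        return list(np.unique(partition))

    while True:
        sids = super_ids()
        if len(sids) < 2:
            break
        moments = {}
        for sid in sids:
            members = np.flatnonzero(partition == sid)
            try:
                moments[sid] = gaussian_moment_match(events, weights, members)
            except InvalidParameterError:
                moments[sid] = None
        pairs = []
        for i, a in enumerate(sids):
            for b in sids[i + 1:]:
                if moments[a] is None or moments[b] is None:
                    continue
                dist = bhattacharyya_distance(moments[a][0], moments[a][1],
                                              moments[b][0], moments[b][1])
                pairs.append((dist, a, b))
        pairs.sort(key=lambda p: (p[0], p[1], p[2]))
        merged = False
        for dist, a, b in pairs:
            if dist >= d2:
                break  # sorted: nothing closer than d2 remains
            if dist < d1:
                partition[partition == b] = a
                log.append({"pair": [int(a), int(b)], "d_bhat": float(dist),
                            "dip_p": {}, "decision": "merged (< d1)"})
                merged = True
                break
            # [d1, d2): dip tests on low-overlap axes + Fisher coordinate
            mu_a, s_a = moments[a]
            mu_b, s_b = moments[b]
            in_pair = np.isin(partition[hard], [a, b])
            sel = events[in_pair]
            if sel.shape[0] > max_dip_events:
                sel = sel[rng.choice(sel.shape[0], max_dip_events, replace=False)]
            dips = {}
            reject = False
            if sel.shape[0] >= 4:
                axes = [ax for ax in range(events.shape[1])
                        if _marginal_bhat(mu_a, s_a, mu_b, s_b, ax) > d1]
                projections = {f"axis{ax}": sel[:, ax] for ax in axes}
                try:
                    fc = fisher_coordinate(mu_a, s_a, mu_b, s_b)
                    projections["fisher"] = sel @ fc
                except InvalidParameterError:
                    pass
                for name, proj in projections.items():
                    _, p = dip_test(proj, n_boot=n_boot, rng=None)
                    dips[name] = float(p)
                    if p < dip_alpha:
                        reject = True
            if reject:
                log.append({"pair": [int(a), int(b)], "d_bhat": float(dist),
                            "dip_p": dips, "decision": "kept (multimodal projection)"})
                continue
            partition[partition == b] = a
            log.append({"pair": [int(a), int(b)], "d_bhat": float(dist),
                        "dip_p": dips, "decision": "merged (unimodal)"})
            merged = True
            break
        if not merged:
            break
    return MergeResult(partition=partition, merge_log=log, d1=d1, d2=d2,
                       dip_alpha=dip_alpha)
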