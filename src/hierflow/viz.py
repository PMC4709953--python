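"""Diagnostic and summary visualizations of fitted runs.

All figure builders are pure functions of serialized outputs (traces,
merge results, soft weights) so reports can be re-rendered without
re-running MCMC.  Ellipse conventions: the center is the projected mean,
each semi-axis is an eigenvector of the projected covariance with length
equal to the corresponding eigenvalue; merged latent clusters share a hue
in different shades.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = [
    "EllipseSpec",
    "component_ellipses",
    "weighted_quantile",
    "population_boxes",
    "trace_plots",
    "center_plots",
    "eigen_plots",
    "cluster_colors",
]


@dataclass
class EllipseSpec:
    """Center and semi-axes (orthogonal, scaled by eigenvalue) of one ellipse."""

    center: np.ndarray      # (2,)
    axes: np.ndarray        # (2, 2): rows are the two semi-axis vectors
    label: str = ""

    @property
    def lengths(self) -> np.ndarray:
        return np.linalg.norm(self.axes, axis=1)


def component_ellipses(means: np.ndarray, covs: np.ndarray,
                       dims: tuple[int, int] = (0, 1),
                       labels: Optional[Sequence[str]] = None) -> list[EllipseSpec]:
    """Ellipse specs for a set of Gaussian components projected to two dims."""
    means = np.atleast_2d(np.asarray(means, float))
    covs = np.asarray(covs, float)
    if covs.ndim == 2:
        covs = covs[None]
    i, j = dims
    out = []
    for c, (m, S) in enumerate(zip(means, covs)):
        sub = S[np.ix_([i, j], [i, j])]
        w, V = np.linalg.eigh(sub)
        axes = V.T * w[:, None]       # each row: eigenvector * eigenvalue
        lab = labels[c] if labels is not None else str(c)
        out.append(EllipseSpec(center=m[[i, j]], axes=axes, label=lab))
    return out


def weighted_quantile(values: np.ndarray, weights: np.ndarray,
                      alpha: float) -> float:
    """Quantile of weighted events per the cumulative-weight convention.

    Returns the smallest observed value y with
    ``alpha < sum of (normalized) weights of events strictly below y``;
    if no value satisfies the condition (alpha ~ 1) the maximum is
    returned.
    """
    values = np.asarray(values, float).ravel()
    weights = np.asarray(weights, float).ravel()
    total = weights.sum()
    if total <= 0:
        raise ValueError("weights must have positive total")
    order = np.argsort(values, kind="stable")
    v = values[order]
    w = weights[order] / total
    below = np.concatenate([[0.0], np.cumsum(w)[:-1]])
    # cumulative weight strictly below each value: collapse ties downward
    uniq, first = np.unique(v, return_index=True)
    below_u = below[first]
    idx = np.searchsorted(below_u, alpha, side="right")
    if idx >= len(uniq):
        return float(uniq[-1])
    return float(uniq[idx])


def population_boxes(events: np.ndarray, weights: np.ndarray,
                     partition: np.ndarray,
                     quantiles: tuple[float, ...] = (0.01, 0.25, 0.75, 0.99)) -> dict:
    """Weighted box statistics per super cluster and marker.

    Boxes span the 0.25-0.75 weighted quantiles, whiskers 0.01-0.99,
    computed from the soft-clustering weights summed over each super
    cluster's members.
    """
    events = np.asarray(events, float)
    weights = np.asarray(weights, float)
    out: dict = {}
    for sid in np.unique(partition):
        members = np.flatnonzero(partition == sid)
        w = weights[:, members].sum(axis=1)
        if w.sum() <= 1e-12:
            import warnings

            warnings.warn(f"super cluster {sid} has ~zero weight; skipped")
            continue
        out[int(sid)] = {
            m: {f"q{q}": weighted_quantile(events[:, m], w, q)
                for q in quantiles}
            for m in range(events.shape[1])
        }
    return out


def cluster_colors(partition: np.ndarray) -> list[tuple]:
    """One hue per super cluster, shades per member latent cluster."""
    import matplotlib.colors as mcolors

    partition = np.asarray(partition)
    supers = list(np.unique(partition))
    cmap = plt.get_cmap("tab10")
    colors = []
    for k in range(len(partition)):
        sid = partition[k]
        base = np.array(mcolors.to_rgb(cmap(supers.index(sid) % 10)))
        members = list(np.flatnonzero(partition == sid))
        rank = members.index(k)
        shade = 1.0 - 0.5 * rank / max(len(members) - 1, 1)
        colors.append(tuple(base * shade))
    return colors


def trace_plots(trace, params: Sequence[str] = ("theta",),
                max_panels: int = 16):
    """Trace figures of scalar latent parameters over production iterations."""
    figs = []
    for name in params:
        arr = getattr(trace, name)
        flat = arr.reshape(arr.shape[0], -1)
        n = min(flat.shape[1], max_panels)
        ncol = int(np.ceil(np.sqrt(n)))
        nrow = int(np.ceil(n / ncol))
        fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2 * nrow),
                                 squeeze=False)
        for i in range(n):
            ax = axes[i // ncol][i % ncol]
            ax.plot(flat[:, i], lw=0.5)
            ax.set_title(f"{name}[{i}]", fontsize=8)
        for i in range(n, nrow * ncol):
            axes[i // ncol][i % ncol].axis("off")
        fig.tight_layout()
        figs.append(fig)
    return figs


def center_plots(trace, dim: int = 0):
    """Strip plot of posterior-mean component centers per cluster along one
    dimension; one strip per latent cluster, one dot per active sample."""
    post_mu = trace.posterior_mean_mu()
    act = trace.activation_probability() > 0.5
    J, K, _ = post_mu.shape
    fig, ax = plt.subplots(figsize=(1.2 * K + 2, 3))
    for k in range(K):
        ys = [post_mu[j, k, dim] for j in range(J) if act[j, k]]
        ax.plot(np.full(len(ys), k) + np.linspace(-0.15, 0.15, max(len(ys), 1)),
                ys, "o", ms=3)
    ax.set_xlabel("latent cluster")
    ax.set_ylabel(f"center, dim {dim}")
    fig.tight_layout()
    return fig


def eigen_plots(trace, dims: tuple[int, int] = (0, 1), top: int = 1):
    """Glyphs of the top covariance eigenvectors scaled by their eigenvalues."""
    post_theta = trace.theta.mean(axis=0)
    d = post_theta.shape[1]
    latent_cov = np.array([
        (trace.psi[:, k] / (trace.nu[:, k, None, None] - d - 1)).mean(axis=0)
        for k in range(trace.K)])
    fig, ax = plt.subplots(figsize=(5, 5))
    i, j = dims
    for k in range(trace.K):
        sub = latent_cov[k][np.ix_([i, j], [i, j])]
        w, V = np.linalg.eigh(sub)
        order = np.argsort(w)[::-1]
        c = post_theta[k][[i, j]]
        ax.plot(*c, "ko", ms=3)
        for e in order[:top]:
            vec = V[:, e] * w[e]
            ax.plot([c[0] - vec[0], c[0] + vec[0]],
                    [c[1] - vec[1], c[1] + vec[1]], "-")
    ax.set_xlabel(f"dim {i}")
    ax.set_ylabel(f"dim {j}")
    fig.tight_layout()
    return fig
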