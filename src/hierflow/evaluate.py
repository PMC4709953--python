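"""Parameter-recovery evaluation against synthetic ground truth.

Inferred latent clusters carry arbitrary labels, so every comparison first
matches them to the true clusters by solving the assignment problem on the
distance between posterior-mean and true latent centers.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

from .sampler import McmcTrace
from .synth import SynthTruth

__all__ = ["match_clusters", "theta_coverage", "center_errors",
           "activation_rates", "hard_labels"]


def match_clusters(theta_true: np.ndarray, theta_est: np.ndarray) -> np.ndarray:
    """Permutation perm with inferred cluster perm[k] matching true cluster k."""
    cost = np.linalg.norm(theta_true[:, None, :] - theta_est[None, :, :], axis=2)
    _, col = linear_sum_assignment(cost)
    return col


def theta_coverage(trace: McmcTrace, truth: SynthTruth,
                   level: float = 0.95) -> tuple[float, int, int]:
    """Fraction of true latent-mean coordinates inside the central posterior
    interval; returns (fraction, inside, total)."""
    perm = match_clusters(truth.theta, trace.theta.mean(axis=0))
    a = (1.0 - level) / 2.0
    inside = 0
    total = 0
    for k in range(truth.theta.shape[0]):
        draws = trace.theta[:, perm[k], :]
        lo = np.quantile(draws, a, axis=0)
        hi = np.quantile(draws, 1.0 - a, axis=0)
        inside += int(np.sum((truth.theta[k] >= lo) & (truth.theta[k] <= hi)))
        total += truth.theta.shape[1]
    return inside / total, inside, total


def center_errors(trace: McmcTrace, truth: SynthTruth) -> tuple[float, float]:
    """Mean Euclidean error of posterior-mean component centers vs the error
    of substituting the true latent mean for every sample.

    The second number is the best a model without between-sample variation
    could achieve; hierarchical pooling should beat it.
    """
    perm = match_clusters(truth.theta, trace.theta.mean(axis=0))
    post_mu = trace.posterior_mean_mu()
    errs, base = [], []
    J, K = truth.presence.shape
    for j in range(J):
        for k in range(K):
            if not truth.presence[j, k]:
                continue
            est = post_mu[j, perm[k]]
            if not np.all(np.isfinite(est)):
                continue
            errs.append(np.linalg.norm(est - truth.mu[j, k]))
            base.append(np.linalg.norm(truth.theta[k] - truth.mu[j, k]))
    return float(np.mean(errs)), float(np.mean(base))


def activation_rates(trace: McmcTrace, truth: SynthTruth) -> dict:
    """Posterior activation probabilities split by planted presence."""
    perm = match_clusters(truth.theta, trace.theta.mean(axis=0))
    act = trace.activation_probability()[:, perm]
    present = act[truth.presence]
    absent = act[~truth.presence]
    return {
        "mean_present": float(present.mean()),
        "mean_absent": float(absent.mean()) if absent.size else 0.0,
        "min_present": float(present.min()),
        "max_absent": float(absent.max()) if absent.size else 0.0,
        "present_values": present,
        "absent_values": absent,
    }


def hard_labels(trace: McmcTrace) -> list[np.ndarray]:
    """Per-sample hard labels (0 = outlier) from averaged responsibilities."""
    return [np.argmax(r, axis=1) for r in trace.responsibilities]
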