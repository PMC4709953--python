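"""Synthetic multi-sample flow cytometry data from the hierarchical model.

Generates datasets with the exact generative structure the sampler assumes:
latent clusters (theta_k, Sigma_theta_k, Psi_k, nu_k) are fixed, per-sample
component parameters are drawn from the hierarchical priors, weights from a
Dirichlet restricted to the clusters present in each sample, and events
from the resulting mixtures.  Two committed designs reproduce the study
conditions used throughout:

* ``small_design`` — 3 dimensions, 4 latent clusters, 80 samples of 15,000
  cells (1.2 million in total); one cluster present in only 8 samples and
  holding 1% of all cells, another present in 24 samples;
* ``large_design`` — 8 dimensions, 11 latent clusters, 192 samples of
  150,000 cells (28 million in total); 4 clusters missing in half the
  samples.

Both expose a ``scale`` factor shrinking the number of samples and cells
while preserving the presence structure and the rare-cluster share, so the
full pipeline can be exercised at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .model import SampleData

__all__ = ["SynthConfig", "SynthTruth", "generate_dataset",
           "small_design", "large_design"]


@dataclass
class SynthConfig:
    """Generator settings; the committed design functions fill these in."""

    d: int
    K: int
    J: int
    n_per_sample: int
    presence_fraction: np.ndarray          # (K,) fraction of samples containing k
    total_fraction: Optional[np.ndarray] = None   # (K,) share of all cells, or None
    presence: Optional[np.ndarray] = None  # explicit (J, K) matrix overrides fractions
    weight_concentration: float = 200.0    # Dirichlet jitter of sample weights
    sigma_theta_sd: float = 0.02           # between-sample component-mean sd
    cluster_sd_range: tuple[float, float] = (0.04, 0.08)
    nu_mode: str = "fixed"                 # "fixed" or "draw"
    nu_fixed: int = 35
    nu_range: tuple[int, int] = (25, 45)
    outlier_fraction: float = 0.0
    min_separation: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        self.presence_fraction = np.asarray(self.presence_fraction, float)
        if self.total_fraction is not None:
            self.total_fraction = np.asarray(self.total_fraction, float)

    @property
    def total_events(self) -> int:
        return self.J * self.n_per_sample


@dataclass
class SynthTruth:
    """Complete ground truth of a generated dataset."""

    theta: np.ndarray            # (K, d)
    sigma_theta: np.ndarray      # (K, d, d)
    psi: np.ndarray              # (K, d, d)
    nu: np.ndarray               # (K,)
    presence: np.ndarray         # (J, K) bool
    weights: np.ndarray          # (J, K+1), index 0 = outlier
    mu: np.ndarray               # (J, K, d), NaN where absent
    sigma: np.ndarray            # (J, K, d, d), NaN where absent
    labels: list = field(default_factory=list)  # per sample, 0=outlier, 1..K

    @property
    def latent_cov(self) -> np.ndarray:
        d = self.theta.shape[1]
        return self.psi / (self.nu[:, None, None] - d - 1)

    def cluster_event_fraction(self) -> np.ndarray:
        """(K+1,) realized share of all events per component (0 = outlier)."""
        counts = np.zeros(self.theta.shape[0] + 1)
        total = 0
        for lab in self.labels:
            counts += np.bincount(lab, minlength=len(counts))
            total += len(lab)
        return counts / total


def _presence_matrix(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.presence is not None:
        pres = np.asarray(cfg.presence, bool)
        if pres.shape != (cfg.J, cfg.K):
            raise ValueError("presence matrix must be (J, K)")
    else:
        pres = np.zeros((cfg.J, cfg.K), bool)
        for k in range(cfg.K):
            n_k = max(1, int(round(cfg.presence_fraction[k] * cfg.J)))
            idx = rng.choice(cfg.J, size=min(n_k, cfg.J), replace=False)
            pres[idx, k] = True
    if not pres.any(axis=1).all():
        raise ValueError("some sample has no present cluster")
    return pres


def _random_spd(d: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Random covariance with eigenvalues ~ sd^2 (0.7x-1.3x) and random axes."""
    eig = sd ** 2 * rng.uniform(0.7, 1.3, size=d)
    q, _ = np.linalg.qr(rng.standard_normal((d, d)))
    return (q * eig) @ q.T


def _latent_means(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Latent cluster centers in the unit box with minimum separation."""
    for _ in range(2000):
        theta = rng.uniform(0.15, 0.85, size=(cfg.K, cfg.d))
        dists = np.linalg.norm(theta[:, None] - theta[None, :], axis=2)
        np.fill_diagonal(dists, np.inf)
        if dists.min() >= cfg.min_separation:
            return theta
    raise RuntimeError("could not place latent means with the requested separation")


def _sample_weights(cfg: SynthConfig, pres: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    """Expected per-sample weights honoring total shares, with Dirichlet jitter."""
    K, J = cfg.K, cfg.J
    counts = pres.sum(axis=0)
    if cfg.total_fraction is not None:
        tf = cfg.total_fraction.copy()
        fixed = np.isfinite(tf)
    else:
        tf = np.full(K, np.nan)
        fixed = np.zeros(K, bool)
    weights = np.zeros((J, K + 1))
    weights[:, 0] = cfg.outlier_fraction
    mass = 1.0 - cfg.outlier_fraction
    for j in range(J):
        omega = np.zeros(K)
        # clusters with a pinned share of all cells get exactly
        # share * J / (number of samples containing them) when present
        sel_fix = pres[j] & fixed
        omega[sel_fix] = tf[sel_fix] * J / np.maximum(counts[sel_fix], 1)
        sel_free = pres[j] & ~fixed
        remainder = mass - omega.sum()
        if sel_free.any():
            if remainder <= 0.01:
                raise ValueError(f"sample {j}: pinned shares leave no mass "
                                 "for the free clusters")
            omega[sel_free] = remainder / sel_free.sum()
        else:
            if omega.sum() <= 0:
                raise ValueError(f"sample {j}: no positive expected weight")
            omega *= mass / omega.sum()
        present = np.flatnonzero(omega > 0)
        draw = rng.dirichlet(cfg.weight_concentration * omega[present])
        weights[j, 1 + present] = draw * mass
    return weights


def generate_dataset(cfg: SynthConfig) -> tuple[list[SampleData], SynthTruth]:
    """Generate samples and the full ground-truth record.

    The same seed reproduces the dataset byte for byte.
    """
    rng = np.random.default_rng(cfg.seed)
    d, K, J = cfg.d, cfg.K, cfg.J
    pres = _presence_matrix(cfg, rng)
    theta = _latent_means(cfg, rng)
    sigma_theta = np.tile(np.eye(d) * cfg.sigma_theta_sd ** 2, (K, 1, 1))
    if cfg.nu_mode == "fixed":
        nu = np.full(K, cfg.nu_fixed, dtype=int)
    elif cfg.nu_mode == "draw":
        nu = rng.integers(cfg.nu_range[0], cfg.nu_range[1] + 1, size=K)
    else:
        raise ValueError(f"unknown nu_mode {cfg.nu_mode!r}")
    sds = rng.uniform(*cfg.cluster_sd_range, size=K)
    psi = np.stack([_random_spd(d, sds[k], rng) * (nu[k] - d - 1)
                    for k in range(K)])
    weights = _sample_weights(cfg, pres, rng)

    mu = np.full((J, K, d), np.nan)
    sigma = np.full((J, K, d, d), np.nan)
    samples, labels = [], []
    outlier_mu = np.full(d, 0.5)
    outlier_sd = 0.6
    for j in range(J):
        for k in range(K):
            if pres[j, k]:
                mu[j, k] = rng.multivariate_normal(theta[k], sigma_theta[k])
                sigma[j, k] = stats.invwishart.rvs(df=int(nu[k]), scale=psi[k],
                                                   random_state=rng)
        counts = rng.multinomial(cfg.n_per_sample, weights[j])
        events = np.empty((cfg.n_per_sample, d))
        lab = np.empty(cfg.n_per_sample, dtype=np.int64)
        pos = 0
        if counts[0] > 0:
            events[pos:pos + counts[0]] = rng.normal(
                outlier_mu, outlier_sd, size=(counts[0], d))
            lab[pos:pos + counts[0]] = 0
            pos += counts[0]
        for k in range(K):
            c = counts[k + 1]
            if c == 0:
                continue
            chol = np.linalg.cholesky(sigma[j, k])
            events[pos:pos + c] = mu[j, k] + rng.standard_normal((c, d)) @ chol.T
            lab[pos:pos + c] = k + 1
            pos += c
        perm = rng.permutation(cfg.n_per_sample)
        samples.append(SampleData(events[perm], sample_id=f"sample{j:03d}",
                                  markers=[f"m{m}" for m in range(d)]))
        labels.append(lab[perm])
    truth = SynthTruth(theta=theta, sigma_theta=sigma_theta, psi=psi, nu=nu,
                       presence=pres, weights=weights, mu=mu, sigma=sigma,
                       labels=labels)
    return samples, truth


def small_design(scale: float = 1.0, seed: int = 0) -> SynthConfig:
    """Three-dimensional design: 4 latent clusters, 80 samples x 15,000 cells.

    Cluster 3 is present in 8 samples and holds 1% of all cells; cluster 2
    is present in 24 samples (10% of all cells by default); clusters 0-1
    are everywhere and split the remainder.  ``scale`` shrinks J and the
    cells per sample proportionally, preserving the presence pattern and
    cell shares.
    """
    J = max(2, int(round(80 * scale)))
    n = max(50, int(round(15000 * scale)))
    return SynthConfig(
        d=3, K=4, J=J, n_per_sample=n,
        presence_fraction=np.array([1.0, 1.0, 24 / 80, 8 / 80]),
        total_fraction=np.array([np.nan, np.nan, 0.10, 0.01]),
        outlier_fraction=0.0,
        seed=seed,
    )


def large_design(scale: float = 1.0, seed: int = 0) -> SynthConfig:
    """Eight-dimensional design: 11 latent clusters, 192 samples x 150,000
    cells, with 4 of the clusters missing in half the samples."""
    J = max(2, int(round(192 * scale)))
    n = max(50, int(round(150000 * scale)))
    return SynthConfig(
        d=8, K=11, J=J, n_per_sample=n,
        presence_fraction=np.array([1.0] * 7 + [0.5] * 4),
        total_fraction=None,
        outlier_fraction=0.0,
        min_separation=0.3,
        seed=seed,
    )
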