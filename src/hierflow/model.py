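"""Core hierarchical Gaussian mixture model: state containers and densities.

The model describes J flow cytometry samples jointly.  Within sample j the
cells follow a K-component Gaussian mixture plus one shared broad "outlier"
Gaussian (index 0):

    f(y_ij) = sum_k pi_jk N(y_ij; mu_jk, Sigma_jk) + pi_j0 N(y_ij; mu_0, Sigma_0)

Each non-outlier component is a noisy realization of a *latent cluster* k
shared across samples:

    mu_jk    | theta_k, Sigma_theta_k  ~  N(theta_k, Sigma_theta_k)
    Sigma_jk | Psi_k, nu_k             ~  IW(Psi_k, nu_k)

with conjugate hyper-priors on the latent-cluster parameters
(theta_k ~ N(t_k, S_k); Sigma_theta_k ~ IW(Q_k, n_theta_k);
Psi_k ~ W(H_k, n_Psi_k); nu_k has an exponential prior on the integers
nu >= d+2; pi_j ~ Dirichlet(a)).  Binary activation flags Z_jk say which
components exist in which samples; their prior is proportional to
exp(-c_s * sum_k Z_jk) with at least one component required active.

This module holds every symbol of the model and evaluates the mixture
density and the joint log posterior used by the sampler and the tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._linalg import (
    InvalidParameterError,
    InvalidStateError,
    dirichlet_logpdf,
    invwishart_logpdf,
    logsumexp_rows,
    mvn_logpdf,
    spd_cholesky,
    wishart_logpdf,
)

__all__ = [
    "SampleData",
    "ComponentParams",
    "LatentCluster",
    "SampleMixture",
    "PriorSpec",
    "log_mixture_density",
    "log_joint_posterior",
]


@dataclass
class SampleData:
    """One flow cytometry sample: an events x markers matrix plus metadata."""

    events: np.ndarray
    sample_id: str
    group_id: Optional[str] = None
    markers: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=float)
        if self.events.ndim != 2 or self.events.shape[0] < 1:
            raise ValueError("events must be a non-empty (n, d) matrix")
        if not np.all(np.isfinite(self.events)):
            raise ValueError(f"sample {self.sample_id!r} contains non-finite values")

    @property
    def n(self) -> int:
        return self.events.shape[0]

    @property
    def d(self) -> int:
        return self.events.shape[1]


@dataclass
class ComponentParams:
    """Mean and covariance of one mixture component in one sample."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float).ravel()
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.chol = spd_cholesky(self.sigma)  # validates SPD

    def copy(self) -> "ComponentParams":
        return ComponentParams(self.mu.copy(), self.sigma.copy())


@dataclass
class LatentCluster:
    """Shared description of one cell population across all samples.

    ``theta`` is the latent mean, ``sigma_theta`` the between-sample spread of
    component means, and ``psi``/``nu`` parametrize the inverse-Wishart from
    which component covariances are drawn; the latent covariance matrix is
    ``psi / (nu - d - 1)``.
    """

    theta: np.ndarray
    sigma_theta: np.ndarray
    psi: np.ndarray
    nu: int

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float).ravel()
        self.sigma_theta = np.asarray(self.sigma_theta, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        d = self.theta.shape[0]
        if self.nu <= d + 1:
            raise InvalidParameterError(
                f"nu must exceed d+1={d + 1} so the latent covariance exists; got {self.nu}")
        spd_cholesky(self.sigma_theta)
        spd_cholesky(self.psi)

    @property
    def d(self) -> int:
        return self.theta.shape[0]

    @property
    def latent_cov(self) -> np.ndarray:
        """A-priori expected component covariance, psi / (nu - d - 1)."""
        return self.psi / (self.nu - self.d - 1)

    def copy(self) -> "LatentCluster":
        return LatentCluster(self.theta.copy(), self.sigma_theta.copy(),
                             self.psi.copy(), int(self.nu))


@dataclass
class SampleMixture:
    """Full mixture state of one sample at one MCMC iteration.

    ``weights`` has length K+1 with index 0 the outlier weight; ``components``
    holds one :class:`ComponentParams` per latent cluster (entries for
    inactive components are retained but carry zero weight and no cells).
    ``assignments`` maps each event to {0 (outlier), 1..K}.
    """

    components: list[ComponentParams]
    weights: np.ndarray
    active: np.ndarray
    assignments: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        self.active = np.asarray(self.active, dtype=bool).ravel()
        self.assignments = np.asarray(self.assignments, dtype=np.int64).ravel()

    @property
    def K(self) -> int:
        return len(self.components)

    def validate(self) -> None:
        K = self.K
        if self.weights.shape != (K + 1,):
            raise InvalidStateError("weights must have length K+1")
        if np.any(self.weights < -1e-12) or abs(self.weights.sum() - 1.0) > 1e-8:
            raise InvalidStateError("weights must be a probability vector")
        if not np.any(self.active):
            raise InvalidStateError("at least one component must be active")
        if np.any(self.weights[1:][~self.active] != 0.0):
            raise InvalidStateError("inactive components must have exactly zero weight")
        bad = (self.assignments > 0) & ~self.active[self.assignments - 1]
        if np.any(bad):
            raise InvalidStateError("assignments point to inactive components")

    def copy(self) -> "SampleMixture":
        return SampleMixture([c.copy() for c in self.components],
                             self.weights.copy(), self.active.copy(),
                             self.assignments.copy())


@dataclass
class PriorSpec:
    """Hyper-prior parameters for all K latent clusters plus outlier/activation.

    Arrays are stacked over clusters: ``t`` is (K, d), ``S``/``Q``/``H`` are
    (K, d, d), ``n_theta``/``n_psi``/``lam`` are (K,), ``a`` is the (K+1,)
    Dirichlet concentration (index 0 = outlier).  ``c_s`` is the activation
    penalty; ``outlier_mu``/``outlier_sigma`` are the fixed parameters of the
    shared noise-catcher component.
    """

    t: np.ndarray
    S: np.ndarray
    Q: np.ndarray
    n_theta: np.ndarray
    H: np.ndarray
    n_psi: np.ndarray
    lam: np.ndarray
    a: np.ndarray
    c_s: float
    outlier_mu: np.ndarray
    outlier_sigma: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.atleast_2d(np.asarray(self.t, dtype=float))
        self.S = np.asarray(self.S, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)
        self.H = np.asarray(self.H, dtype=float)
        self.n_theta = np.asarray(self.n_theta, dtype=float).ravel()
        self.n_psi = np.asarray(self.n_psi, dtype=float).ravel()
        self.lam = np.asarray(self.lam, dtype=float).ravel()
        self.a = np.asarray(self.a, dtype=float).ravel()
        self.outlier_mu = np.asarray(self.outlier_mu, dtype=float).ravel()
        self.outlier_sigma = np.asarray(self.outlier_sigma, dtype=float)
        K, d = self.t.shape
        if self.a.shape != (K + 1,):
            raise InvalidParameterError("a must have length K+1")
        if np.any(self.n_theta <= d + 1):
            raise InvalidParameterError("n_theta entries must exceed d+1")
        if np.any(self.n_psi < d):
            raise InvalidParameterError("n_psi entries must be >= d")
        if self.c_s <= 0:
            raise InvalidParameterError("c_s must be positive")
        self._outlier_chol = spd_cholesky(self.outlier_sigma)

    @property
    def K(self) -> int:
        return self.t.shape[0]

    @property
    def d(self) -> int:
        return self.t.shape[1]

    @classmethod
    def from_data(cls, data: Sequence[SampleData], K: int, *,
                  latent_location_sd: float = 1.0,
                  between_sample_sd: float = 0.05,
                  n_theta_per_sample: float = 0.3,
                  within_cluster_var_frac: float = 0.1,
                  nu_prior_rate: float = 0.1,
                  a_outlier: float = 0.5,
                  a_component: float = 0.5,
                  c_s: float = 10.0,
                  outlier_sd_factor: float = 3.0) -> "PriorSpec":
        """Weakly informative priors derived from the pooled data.

        The location prior is centered at the pooled mean with sd
        ``latent_location_sd`` per marker (broad on percentile-scaled data).
        ``n_theta`` is expressed per sample and scaled by J internally so
        one configuration value has a comparable effect across dataset sizes.
        """
        pooled = np.vstack([s.events for s in data])
        d = pooled.shape[1]
        J = len(data)
        mean = pooled.mean(axis=0)
        var = pooled.var(axis=0)

        t = np.tile(mean, (K, 1))
        S = np.tile(np.diag(np.full(d, latent_location_sd ** 2)), (K, 1, 1))
        n_theta_k = d + 2.0 + n_theta_per_sample * J
        n_theta = np.full(K, n_theta_k)
        Q = np.tile(np.diag(np.full(d, between_sample_sd ** 2))
                    * (n_theta_k - d - 1.0), (K, 1, 1))
        # E[Psi_k] = n_psi * H ~ (nu0 - d - 1) * within-cluster covariance guess
        nu0 = d + 17.0
        within = np.diag(var * within_cluster_var_frac)
        n_psi = np.full(K, float(d))
        H = np.tile(within * (nu0 - d - 1.0) / d, (K, 1, 1))
        lam = np.full(K, nu_prior_rate)
        a = np.concatenate([[a_outlier], np.full(K, a_component)])
        outlier_sigma = np.diag((outlier_sd_factor * np.sqrt(var)) ** 2)
        return cls(t=t, S=S, Q=Q, n_theta=n_theta, H=H, n_psi=n_psi, lam=lam,
                   a=a, c_s=c_s, outlier_mu=mean, outlier_sigma=outlier_sigma)


def component_log_densities(Y: np.ndarray, mixture: SampleMixture,
                            priors: PriorSpec) -> np.ndarray:
    """(n, K+1) matrix of log[pi_jc N(y; mu_jc, Sigma_jc)], column 0 = outlier.

    Inactive components get -inf columns.  Shared workhorse of the mixture
    density and the assignment update; one Cholesky per component.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n = Y.shape[0]
    K = mixture.K
    logd = np.full((n, K + 1), -np.inf)
    w = mixture.weights
    if w[0] > 0:
        logd[:, 0] = np.log(w[0]) + mvn_logpdf(
            Y, priors.outlier_mu, chol=priors._outlier_chol)
    for k in range(K):
        if mixture.active[k] and w[k + 1] > 0:
            comp = mixture.components[k]
            logd[:, k + 1] = np.log(w[k + 1]) + mvn_logpdf(Y, comp.mu, chol=comp.chol)
    return logd


def log_mixture_density(y: np.ndarray, mixture: SampleMixture,
                        priors: PriorSpec) -> np.ndarray | float:
    """Log of the sample mixture density at one event (or each row of a matrix).

    Inactive components carry zero weight and contribute nothing.
    """
    y = np.asarray(y, dtype=float)
    single = y.ndim == 1
    out = logsumexp_rows(component_log_densities(y, mixture, priors))
    return float(out[0]) if single else out


def _nu_log_prior(nu: int, lam: float, d: int) -> float:
    """Unnormalized exponential prior mass on integers nu >= d+2."""
    if nu < d + 2:
        return -np.inf
    return -lam * nu


def log_joint_posterior(states: Sequence[SampleMixture],
                        latents: Sequence[LatentCluster],
                        priors: PriorSpec,
                        data: Sequence[SampleData]) -> float:
    """Joint log posterior of all parameters and assignments, up to a constant.

    Sums, over samples: the data log likelihood given assignments, the
    categorical log prior of assignments, the Eq-style Normal/inverse-Wishart
    priors of active component parameters given their latent cluster, the
    Dirichlet prior of the weights restricted to {outlier} + active set, and
    the activation penalty -c_s * sum(Z_j); over clusters: the latent
    hyper-priors of (theta_k, Sigma_theta_k, Psi_k, nu_k).

    Raises
    ------
    InvalidStateError
        If any sample has all components inactive.
    """
    total = 0.0
    K = priors.K
    for k, lat in enumerate(latents):
        chol_st = spd_cholesky(lat.sigma_theta)
        chol_psi = spd_cholesky(lat.psi)
        total += mvn_logpdf(lat.theta, priors.t[k], priors.S[k])
        total += invwishart_logpdf(lat.sigma_theta, priors.Q[k], priors.n_theta[k],
                                   chol_S=chol_st)
        total += wishart_logpdf(lat.psi, priors.H[k], priors.n_psi[k],
                                chol_W=chol_psi)
        total += _nu_log_prior(lat.nu, priors.lam[k], lat.d)

    for mix, sam in zip(states, data):
        if not np.any(mix.active):
            raise InvalidStateError(
                f"sample {sam.sample_id!r}: all activation flags are off")
        mix.validate()
        # data likelihood + categorical assignment prior
        logd = component_log_densities(sam.events, mix, priors)
        total += float(logd[np.arange(sam.n), mix.assignments].sum())
        # component priors given latent clusters (active components only)
        for k in range(K):
            if mix.active[k]:
                comp = mix.components[k]
                lat = latents[k]
                total += mvn_logpdf(comp.mu, lat.theta, lat.sigma_theta)
                total += invwishart_logpdf(comp.sigma, lat.psi, lat.nu,
                                           chol_S=comp.chol)
        # Dirichlet prior of weights restricted to {0} + active set
        idx = np.concatenate([[0], 1 + np.flatnonzero(mix.active)])
        total += dirichlet_logpdf(mix.weights[idx], priors.a[idx])
        # activation prior (unnormalized, as printed)
        total += -priors.c_s * float(np.sum(mix.active))
    return total
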