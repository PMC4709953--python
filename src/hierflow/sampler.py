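"""MCMC inference for the hierarchical mixture model.

Blocked Gibbs sampling with conjugate conditionals for component and
latent-cluster parameters, a Metropolis step for the integer inverse-Wishart
degrees of freedom, reversible-jump moves for component activation, optional
label-switching moves, a five-phase burn-in schedule, and posterior-
predictive draws during production.

The reversible-jump birth move draws new component parameters from their
hierarchical prior and the new weight from the Dirichlet stick-breaking
conditional, so all proposal and Jacobian factors cancel and the acceptance
ratio reduces to exp(-c_s) * (1 - v)^n_j for a birth (mirrored for a death
of an empty component).  Deaths of components with assigned cells, and
moves that would leave a sample with no active component, are rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.mixture import GaussianMixture

from ._linalg import cho_inverse, spd_cholesky
from .model import (
    ComponentParams,
    LatentCluster,
    PriorSpec,
    SampleData,
    SampleMixture,
    component_log_densities,
    log_joint_posterior,
)

logger = logging.getLogger(__name__)

__all__ = [
    "McmcConfig",
    "McmcTrace",
    "ModelState",
    "initialize",
    "run_mcmc",
    "update_assignments",
    "update_component_params",
    "update_latent_params",
    "update_nu",
    "update_weights",
    "update_activation",
]

#: burn-in phase lengths are proportional to these (they sum to 16)
PHASE_PROPORTIONS = (4, 4, 1, 3, 4)


@dataclass
class McmcConfig:
    """Run settings for the sampler.

    ``phase_boundaries`` are cumulative iteration counts ending each of the
    five burn-in phases; if omitted they are derived from ``n_burnin`` in
    the proportions 4:4:1:3:4.  Phase 1 tightens the location/shape priors
    (``n_theta`` multiplied and ``Q`` divided by ``phase1_tighten``) to
    force corresponding components together; outlier-like components (total
    assignment fraction below ``outlier_off_threshold``) are switched off at
    the end of phase 2 and frozen during phase 3; activation moves run from
    phase 4 onward; label-switching moves are allowed during phases 1-4.
    """

    n_burnin: int = 1000
    n_production: int = 1000
    phase_boundaries: Optional[tuple[int, int, int, int, int]] = None
    seed: int = 0
    nu_step: int = 2
    label_switch_allowed_until: int = 4
    activation_moves_per_iter: int = 1
    phase1_tighten: float = 10.0
    outlier_off_threshold: float = 1e-4
    n_ppc_per_iter: int = 1
    store_component_params: bool = True
    diagonal_covariance: bool = False
    logpost_check_every: int = 500

    def boundaries(self) -> tuple[int, ...]:
        if self.phase_boundaries is not None:
            b = tuple(self.phase_boundaries)
            if list(b) != sorted(b) or b[-1] != self.n_burnin:
                raise ValueError("phase boundaries must increase and end at n_burnin")
            return b
        total = sum(PHASE_PROPORTIONS)
        cum = np.cumsum(PHASE_PROPORTIONS) / total
        b = [int(round(c * self.n_burnin)) for c in cum]
        b[-1] = self.n_burnin
        return tuple(b)


@dataclass
class ModelState:
    """All model variables at one MCMC iteration."""

    latents: list[LatentCluster]
    mixtures: list[SampleMixture]

    @property
    def K(self) -> int:
        return len(self.latents)

    def copy(self) -> "ModelState":
        return ModelState([l.copy() for l in self.latents],
                          [m.copy() for m in self.mixtures])


@dataclass
class McmcTrace:
    """Stored production draws, soft clustering and posterior predictive."""

    theta: np.ndarray          # (T, K, d)
    sigma_theta: np.ndarray    # (T, K, d, d)
    psi: np.ndarray            # (T, K, d, d)
    nu: np.ndarray             # (T, K)
    weights: np.ndarray        # (T, J, K+1)
    active: np.ndarray         # (T, J, K)
    mu: Optional[np.ndarray]   # (T, J, K, d)
    sigma: Optional[np.ndarray]  # (T, J, K, d, d)
    responsibilities: list[np.ndarray]  # per sample (n_j, K+1), averaged
    ppc: list[np.ndarray]      # per sample (T * n_ppc_per_iter, d)
    log_post: np.ndarray       # (T,)
    sample_ids: list[str]

    @property
    def n_iterations(self) -> int:
        return self.theta.shape[0]

    @property
    def K(self) -> int:
        return self.theta.shape[1]

    def activation_probability(self) -> np.ndarray:
        """(J, K) posterior probability that component k is active in j."""
        return self.active.mean(axis=0)

    def posterior_mean_mu(self) -> np.ndarray:
        """(J, K, d) posterior mean component centers over iterations where
        the component was active (NaN where never active)."""
        act = self.active[..., None].astype(float)
        s = (self.mu * act).sum(axis=0)
        n = act.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, s / np.maximum(n, 1e-12), np.nan)

    def soft_clustering(self) -> np.ndarray:
        """Pooled (sum n_j, K+1) responsibilities averaged over production."""
        return np.vstack(self.responsibilities)


# ---------------------------------------------------------------------------
# conditional posterior parameters (exposed for oracle tests)
# ---------------------------------------------------------------------------

def mu_conditional(theta, sigma_theta, sigma_jk, n_jk, ybar):
    """Normal conditional of a component mean: returns (mean, covariance)."""
    st_inv = cho_inverse(np.asarray(sigma_theta, float))
    s_inv = cho_inverse(np.asarray(sigma_jk, float))
    prec = st_inv + n_jk * s_inv
    V = cho_inverse(prec)
    mean = V @ (st_inv @ np.asarray(theta, float)
                + n_jk * (s_inv @ np.asarray(ybar, float)))
    return mean, V


def sigma_conditional(psi, nu, scatter, n_jk):
    """Inverse-Wishart conditional of a component covariance: (scale, df)."""
    return np.asarray(psi, float) + np.asarray(scatter, float), nu + n_jk


def theta_conditional(t, S, sigma_theta, mus):
    """Normal conditional of a latent mean given the active component means."""
    S_inv = cho_inverse(np.asarray(S, float))
    st_inv = cho_inverse(np.asarray(sigma_theta, float))
    J_k = len(mus)
    prec = S_inv + J_k * st_inv
    V = cho_inverse(prec)
    mu_sum = np.sum(np.asarray(mus, float), axis=0) if J_k else np.zeros(len(t))
    mean = V @ (S_inv @ np.asarray(t, float) + st_inv @ mu_sum)
    return mean, V


def sigma_theta_conditional(Q, n_theta, theta, mus):
    """Inverse-Wishart conditional of the between-sample mean spread."""
    theta = np.asarray(theta, float)
    scatter = np.zeros((len(theta), len(theta)))
    for mu in mus:
        r = np.asarray(mu, float) - theta
        scatter += np.outer(r, r)
    return np.asarray(Q, float) + scatter, n_theta + len(mus)


def psi_conditional(H, n_psi, nu, sigmas):
    """Wishart conditional of the latent scale matrix: (scale, df)."""
    H = np.asarray(H, float)
    acc = cho_inverse(H)
    for sig in sigmas:
        acc = acc + cho_inverse(np.asarray(sig, float))
    return cho_inverse(acc), n_psi + len(sigmas) * nu


# ---------------------------------------------------------------------------
# Gibbs updates
# ---------------------------------------------------------------------------

def _sample_mvn(mean, cov, rng):
    chol = spd_cholesky(cov)
    return mean + chol @ rng.standard_normal(len(mean))


def _sample_invwishart(scale, df, rng, diagonal=False):
    if diagonal:
        # inverse-Wishart density restricted to diagonal matrices factorizes
        # into invgamma((df + d - 1)/2, scale_ii/2) per entry
        d = scale.shape[0]
        out = np.zeros_like(scale)
        for i in range(d):
            out[i, i] = stats.invgamma.rvs((df + d - 1) / 2.0,
                                           scale=scale[i, i] / 2.0,
                                           random_state=rng)
        return out
    out = stats.invwishart.rvs(df=df, scale=scale, random_state=rng)
    return np.asarray(out, dtype=float).reshape(scale.shape)


def responsibilities(sample: SampleData, mixture: SampleMixture,
                     priors: PriorSpec) -> np.ndarray:
    """(n_j, K+1) posterior assignment probabilities given current params."""
    logd = component_log_densities(sample.events, mixture, priors)
    m = logd.max(axis=1, keepdims=True)
    w = np.exp(logd - m)
    return w / w.sum(axis=1, keepdims=True)


def update_assignments(sample: SampleData, mixture: SampleMixture,
                       priors: PriorSpec, rng: np.random.Generator) -> None:
    """Draw each x_ij from its categorical conditional (log-sum-exp safe)."""
    logd = component_log_densities(sample.events, mixture, priors)
    gumb = rng.gumbel(size=logd.shape)
    mixture.assignments = np.argmax(logd + gumb, axis=1).astype(np.int64)


def update_weights(mixture: SampleMixture, priors: PriorSpec,
                   rng: np.random.Generator) -> None:
    """Dirichlet conditional over {outlier} + active components."""
    K = mixture.K
    counts = np.bincount(mixture.assignments, minlength=K + 1).astype(float)
    idx = np.concatenate([[0], 1 + np.flatnonzero(mixture.active)])
    draw = rng.dirichlet(priors.a[idx] + counts[idx])
    w = np.zeros(K + 1)
    w[idx] = draw
    mixture.weights = w


def update_component_params(sample: SampleData, mixture: SampleMixture,
                            latents: Sequence[LatentCluster],
                            rng: np.random.Generator,
                            diagonal: bool = False) -> None:
    """Conjugate update of (mu_jk, Sigma_jk) for every active component.

    Components with no assigned cells are redrawn from their hierarchical
    prior.  A singular posterior scale matrix is retried with jitter.
    """
    Y = sample.events
    x = mixture.assignments
    for k in np.flatnonzero(mixture.active):
        lat = latents[k]
        comp = mixture.components[k]
        sel = Y[x == k + 1]
        n_jk = sel.shape[0]
        if n_jk == 0:
            mu = _sample_mvn(lat.theta, lat.sigma_theta, rng)
            sig = _sample_invwishart(lat.psi, lat.nu, rng, diagonal)
            mixture.components[k] = ComponentParams(mu, sig)
            continue
        ybar = sel.mean(axis=0)
        mean, V = mu_conditional(lat.theta, lat.sigma_theta, comp.sigma,
                                 n_jk, ybar)
        mu = _sample_mvn(mean, V, rng)
        resid = sel - mu
        scatter = resid.T @ resid
        if diagonal:
            scatter = np.diag(np.diag(scatter))
        scale, df = sigma_conditional(lat.psi, lat.nu, scatter, n_jk)
        for attempt in range(3):
            try:
                sig = _sample_invwishart(scale, df, rng, diagonal)
                mixture.components[k] = ComponentParams(mu, sig)
                break
            except (np.linalg.LinAlgError, ValueError):
                logger.warning("jittering singular scale matrix (sample %s, k=%d)",
                               sample.sample_id, k)
                scale = scale + 1e-8 * np.eye(scale.shape[0]) * np.trace(scale)
        else:
            raise RuntimeError("could not sample component covariance")


def update_latent_params(state: ModelState, priors: PriorSpec,
                         rng: np.random.Generator,
                         diagonal: bool = False) -> None:
    """Conjugate updates of (theta_k, Sigma_theta_k, Psi_k), active samples only."""
    K = state.K
    for k in range(K):
        lat = state.latents[k]
        mus = [m.components[k].mu for m in state.mixtures if m.active[k]]
        sigmas = [m.components[k].sigma for m in state.mixtures if m.active[k]]
        mean, V = theta_conditional(priors.t[k], priors.S[k], lat.sigma_theta, mus)
        lat.theta = _sample_mvn(mean, V, rng)
        scale, df = sigma_theta_conditional(priors.Q[k], priors.n_theta[k],
                                            lat.theta, mus)
        if diagonal:
            scale = np.diag(np.diag(scale))
        lat.sigma_theta = _sample_invwishart(scale, df, rng, diagonal)
        w_scale, w_df = psi_conditional(priors.H[k], priors.n_psi[k], lat.nu,
                                        sigmas)
        if diagonal:
            w_scale = np.diag(np.diag(w_scale))
            d = w_scale.shape[0]
            psi = np.zeros_like(w_scale)
            for i in range(d):
                psi[i, i] = stats.gamma.rvs((w_df - d + 1) / 2.0,
                                            scale=2.0 * w_scale[i, i],
                                            random_state=rng)
            lat.psi = psi
        else:
            draw = stats.wishart.rvs(df=w_df, scale=w_scale, random_state=rng)
            lat.psi = np.asarray(draw, dtype=float).reshape(w_scale.shape)


def _iw_logpdf_nu_terms(sigmas_logdet, psi_logdet, psi_tr, nu, d):
    """Sum of IW(Sigma_jk; Psi, nu) log densities as a function of nu only."""
    from scipy.special import multigammaln

    J = len(sigmas_logdet)
    return (0.5 * nu * psi_logdet * J
            - 0.5 * nu * d * np.log(2.0) * J
            - J * multigammaln(0.5 * nu, d)
            - 0.5 * (nu + d + 1.0) * np.sum(sigmas_logdet)
            - 0.5 * np.sum(psi_tr))


def nu_log_conditional(nu: int, k: int, state: ModelState,
                       priors: PriorSpec) -> float:
    """Unnormalized log conditional mass of nu_k at an integer nu >= d+2."""
    lat = state.latents[k]
    d = lat.d
    if nu < d + 2:
        return -np.inf
    chol_psi = spd_cholesky(lat.psi)
    psi_logdet = 2.0 * np.sum(np.log(np.diag(chol_psi)))
    lds, trs = [], []
    from scipy.linalg import solve_triangular
    for m in state.mixtures:
        if m.active[k]:
            comp = m.components[k]
            lds.append(2.0 * np.sum(np.log(np.diag(comp.chol))))
            A = solve_triangular(comp.chol, chol_psi, lower=True)
            trs.append(float(np.sum(A * A)))
    return (-priors.lam[k] * nu
            + _iw_logpdf_nu_terms(np.array(lds), psi_logdet, np.array(trs),
                                  float(nu), d))


def update_nu(state: ModelState, priors: PriorSpec,
              rng: np.random.Generator, step: int = 2) -> int:
    """Metropolis update of every nu_k on the integers >= d+2.

    Proposes nu' = nu +/- U{1..step}; proposals below the support are
    rejected.  Returns the number of accepted moves.
    """
    accepted = 0
    for k in range(state.K):
        lat = state.latents[k]
        delta = int(rng.integers(1, step + 1)) * (1 if rng.random() < 0.5 else -1)
        prop = lat.nu + delta
        if prop < lat.d + 2:
            continue
        cur = nu_log_conditional(lat.nu, k, state, priors)
        new = nu_log_conditional(prop, k, state, priors)
        if np.log(rng.random()) < new - cur:
            lat.nu = prop
            accepted += 1
    return accepted


def update_activation(j: int, state: ModelState, priors: PriorSpec,
                      rng: np.random.Generator, n_moves: int = 1) -> None:
    """Reversible-jump toggles of the activation flags Z_j for sample j.

    Birth: draw (mu, Sigma) from the hierarchical prior, draw the new
    weight v from the stick-breaking Beta conditional and rescale the
    existing weights by (1 - v); acceptance = exp(-c_s) (1-v)^{n_j}.
    Death (empty components only): remove the component, renormalize;
    acceptance = exp(+c_s) (1-pi_jk)^{-n_j}.  A death that would leave the
    sample with no active component is rejected outright.
    """
    mix = state.mixtures[j]
    K = mix.K
    n_j = mix.assignments.shape[0]
    counts = np.bincount(mix.assignments, minlength=K + 1)
    for _ in range(n_moves):
        k = int(rng.integers(K))
        if mix.active[k]:
            # death proposal
            if counts[k + 1] > 0:
                continue  # likelihood of assigned cells would vanish
            if mix.active.sum() <= 1:
                continue  # indicator I(sum Z > 0)
            v = mix.weights[k + 1]
            log_alpha = priors.c_s - n_j * np.log1p(-min(v, 1 - 1e-12))
            if np.log(rng.random()) < log_alpha:
                mix.active[k] = False
                w = mix.weights.copy()
                w[k + 1] = 0.0
                mix.weights = w / w.sum()
        else:
            # birth proposal
            lat = state.latents[k]
            idx = np.concatenate([[0], 1 + np.flatnonzero(mix.active)])
            a_rest = priors.a[idx].sum()
            v = rng.beta(priors.a[k + 1], a_rest)
            log_alpha = -priors.c_s + n_j * np.log1p(-v)
            if np.log(rng.random()) < log_alpha:
                mu = _sample_mvn(lat.theta, lat.sigma_theta, rng)
                sig = _sample_invwishart(lat.psi, lat.nu, rng)
                mix.components[k] = ComponentParams(mu, sig)
                mix.active[k] = True
                w = mix.weights * (1.0 - v)
                w[k + 1] = v
                mix.weights = w / w.sum()


def label_switch_move(j: int, state: ModelState, priors: PriorSpec,
                      rng: np.random.Generator) -> bool:
    """Metropolis swap of two components' full per-sample blocks.

    Swapping (mu, Sigma, weight, activation, assignments) of components k
    and l within one sample changes only the latent-prior and weight-prior
    factors, giving a cheap symmetric move that relinks sample components
    to different latent clusters to escape labeling minima.
    """
    from ._linalg import invwishart_logpdf, mvn_logpdf

    mix = state.mixtures[j]
    K = mix.K
    if K < 2:
        return False
    k, l = rng.choice(K, size=2, replace=False)
    lat_k, lat_l = state.latents[k], state.latents[l]

    def block_logp(comp, active, lat):
        if not active:
            return 0.0
        return (mvn_logpdf(comp.mu, lat.theta, lat.sigma_theta)
                + invwishart_logpdf(comp.sigma, lat.psi, lat.nu,
                                    chol_S=comp.chol))

    cur = (block_logp(mix.components[k], mix.active[k], lat_k)
           + block_logp(mix.components[l], mix.active[l], lat_l))
    new = (block_logp(mix.components[k], mix.active[k], lat_l)
           + block_logp(mix.components[l], mix.active[l], lat_k))
    # Dirichlet prior of the weights under the current vs swapped active set
    from ._linalg import dirichlet_logpdf

    idx_cur = np.concatenate([[0], 1 + np.flatnonzero(mix.active)])
    act_new = mix.active.copy()
    act_new[k], act_new[l] = act_new[l], act_new[k]
    idx_new = np.concatenate([[0], 1 + np.flatnonzero(act_new)])
    w_new = mix.weights.copy()
    w_new[k + 1], w_new[l + 1] = w_new[l + 1], w_new[k + 1]
    cur += dirichlet_logpdf(mix.weights[idx_cur], priors.a[idx_cur])
    new += dirichlet_logpdf(w_new[idx_new], priors.a[idx_new])
    if np.log(rng.random()) < new - cur:
        mix.components[k], mix.components[l] = mix.components[l], mix.components[k]
        w = mix.weights.copy()
        w[k + 1], w[l + 1] = w[l + 1], w[k + 1]
        mix.weights = w
        act = mix.active.copy()
        act[k], act[l] = act[l], act[k]
        mix.active = act
        x = mix.assignments
        sel_k = x == k + 1
        sel_l = x == l + 1
        x[sel_k] = l + 1
        x[sel_l] = k + 1
        return True
    return False


# ---------------------------------------------------------------------------
# initialization and the full run
# ---------------------------------------------------------------------------

def initialize(data: Sequence[SampleData], K: int, priors: PriorSpec,
               rng: np.random.Generator, *,
               subsample: int = 20000,
               informative: Optional[dict[int, tuple[np.ndarray, np.ndarray]]] = None,
               n_init: int = 5,
               max_retries: int = 3) -> ModelState:
    """EM initialization on pooled data.

    Fits a K-component Gaussian mixture (EM) to a subsample of the pooled
    events; latent means start at the EM means, per-sample components start
    at the latent values.  ``informative`` optionally overrides the start of
    selected components with a user-supplied (mean, covariance), e.g. for a
    population identified in a scatter plot.
    """
    pooled = np.vstack([s.events for s in data])
    d = pooled.shape[1]
    if pooled.shape[0] > subsample:
        sel = rng.choice(pooled.shape[0], size=subsample, replace=False)
        pooled_fit = pooled[sel]
    else:
        pooled_fit = pooled
    for attempt in range(max_retries):
        gm = GaussianMixture(n_components=K, covariance_type="full",
                             n_init=n_init, reg_covar=1e-6,
                             random_state=int(rng.integers(2**31 - 1)))
        gm.fit(pooled_fit)
        if np.all(np.isfinite(gm.means_)) and np.all(gm.weights_ > 1e-12):
            break
        logger.warning("degenerate EM fit, re-seeding (attempt %d)", attempt + 1)
    means = gm.means_
    covs = gm.covariances_
    weights = gm.weights_
    if informative:
        for k, (mu0, sig0) in informative.items():
            means[k] = np.asarray(mu0, float)
            covs[k] = np.asarray(sig0, float)

    nu0 = d + 17
    latents = []
    for k in range(K):
        latents.append(LatentCluster(
            theta=means[k].copy(),
            sigma_theta=np.diag(np.full(d, 0.05 ** 2)),
            psi=covs[k] * (nu0 - d - 1),
            nu=nu0,
        ))
    mixtures = []
    for s in data:
        comps = [ComponentParams(means[k].copy(), covs[k].copy())
                 for k in range(K)]
        w = np.concatenate([[0.01], weights * 0.99])
        mix = SampleMixture(components=comps, weights=w / w.sum(),
                            active=np.ones(K, bool),
                            assignments=np.zeros(s.n, np.int64))
        mixtures.append(mix)
    state = ModelState(latents, mixtures)
    for j, s in enumerate(data):
        update_assignments(s, state.mixtures[j], priors, rng)
    return state


def _tightened_priors(priors: PriorSpec, factor: float) -> PriorSpec:
    """Phase-1 priors: force component means together across samples."""
    return PriorSpec(t=priors.t, S=priors.S, Q=priors.Q / factor,
                     n_theta=priors.n_theta * factor, H=priors.H,
                     n_psi=priors.n_psi, lam=priors.lam, a=priors.a,
                     c_s=priors.c_s, outlier_mu=priors.outlier_mu,
                     outlier_sigma=priors.outlier_sigma)


def _gibbs_sweep(state: ModelState, data, priors, rng, cfg,
                 allow_activation: bool, allow_label_switch: bool) -> None:
    for j, s in enumerate(data):
        mix = state.mixtures[j]
        update_assignments(s, mix, priors, rng)
        update_weights(mix, priors, rng)
        update_component_params(s, mix, state.latents, rng,
                                diagonal=cfg.diagonal_covariance)
    update_latent_params(state, priors, rng, diagonal=cfg.diagonal_covariance)
    update_nu(state, priors, rng, step=cfg.nu_step)
    if allow_activation:
        for j in range(len(data)):
            update_activation(j, state, priors, rng,
                              n_moves=cfg.activation_moves_per_iter)
    if allow_label_switch:
        for j in range(len(data)):
            label_switch_move(j, state, priors, rng)


def _turn_off_outlier_components(state: ModelState, data, priors, rng,
                                 threshold: float) -> None:
    """Deactivate components whose pooled assignment fraction is negligible."""
    total = sum(s.n for s in data)
    K = state.K
    counts = np.zeros(K)
    for j, s in enumerate(data):
        c = np.bincount(state.mixtures[j].assignments, minlength=K + 1)
        counts += c[1:]
    off = counts / total < threshold
    if not off.any():
        return
    logger.info("turning off %d outlier-like component(s)", int(off.sum()))
    for j, s in enumerate(data):
        mix = state.mixtures[j]
        keep = mix.active & ~off
        if not keep.any():
            continue  # never leave a sample with no active component
        mix.active = keep
        w = mix.weights.copy()
        w[1:][~keep] = 0.0
        mix.weights = w / w.sum()
        update_assignments(s, mix, priors, rng)


def _draw_posterior_predictive(state: ModelState, priors, rng, n_events: int,
                               j: int) -> np.ndarray:
    mix = state.mixtures[j]
    d = priors.d
    out = np.empty((n_events, d))
    comps = rng.choice(mix.K + 1, size=n_events, p=mix.weights)
    for i, c in enumerate(comps):
        if c == 0:
            out[i] = _sample_mvn(priors.outlier_mu, priors.outlier_sigma, rng)
        else:
            comp = mix.components[c - 1]
            out[i] = comp.mu + comp.chol @ rng.standard_normal(d)
    return out


def run_mcmc(data: Sequence[SampleData], priors: PriorSpec, config: McmcConfig,
             state: Optional[ModelState] = None, K: Optional[int] = None,
             callback: Optional[Callable[[int, ModelState], None]] = None) -> McmcTrace:
    """Run the five-phase burn-in followed by production sampling.

    Phase 1 tightens the location/shape priors to force corresponding
    components together; phase 2 restores them; at the end of phase 2
    outlier-like components are switched off; phase 3 keeps activations
    frozen; phases 4-5 (and production) allow activation moves.  Label
    switching is proposed during the first four phases only.  Every
    production iteration stores the latent and component parameters,
    accumulates assignment responsibilities, and draws posterior-predictive
    events.
    """
    rng = np.random.default_rng(config.seed)
    if state is None:
        if K is None:
            raise ValueError("either an initial state or K must be given")
        state = initialize(data, K, priors, rng)
    K = state.K
    d = priors.d
    J = len(data)
    bounds = config.boundaries()
    tight = _tightened_priors(priors, config.phase1_tighten)

    def check_finite(it: int) -> None:
        lp = log_joint_posterior(state.mixtures, state.latents, priors, data)
        if not np.isfinite(lp):
            dump = {
                "iteration": it,
                "theta": [l.theta.tolist() for l in state.latents],
                "nu": [l.nu for l in state.latents],
                "weights": [m.weights.tolist() for m in state.mixtures],
            }
            raise RuntimeError(f"non-finite log posterior at iteration {it}: {dump}")

    for it in range(config.n_burnin):
        phase = int(np.searchsorted(bounds, it, side="right")) + 1
        pri = tight if phase == 1 else priors
        allow_act = phase >= 4
        allow_ls = phase <= config.label_switch_allowed_until
        _gibbs_sweep(state, data, pri, rng, config, allow_act, allow_ls)
        if it + 1 == bounds[1]:
            _turn_off_outlier_components(state, data, priors, rng,
                                         config.outlier_off_threshold)
        if config.logpost_check_every and (it + 1) % config.logpost_check_every == 0:
            check_finite(it)
        if callback is not None:
            callback(it - config.n_burnin, state)

    T = config.n_production
    theta_tr = np.empty((T, K, d))
    st_tr = np.empty((T, K, d, d))
    psi_tr = np.empty((T, K, d, d))
    nu_tr = np.empty((T, K), dtype=np.int64)
    w_tr = np.empty((T, J, K + 1))
    act_tr = np.empty((T, J, K), dtype=bool)
    if config.store_component_params:
        mu_tr = np.empty((T, J, K, d))
        sig_tr = np.empty((T, J, K, d, d))
    else:
        mu_tr = sig_tr = None
    resp = [np.zeros((s.n, K + 1)) for s in data]
    ppc = [np.empty((T * config.n_ppc_per_iter, d)) for _ in data]
    lp_tr = np.full(T, np.nan)

    for t in range(T):
        _gibbs_sweep(state, data, priors, rng, config,
                     allow_activation=True, allow_label_switch=False)
        for k in range(K):
            lat = state.latents[k]
            theta_tr[t, k] = lat.theta
            st_tr[t, k] = lat.sigma_theta
            psi_tr[t, k] = lat.psi
            nu_tr[t, k] = lat.nu
        for j, s in enumerate(data):
            mix = state.mixtures[j]
            w_tr[t, j] = mix.weights
            act_tr[t, j] = mix.active
            if config.store_component_params:
                for k in range(K):
                    mu_tr[t, j, k] = mix.components[k].mu
                    sig_tr[t, j, k] = mix.components[k].sigma
            resp[j] += responsibilities(s, mix, priors)
            n_ppc = config.n_ppc_per_iter
            ppc[j][t * n_ppc:(t + 1) * n_ppc] = _draw_posterior_predictive(
                state, priors, rng, n_ppc, j)
        if config.logpost_check_every and (t + 1) % config.logpost_check_every == 0:
            lp_tr[t] = log_joint_posterior(state.mixtures, state.latents,
                                           priors, data)
            if not np.isfinite(lp_tr[t]):
                check_finite(config.n_burnin + t)
        if callback is not None:
            callback(t, state)

    for j in range(J):
        resp[j] /= T
    return McmcTrace(theta=theta_tr, sigma_theta=st_tr, psi=psi_tr, nu=nu_tr,
                     weights=w_tr, active=act_tr, mu=mu_tr, sigma=sig_tr,
                     responsibilities=resp, ppc=ppc, log_post=lp_tr,
                     sample_ids=[s.sample_id for s in data])
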