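"""Gibbs sampler: conjugate conditionals, Metropolis steps, reversible
jump, initialization and run bookkeeping."""

import numpy as np
import pytest
from scipy import stats

from hierflow.model import (ComponentParams, LatentCluster, PriorSpec,
                            SampleData, SampleMixture, log_joint_posterior)
from hierflow.sampler import (McmcConfig, ModelState, initialize,
                              mu_conditional, nu_log_conditional,
                              psi_conditional, responsibilities, run_mcmc,
                              sigma_conditional, sigma_theta_conditional,
                              theta_conditional, update_activation,
                              update_assignments, update_component_params,
                              update_nu, update_weights)

from conftest import make_mixture_1d, make_priors_1d


class TestConditionalClosedForms:
    def test_mu_normal_normal_update(self):
        mean, V = mu_conditional([0.0], [[1.0]], [[1.0]], 4, [1.0])
        assert mean[0] == pytest.approx(0.8)
        assert V[0, 0] == pytest.approx(0.2)

    def test_sigma_inverse_wishart_update(self):
        scale, df = sigma_conditional([[1.0]], 5, [[2.0]], 10)
        assert scale[0, 0] == pytest.approx(3.0)
        assert df == 15
        # posterior mean of a 1-D IW(3, 15) is 3 / (15 - 2)
        assert scale[0, 0] / (df - 2) == pytest.approx(3 / 13)

    def test_theta_flat_prior_concentrates_on_common_mean(self):
        mus = [np.array([2.0])] * 6
        mean, V = theta_conditional([0.0], [[1e8]], [[1e-6]], mus)
        assert mean[0] == pytest.approx(2.0, abs=1e-4)
        assert V[0, 0] < 1e-6

    def test_psi_wishart_dof_bookkeeping(self):
        sigmas = [np.eye(2)] * 5
        _, df = psi_conditional(np.eye(2), 2.0, 7, sigmas)
        assert df == 2.0 + 5 * 7


class TestGridOracles:
    """Closed-form conditionals vs brute-force discretized posteriors (d=1)."""

    @staticmethod
    def _cdf_gap(grid, log_dens, closed_cdf):
        dens = np.exp(log_dens - log_dens.max())
        cdf = np.cumsum(dens)
        cdf /= cdf[-1]
        return np.max(np.abs(cdf - closed_cdf(grid)))

    def test_theta_conditional_matches_grid(self):
        t, S, st = 0.3, 2.0, 0.25
        mus = [np.array([1.2]), np.array([0.9]), np.array([1.4])]
        mean, V = theta_conditional([t], [[S]], [[st]], mus)
        grid = np.linspace(-3, 4, 20001)
        logd = stats.norm.logpdf(grid, t, np.sqrt(S))
        for mu in mus:
            logd += stats.norm.logpdf(mu[0], grid, np.sqrt(st))
        gap = self._cdf_gap(grid, logd,
                            lambda g: stats.norm.cdf(g, mean[0], np.sqrt(V[0, 0])))
        assert gap < 0.01

    def test_mu_conditional_matches_grid(self):
        theta, st, sig = 0.5, 0.3, 0.8
        y = np.array([0.2, 1.1, 0.7, -0.3, 0.9])
        mean, V = mu_conditional([theta], [[st]], [[sig]], len(y), [y.mean()])
        grid = np.linspace(-3, 4, 20001)
        logd = stats.norm.logpdf(grid, theta, np.sqrt(st))
        for yi in y:
            logd += stats.norm.logpdf(yi, grid, np.sqrt(sig))
        gap = self._cdf_gap(grid, logd,
                            lambda g: stats.norm.cdf(g, mean[0], np.sqrt(V[0, 0])))
        assert gap < 0.01

    def test_sigma_conditional_matches_grid(self):
        psi, nu = 0.6, 6
        y = np.array([0.2, -0.4, 0.5, 0.1])
        mu = 0.1
        scatter = np.sum((y - mu) ** 2)
        scale, df = sigma_conditional([[psi]], nu, [[scatter]], len(y))
        grid = np.linspace(1e-3, 5, 40001)
        logd = stats.invwishart.logpdf(grid, df=nu, scale=psi)
        for yi in y:
            logd += stats.norm.logpdf(yi, mu, np.sqrt(grid))
        # 1-D inverse Wishart is inverse-gamma(df/2, scale/2)
        gap = self._cdf_gap(grid, logd,
                            lambda g: stats.invgamma.cdf(g, a=df / 2,
                                                         scale=scale[0, 0] / 2))
        assert gap < 0.01


class TestJointConsistency:
    """Each conditional agrees with differences of the joint log posterior."""

    def _state(self, rng):
        y = rng.normal(size=(6, 1))
        data = [SampleData(y, "s0")]
        priors = make_priors_1d(K=2)
        lats = [LatentCluster([0.0], [[0.2]], [[0.6]], 6),
                LatentCluster([1.0], [[0.3]], [[0.8]], 7)]
        mix = make_mixture_1d([0.1, 0.9], [0.5, 0.7], [0.5, 0.4],
                              outlier_weight=0.1, n=6)
        mix.assignments = np.array([1, 2, 1, 0, 2, 1])
        return data, priors, lats, [mix]

    def test_theta_perturbation(self, rng):
        data, priors, lats, mixes = self._state(rng)
        mus = [mixes[0].components[0].mu]
        mean, V = theta_conditional(priors.t[0], priors.S[0],
                                    lats[0].sigma_theta, mus)
        lp1 = log_joint_posterior(mixes, lats, priors, data)
        lats2 = [lats[0].copy(), lats[1].copy()]
        lats2[0].theta = np.array([0.45])
        lp2 = log_joint_posterior(mixes, lats2, priors, data)
        expected = (stats.norm.logpdf(0.45, mean[0], np.sqrt(V[0, 0]))
                    - stats.norm.logpdf(0.0, mean[0], np.sqrt(V[0, 0])))
        assert lp2 - lp1 == pytest.approx(expected, abs=1e-8)

    def test_nu_conditional_matches_joint_difference(self, rng):
        data, priors, lats, mixes = self._state(rng)
        state = ModelState(lats, mixes)
        c1 = nu_log_conditional(6, 0, state, priors)
        c2 = nu_log_conditional(9, 0, state, priors)
        lp1 = log_joint_posterior(mixes, lats, priors, data)
        lats2 = [lats[0].copy(), lats[1].copy()]
        lats2[0].nu = 9
        lp2 = log_joint_posterior(mixes, lats2, priors, data)
        assert lp2 - lp1 == pytest.approx(c2 - c1, abs=1e-8)

    def test_weight_perturbation_matches_dirichlet_conditional(self, rng):
        data, priors, lats, mixes = self._state(rng)
        mix = mixes[0]
        counts = np.bincount(mix.assignments, minlength=3).astype(float)
        alpha = priors.a + counts
        w1 = mix.weights.copy()
        w2 = np.array([0.15, 0.35, 0.5])
        lp1 = log_joint_posterior(mixes, lats, priors, data)
        mix.weights = w2
        lp2 = log_joint_posterior(mixes, lats, priors, data)
        mix.weights = w1
        expected = (stats.dirichlet.logpdf(w2, alpha)
                    - stats.dirichlet.logpdf(w1, alpha))
        assert lp2 - lp1 == pytest.approx(expected, abs=1e-8)


class TestAssignments:
    def test_symmetric_components_split_evenly(self, rng):
        mix = make_mixture_1d([0.0, 0.0], [1.0, 1.0], [0.5, 0.5], n=4000)
        priors = make_priors_1d(K=2)
        data = SampleData(rng.normal(size=(4000, 1)), "s")
        update_assignments(data, mix, priors, rng)
        frac = np.mean(mix.assignments == 1)
        assert frac == pytest.approx(0.5, abs=0.03)

    def test_categorical_mass_for_separated_components(self):
        mix = make_mixture_1d([0.0, 4.0], [1.0, 1.0], [0.5, 0.5])
        priors = make_priors_1d(K=2)
        data = SampleData(np.array([[0.0]]), "s")
        r = responsibilities(data, mix, priors)
        assert r[0, 1] == pytest.approx(1 / (1 + np.exp(-8)), rel=1e-6)

    def test_inactive_component_never_selected(self, rng):
        mix = make_mixture_1d([0.0, 0.0], [1.0, 1.0], [1.0, 0.0],
                              active=[True, False], n=500)
        priors = make_priors_1d(K=2)
        data = SampleData(rng.normal(size=(500, 1)), "s")
        update_assignments(data, mix, priors, rng)
        assert not np.any(mix.assignments == 2)


class TestComponentUpdate:
    def test_empty_component_redrawn_from_prior(self, rng):
        """With no assigned cells the draw distribution is the prior."""
        lat = LatentCluster([2.0], [[0.5]], [[1.2]], 8)
        priors = make_priors_1d(K=1)
        data = SampleData(np.zeros((5, 1)), "s")
        draws = []
        for _ in range(400):
            mix = make_mixture_1d([0.0], [1.0], [1.0], n=5)
            mix.assignments = np.zeros(5, np.int64)  # all outlier... none to k
            update_component_params(data, mix, [lat], rng)
            draws.append(mix.components[0].mu[0])
        # two-sided KS against N(2, 0.5)
        stat, p = stats.kstest(draws, lambda x: stats.norm.cdf(x, 2.0,
                                                               np.sqrt(0.5)))
        assert p > 0.01


class TestNuUpdate:
    def test_stationary_distribution_matches_enumeration(self, rng):
        """Single sample, d=1: MH chain over nu matches the normalized mass."""
        lam = 0.15
        psi = 1.4
        sig = 0.9
        lat = LatentCluster([0.0], [[0.2]], [[psi]], 6)
        mix = make_mixture_1d([0.0], [sig], [1.0], n=1)
        state = ModelState([lat], [mix])
        priors = make_priors_1d(K=1, lam=lam)
        # brute-force normalized mass on {3, ..., 80}
        support = np.arange(3, 81)
        logm = np.array([-lam * v + stats.invwishart.logpdf(sig, df=v, scale=psi)
                         for v in support])
        mass = np.exp(logm - logm.max())
        mass /= mass.sum()
        draws = []
        for _ in range(6000):
            update_nu(state, priors, rng, step=3)
            draws.append(state.latents[0].nu)
        counts = np.bincount(draws, minlength=81)[3:81]
        # chi-square over bins with decent expectation
        exp = mass * len(draws)
        keep = exp >= 5
        chi2 = np.sum((counts[keep] - exp[keep]) ** 2 / exp[keep])
        dof = keep.sum() - 1
        # autocorrelated draws inflate chi2; allow a generous factor
        assert chi2 < 12 * dof

    def test_proposal_below_support_rejected(self, rng):
        lat = LatentCluster([0.0], [[0.2]], [[1.0]], 3)  # at the boundary d+2
        mix = make_mixture_1d([0.0], [1.0], [1.0])
        state = ModelState([lat], [mix])
        priors = make_priors_1d(K=1, lam=50.0)  # heavy prior favors small nu
        for _ in range(200):
            update_nu(state, priors, rng, step=1)
            assert state.latents[0].nu >= 3

    def test_huge_rate_collapses_to_minimum(self, rng):
        lat = LatentCluster([0.0], [[0.2]], [[1.0]], 10)
        mix = make_mixture_1d([0.0], [1.0], [1.0])
        state = ModelState([lat], [mix])
        priors = make_priors_1d(K=1, lam=60.0)
        for _ in range(300):
            update_nu(state, priors, rng, step=2)
        assert state.latents[0].nu == 3


class TestActivation:
    def _one_sample_state(self, y, active=(True, True), weights=(0.45, 0.45)):
        lats = [LatentCluster([0.0], [[0.3]], [[0.5]], 6),
                LatentCluster([3.0], [[0.3]], [[0.5]], 6)]
        mix = make_mixture_1d([0.0, 3.0], [0.5, 0.5], list(weights),
                              outlier_weight=0.1, active=list(active),
                              n=len(y))
        data = SampleData(np.asarray(y, float)[:, None], "s")
        return ModelState(lats, [mix]), data

    def test_only_active_component_never_deactivated(self, rng):
        state, data = self._one_sample_state([0.1, -0.2], active=(True, False),
                                             weights=(0.9, 0.0))
        state.mixtures[0].assignments = np.zeros(2, np.int64)
        priors = make_priors_1d(K=2, c_s=0.1)
        for _ in range(300):
            update_activation(0, state, priors, rng)
            assert state.mixtures[0].active.any()
            assert state.mixtures[0].active[0] or state.mixtures[0].active[1]

    def test_component_with_assigned_cells_cannot_die(self, rng):
        state, data = self._one_sample_state([0.1, 3.2, 2.9])
        state.mixtures[0].assignments = np.array([1, 2, 2])
        priors = make_priors_1d(K=2, c_s=0.01)
        for _ in range(300):
            update_activation(0, state, priors, rng)
        assert state.mixtures[0].active.all()

    def test_planted_empty_cluster_rarely_active(self, rng):
        """With a strong activation penalty, a cluster with no cells stays
        off: posterior activation probability below 0.05."""
        y = rng.normal(0.0, 0.7, size=40)
        state, data = self._one_sample_state(y)
        mix = state.mixtures[0]
        priors = make_priors_1d(K=2, c_s=8.0)
        on = 0
        total = 2000
        for it in range(total):
            update_assignments(data, mix, priors, rng)
            update_weights(mix, priors, rng)
            update_component_params(data, mix, state.latents, rng)
            update_activation(0, state, priors, rng)
            on += mix.active[1]
        assert on / total < 0.05


class TestInitialize:
    def test_single_component_recovers_pooled_moments(self, rng):
        y = rng.normal(2.0, 1.5, size=(2000, 1))
        data = [SampleData(y, "s")]
        priors = make_priors_1d(K=1)
        state = initialize(data, 1, priors, rng)
        assert state.latents[0].theta[0] == pytest.approx(y.mean(), abs=0.05)
        assert state.mixtures[0].components[0].sigma[0, 0] == \
            pytest.approx(y.var(), rel=0.1)

    def test_informative_override_sets_component_start(self, rng):
        y = rng.normal(size=(500, 1))
        data = [SampleData(y, "a"), SampleData(y + 0.1, "b")]
        priors = make_priors_1d(K=2)
        mu0 = np.array([7.0])
        sig0 = np.array([[0.25]])
        state = initialize(data, 2, priors, rng,
                           informative={1: (mu0, sig0)})
        for mix in state.mixtures:
            assert mix.components[1].mu[0] == 7.0

    def test_two_blob_em_finds_centers(self, rng):
        a = rng.normal(0.0, 0.05, size=(800, 2))
        b = rng.normal(1.0, 0.05, size=(800, 2))
        data = [SampleData(np.vstack([a, b]), "s")]
        from hierflow.model import PriorSpec

        priors = PriorSpec.from_data(data, K=2)
        state = initialize(data, 2, priors, rng)
        centers = sorted(l.theta[0] for l in state.latents)
        assert centers[0] == pytest.approx(0.0, abs=0.1)
        assert centers[1] == pytest.approx(1.0, abs=0.1)


class TestRunBookkeeping:
    def test_trace_and_ppc_lengths(self, rng):
        data = [SampleData(rng.normal(size=(80, 1)), f"s{j}") for j in range(2)]
        from hierflow.model import PriorSpec

        priors = PriorSpec.from_data(data, K=1)
        cfg = McmcConfig(n_burnin=32, n_production=25, seed=3,
                         logpost_check_every=0)
        trace = run_mcmc(data, priors, cfg, K=1)
        assert trace.n_iterations == 25
        for j in range(2):
            # one posterior-predictive draw per production iteration per sample
            assert trace.ppc[j].shape == (25, 1)
            assert trace.responsibilities[j].shape == (80, 2)
            np.testing.assert_allclose(trace.responsibilities[j].sum(axis=1),
                                       1.0, atol=1e-9)

    def test_seed_reproducibility(self, rng):
        data = [SampleData(rng.normal(size=(60, 1)), "s")]
        from hierflow.model import PriorSpec

        priors = PriorSpec.from_data(data, K=1)
        cfg = McmcConfig(n_burnin=16, n_production=10, seed=42,
                         logpost_check_every=0)
        t1 = run_mcmc(data, priors, cfg, K=1)
        t2 = run_mcmc(data, priors, cfg, K=1)
        np.testing.assert_array_equal(t1.theta, t2.theta)


class TestGewekeJoint:
    def test_successive_conditional_moments_match_prior(self):
        """Joint-distribution check: alternating parameter sweeps with data
        regeneration leaves the prior invariant (compared on theta moments)."""
        from hierflow.sampler import _gibbs_sweep

        rng = np.random.default_rng(77)
        priors = make_priors_1d(K=1, t=0.5, S=0.4, Q=0.08, n_theta=6.0,
                                H=0.2, n_psi=3.0, lam=0.4, a=2.0, c_s=2.0,
                                outlier_mu=0.0, outlier_var=25.0)
        cfg = McmcConfig(n_burnin=0, n_production=1, seed=0,
                         logpost_check_every=0)
        n, J = 5, 2

        def prior_state():
            lats = [LatentCluster(
                theta=np.array([rng.normal(0.5, np.sqrt(0.4))]),
                sigma_theta=stats.invwishart.rvs(df=6.0, scale=0.08,
                                                 random_state=rng).reshape(1, 1),
                psi=stats.wishart.rvs(df=3.0, scale=0.2,
                                      random_state=rng).reshape(1, 1),
                nu=3 + int(rng.geometric(1 - np.exp(-0.4)) - 1))]
            mixes = []
            for _ in range(J):
                mu = rng.normal(lats[0].theta[0],
                                np.sqrt(lats[0].sigma_theta[0, 0]))
                sig = stats.invwishart.rvs(df=lats[0].nu, scale=lats[0].psi,
                                           random_state=rng)
                w = rng.dirichlet([2.0, 2.0])
                mixes.append(SampleMixture(
                    components=[ComponentParams([mu], np.reshape(sig, (1, 1)))],
                    weights=w, active=np.ones(1, bool),
                    assignments=np.zeros(n, np.int64)))
            return ModelState(lats, mixes)

        def draw_data(state):
            out = []
            for j in range(J):
                mix = state.mixtures[j]
                x = rng.choice(2, size=n, p=mix.weights)
                y = np.where(
                    x == 0,
                    rng.normal(0.0, 5.0, size=n),
                    rng.normal(mix.components[0].mu[0],
                               np.sqrt(mix.components[0].sigma[0, 0]), size=n))
                mix.assignments = x.astype(np.int64)
                out.append(SampleData(y[:, None], f"s{j}"))
            return out

        # direct prior sample of theta
        prior_thetas = np.array([prior_state().latents[0].theta[0]
                                 for _ in range(3000)])
        # successive-conditional chain
        state = prior_state()
        chain_thetas = []
        for it in range(3000):
            data = draw_data(state)
            _gibbs_sweep(state, data, priors, rng, cfg,
                         allow_activation=False, allow_label_switch=False)
            chain_thetas.append(state.latents[0].theta[0])
        chain_thetas = np.array(chain_thetas[200:])

        def batch_se(x, nb=30):
            b = len(x) // nb
            means = x[: b * nb].reshape(nb, b).mean(axis=1)
            return means.std(ddof=1) / np.sqrt(nb)

        se = np.hypot(batch_se(chain_thetas),
                      prior_thetas.std() / np.sqrt(len(prior_thetas)))
        assert abs(chain_thetas.mean() - prior_thetas.mean()) < 5 * se
        se2 = np.hypot(batch_se(chain_thetas ** 2),
                       (prior_thetas ** 2).std() / np.sqrt(len(prior_thetas)))
        assert abs(np.mean(chain_thetas ** 2) - np.mean(prior_thetas ** 2)) < 5 * se2


class TestDiagonalMode:
    def test_diagonal_covariance_run(self, rng):
        data = [SampleData(np.vstack([rng.normal([0, 0], 0.2, (150, 2)),
                                      rng.normal([1, 1], 0.2, (100, 2))]),
                           f"s{j}") for j in range(2)]
        priors = PriorSpec.from_data(data, K=2)
        cfg = McmcConfig(n_burnin=40, n_production=20, seed=1,
                         diagonal_covariance=True, logpost_check_every=0)
        trace = run_mcmc(data, priors, cfg, K=2)
        # every stored covariance is diagonal
        off = trace.sigma.copy()
        for i in range(2):
            off[..., i, i] = 0.0
        assert np.abs(off).max() == 0.0
        off_psi = trace.psi.copy()
        for i in range(2):
            off_psi[..., i, i] = 0.0
        assert np.abs(off_psi).max() == 0.0
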