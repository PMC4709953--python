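import numpy as np
import pytest

from hierflow.model import ComponentParams, LatentCluster, PriorSpec, SampleData, SampleMixture


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_mixture_1d(means, variances, weights, outlier_weight=0.0,
                    active=None, n=1):
    """1-D mixture state with given component means/variances."""
    K = len(means)
    comps = [ComponentParams(np.array([m]), np.array([[v]]))
             for m, v in zip(means, variances)]
    w = np.concatenate([[outlier_weight], np.asarray(weights, float)])
    if active is None:
        active = np.ones(K, bool)
    return SampleMixture(components=comps, weights=w / w.sum(),
                         active=np.asarray(active, bool),
                         assignments=np.zeros(n, np.int64))


def make_priors_1d(K=1, t=0.0, S=4.0, Q=0.04, n_theta=5.0, H=0.5, n_psi=1.0,
                   lam=0.1, a=0.5, c_s=2.0, outlier_mu=0.0, outlier_var=25.0):
    return PriorSpec(
        t=np.full((K, 1), t), S=np.full((K, 1, 1), S),
        Q=np.full((K, 1, 1), Q), n_theta=np.full(K, n_theta),
        H=np.full((K, 1, 1), H), n_psi=np.full(K, n_psi),
        lam=np.full(K, lam), a=np.full(K + 1, a), c_s=c_s,
        outlier_mu=np.array([outlier_mu]),
        outlier_sigma=np.array([[outlier_var]]),
    )


@pytest.fixture
def mixture_1d_factory():
    return make_mixture_1d


@pytest.fixture
def priors_1d_factory():
    return make_priors_1d
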