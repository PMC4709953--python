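"""Cluster merging: Bhattacharyya distance, moment matching, Fisher
coordinate and the two-threshold merge procedure."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from hierflow._linalg import InvalidParameterError
from hierflow.merge import (bhattacharyya_distance, fisher_coordinate,
                            gaussian_moment_match, merge_latent_clusters)


class TestBhattacharyya:
    def test_identical_gaussians_zero(self):
        mu = np.array([1.0, -2.0])
        sig = np.array([[2.0, 0.3], [0.3, 1.0]])
        assert bhattacharyya_distance(mu, sig, mu, sig) == pytest.approx(0.0, abs=1e-12)

    def test_unit_variance_mean_shift(self):
        # d=1, means 0 and 2, unit variances: (1/8) * 4 = 0.5
        assert bhattacharyya_distance([0.0], [[1.0]], [2.0], [[1.0]]) == \
            pytest.approx(0.5, abs=1e-12)

    def test_equal_means_different_variances(self):
        # (1/2) log(2 / sqrt(3))
        expected = 0.5 * np.log(2.0 / np.sqrt(3.0))
        assert bhattacharyya_distance([0.0], [[1.0]], [0.0], [[3.0]]) == \
            pytest.approx(expected, abs=1e-12)

    def test_symmetry(self, rng):
        for _ in range(10):
            m1, m2 = rng.normal(size=(2, 3))
            a = rng.normal(size=(3, 3))
            b = rng.normal(size=(3, 3))
            s1 = a @ a.T + np.eye(3)
            s2 = b @ b.T + np.eye(3)
            assert bhattacharyya_distance(m1, s1, m2, s2) == \
                pytest.approx(bhattacharyya_distance(m2, s2, m1, s1), rel=1e-10)

    def test_equals_minus_log_hellinger_integral(self, rng):
        """1-D: d_bhat = -log int sqrt(f g) on random parameter draws."""
        for _ in range(100):
            m1, m2 = rng.normal(size=2) * 2
            s1, s2 = rng.uniform(0.3, 3.0, size=2)
            d = bhattacharyya_distance([m1], [[s1 ** 2]], [m2], [[s2 ** 2]])
            integrand = lambda x: np.sqrt(norm.pdf(x, m1, s1) * norm.pdf(x, m2, s2))
            val, _ = quad(integrand, min(m1, m2) - 12 * max(s1, s2),
                          max(m1, m2) + 12 * max(s1, s2), limit=200)
            assert d == pytest.approx(-np.log(val), abs=1e-6)

    def test_non_spd_rejected(self):
        with pytest.raises(InvalidParameterError):
            bhattacharyya_distance([0.0, 0.0], np.array([[1.0, 3.0], [3.0, 1.0]]),
                                   [1.0, 1.0], np.eye(2))


class TestMomentMatch:
    def test_one_hot_weights_recover_sample_moments(self, rng):
        x = rng.normal(size=(200, 3))
        w = np.zeros((200, 2))
        sel = rng.random(200) < 0.5
        w[sel, 0] = 1.0
        w[~sel, 1] = 1.0
        mean, cov = gaussian_moment_match(x, w, [0])
        np.testing.assert_allclose(mean, x[sel].mean(axis=0), atol=1e-12)
        resid = x[sel] - x[sel].mean(axis=0)
        np.testing.assert_allclose(cov, resid.T @ resid / sel.sum(), atol=1e-12)

    def test_two_point_symmetry(self):
        x = np.array([[-1.0], [1.0]])
        w = np.ones((2, 1))
        mean, cov = gaussian_moment_match(x, w, [0])
        assert mean[0] == pytest.approx(0.0)
        assert cov[0, 0] == pytest.approx(1.0)

    def test_matches_bruteforce_weighted_moments(self, rng):
        x = rng.normal(size=(120, 2))
        w = rng.random((120, 3))
        w /= w.sum(axis=1, keepdims=True)
        mean, cov = gaussian_moment_match(x, w, [0, 2])
        wt = w[:, 0] + w[:, 2]
        m_ref = np.zeros(2)
        for i in range(120):
            m_ref += wt[i] * x[i]
        m_ref /= wt.sum()
        c_ref = np.zeros((2, 2))
        for i in range(120):
            c_ref += wt[i] * np.outer(x[i] - m_ref, x[i] - m_ref)
        c_ref /= wt.sum()
        np.testing.assert_allclose(mean, m_ref, atol=1e-10)
        np.testing.assert_allclose(cov, c_ref, atol=1e-10)

    def test_zero_weight_cluster_rejected(self):
        with pytest.raises(InvalidParameterError):
            gaussian_moment_match(np.ones((5, 1)), np.zeros((5, 1)), [0])


class TestFisherCoordinate:
    def test_isotropic_along_mean_difference(self):
        w = fisher_coordinate([2.0, 0.0], np.eye(2), [0.0, 0.0], np.eye(2))
        np.testing.assert_allclose(w, [1.0, 0.0], atol=1e-12)

    def test_anisotropic_hand_inverse(self):
        # pooled covariance diag(1, 100), mean difference (1, 1)
        w = fisher_coordinate([1.0, 1.0], np.diag([0.5, 50.0]),
                              [0.0, 0.0], np.diag([0.5, 50.0]))
        expected = np.array([1.0, 0.01])
        np.testing.assert_allclose(w, expected / np.linalg.norm(expected),
                                   atol=1e-12)

    def test_invariant_under_common_rescaling(self, rng):
        m1, m2 = rng.normal(size=(2, 3))
        a = rng.normal(size=(3, 3))
        s1 = a @ a.T + np.eye(3)
        s2 = np.eye(3) * 0.5
        w1 = fisher_coordinate(m1, s1, m2, s2)
        w2 = fisher_coordinate(m1, 7.3 * s1, m2, 7.3 * s2)
        np.testing.assert_allclose(w1, w2, atol=1e-10)

    def test_equal_means_undefined(self):
        with pytest.raises(InvalidParameterError):
            fisher_coordinate([1.0], [[1.0]], [1.0], [[2.0]])


def _blob_data(centers, ns, sds, rng, d=2):
    """Events plus one-hot weights, one latent cluster per blob."""
    events, weights = [], []
    K = len(centers)
    for k, (c, n, s) in enumerate(zip(centers, ns, sds)):
        pts = rng.normal(np.asarray(c, float), s, size=(n, d))
        w = np.zeros((n, K))
        w[:, k] = 1.0
        events.append(pts)
        weights.append(w)
    return np.vstack(events), np.vstack(weights)


class TestMergeProcedure:
    def test_distant_clusters_stay_singletons(self, rng):
        events, w = _blob_data([[0, 0], [8, 0], [0, 8]], [300, 300, 300],
                               [0.3, 0.3, 0.3], rng)
        res = merge_latent_clusters(events, w, d1=0.1, d2=1.0, rng=rng)
        assert res.n_super == 3

    def test_pair_below_d1_merges_even_if_bimodal(self, rng):
        # two tight, clearly separated blobs, but d1 set above their distance
        events, w = _blob_data([[0, 0], [2, 0]], [400, 400], [0.5, 0.5], rng)
        from hierflow.merge import gaussian_moment_match, bhattacharyya_distance
        m0 = gaussian_moment_match(events, w, [0])
        m1 = gaussian_moment_match(events, w, [1])
        dist = bhattacharyya_distance(m0[0], m0[1], m1[0], m1[1])
        res = merge_latent_clusters(events, w, d1=dist + 0.1, d2=dist + 0.2,
                                    rng=rng)
        assert res.n_super == 1
        assert "< d1" in res.merge_log[0]["decision"]

    def test_intermediate_bimodal_pair_not_merged(self, rng):
        # distance in [d1, d2) but clearly bimodal along the Fisher coordinate
        events, w = _blob_data([[0, 0], [2.4, 0]], [500, 500], [0.45, 0.45], rng)
        res = merge_latent_clusters(events, w, d1=0.01, d2=10.0, rng=rng)
        assert res.n_super == 2
        assert any("multimodal" in e["decision"] for e in res.merge_log)

    def test_intermediate_unimodal_pair_merged(self, rng):
        # overlapping blobs forming one mode merge through the dip gate
        events, w = _blob_data([[0, 0], [0.7, 0]], [500, 500], [0.6, 0.6], rng)
        res = merge_latent_clusters(events, w, d1=1e-4, d2=10.0, rng=rng)
        assert res.n_super == 1

    def test_relabeling_invariance(self, rng):
        events, w = _blob_data([[0, 0], [0.8, 0], [7, 7]], [300, 300, 300],
                               [0.5, 0.5, 0.4], rng)
        res = merge_latent_clusters(events, w, d1=0.15, d2=1.0,
                                    rng=np.random.default_rng(0))
        perm = [2, 0, 1]
        res_p = merge_latent_clusters(events, w[:, perm], d1=0.15, d2=1.0,
                                      rng=np.random.default_rng(0))
        # partitions agree as set partitions after undoing the permutation
        base = {frozenset(int(perm[k]) for k in
                          np.flatnonzero(res_p.partition == s))
                for s in np.unique(res_p.partition)}
        orig = {frozenset(int(k) for k in np.flatnonzero(res.partition == s))
                for s in np.unique(res.partition)}
        assert base == orig

    def test_raising_d1_never_refines_partition(self, rng):
        events, w = _blob_data([[0, 0], [1.2, 0], [2.4, 0]], [300, 300, 300],
                               [0.5, 0.5, 0.5], rng)
        sizes = []
        for d1 in (1e-4, 0.05, 0.3, 2.0):
            res = merge_latent_clusters(events, w, d1=d1, d2=max(d1, 1.0),
                                        rng=np.random.default_rng(0))
            sizes.append(res.n_super)
        assert sizes == sorted(sizes, reverse=True)

    def test_d1_above_d2_rejected(self, rng):
        with pytest.raises(ValueError):
            merge_latent_clusters(np.zeros((10, 1)), np.ones((10, 1)),
                                  d1=2.0, d2=1.0, rng=rng)
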