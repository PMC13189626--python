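"""Factorability diagnostics, parallel analysis, and the hierarchical
maximum-likelihood factor model."""

import numpy as np
import pytest

from cogstack.gfactor import (
    HierarchicalFactorModel,
    bartlett,
    efa_oblimin,
    kmo,
    parallel_analysis,
    pick_anchors,
)


def _equicorr(p, r):
    return np.full((p, p), r) + (1 - r) * np.eye(p)


def hierarchical_sample(rng, n, Lambda, gamma, n_factors=None):
    """Draw test scores from an explicit hierarchical factor model."""
    p, m = Lambda.shape
    g = rng.standard_normal(n)
    F = gamma * g[:, None] + np.sqrt(1 - gamma**2) * rng.standard_normal((n, m))
    uniq = 1 - np.sum(Lambda**2, axis=1)
    X = F @ Lambda.T + rng.standard_normal((n, p)) * np.sqrt(uniq)
    return X, g


def simple_structure(p=12, m=4, lam=0.75):
    L = np.zeros((p, m))
    for i in range(p):
        L[i, i % m] = lam
    return L


class TestKmo:
    def test_identity_degenerate(self):
        with pytest.raises(ValueError, match="KMO undefined"):
            kmo(np.eye(12))

    def test_equicorrelation_brute_force(self):
        R = _equicorr(12, 0.5)
        p = 12
        off = ~np.eye(p, dtype=bool)
        Rinv = np.linalg.inv(R)
        d = np.sqrt(np.diag(Rinv))
        Q = -Rinv / np.outer(d, d)
        expected = np.sum(R[off] ** 2) / (np.sum(R[off] ** 2) + np.sum(Q[off] ** 2))
        assert kmo(R) == pytest.approx(expected, abs=1e-12)

    def test_strong_common_factor_high_kmo(self, rng):
        L = simple_structure()
        X, _ = hierarchical_sample(rng, 4000, L, np.array([0.85, 0.8, 0.8, 0.75]))
        R = np.corrcoef(X, rowvar=False)
        assert kmo(R) > 0.8


class TestBartlett:
    def test_identity_gives_zero_chi2(self):
        out = bartlett(np.eye(5), 100)
        assert out["chi2"] == pytest.approx(0.0, abs=1e-10)
        assert out["p"] == pytest.approx(1.0)

    def test_hand_computed_formula(self):
        R = _equicorr(3, 0.5)
        n, p = 100, 3
        expected = -(n - 1 - (2 * p + 5) / 6) * np.log(np.linalg.det(R))
        out = bartlett(R, n)
        assert out["chi2"] == pytest.approx(expected, abs=1e-10)
        assert out["df"] == 3

    def test_correlated_data_significant(self, rng):
        L = simple_structure()
        X, _ = hierarchical_sample(rng, 2000, L, np.array([0.8, 0.7, 0.6, 0.5]))
        out = bartlett(np.corrcoef(X, rowvar=False), 2000)
        assert out["p"] < 0.05

    def test_requires_n_greater_than_p(self):
        with pytest.raises(ValueError, match="n > p"):
            bartlett(np.eye(5), 5)


class TestParallelAnalysis:
    def test_pure_noise_zero_factors(self):
        # the 95th-percentile reference keeps the per-rank false-positive
        # rate near 5% on pure noise (the mean rule is a coin flip there)
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((500, 12))
            if parallel_analysis(X, seed=seed, quantile_rule="p95") == 0:
                hits += 1
        assert hits >= 9

    def test_rank_one_structure(self, rng):
        g = rng.standard_normal(1000)
        X = 0.8 * g[:, None] + 0.6 * rng.standard_normal((1000, 8))
        assert parallel_analysis(X, seed=0) == 1

    def test_four_factor_recovery(self, rng):
        L = simple_structure()
        X, _ = hierarchical_sample(rng, 5000, L, np.array([0.8, 0.7, 0.6, 0.5]))
        assert parallel_analysis(X, seed=0) == 4
        assert parallel_analysis(X, seed=0, method="pc") == 4

    def test_p95_rule_not_more_liberal_than_mean(self, rng):
        L = simple_structure()
        X, _ = hierarchical_sample(rng, 2000, L, np.array([0.8, 0.7, 0.6, 0.5]))
        k_mean = parallel_analysis(X, seed=0, quantile_rule="mean")
        k_p95 = parallel_analysis(X, seed=0, quantile_rule="p95")
        assert k_p95 <= k_mean


class TestHierarchicalFit:
    def test_parameter_recovery_large_n(self):
        rng = np.random.default_rng(42)
        L = simple_structure()
        gamma = np.array([0.8, 0.7, 0.6, 0.5])
        X, g = hierarchical_sample(rng, 100_000, L, gamma)
        res = HierarchicalFactorModel(X, n_factors=4, seed=0).fit()
        assert res.converged
        # align fitted factors to generative ones by dominant loading
        order = np.argmax(np.abs(res.Lambda[[0, 1, 2, 3], :]), axis=1)
        assert sorted(order.tolist()) == [0, 1, 2, 3]
        L_fit = res.Lambda[:, order]
        sign = np.sign(np.sum(L_fit * L, axis=0))
        L_fit = L_fit * sign
        np.testing.assert_allclose(L_fit, L, atol=0.03)
        g_fit = np.sort(np.abs(res.gamma))
        np.testing.assert_allclose(g_fit, np.sort(gamma), atol=0.03)
        uniq_true = 1 - np.sum(L**2, axis=1)
        np.testing.assert_allclose(res.theta, uniq_true, atol=0.03)

    def test_single_factor_hierarchy_collapses(self, rng):
        g = rng.standard_normal(20_000)
        X = 0.7 * g[:, None] + np.sqrt(1 - 0.49) * rng.standard_normal((20_000, 6))
        res = HierarchicalFactorModel(X, n_factors=1, seed=0).fit()
        assert abs(res.gamma[0]) > 0.95

    def test_good_fit_indices_on_true_model(self, rng):
        L = simple_structure()
        X, _ = hierarchical_sample(rng, 5000, L, np.array([0.8, 0.7, 0.6, 0.5]))
        res = HierarchicalFactorModel(X, n_factors=4, seed=0).fit()
        f = res.fit
        assert f.df == 30
        assert f.cfi > 0.96
        assert f.rmsea <= 0.05
        assert f.srmr < 0.05

    def test_scores_track_generative_g_up_to_determinacy(self, rng):
        L = simple_structure()
        X, g = hierarchical_sample(rng, 20_000, L, np.array([0.8, 0.7, 0.6, 0.5]))
        res = HierarchicalFactorModel(X, n_factors=4, seed=0).fit()
        scores = res.score(X)
        r = abs(np.corrcoef(scores, g)[0, 1])
        assert r >= res.determinacy - 0.02

    def test_score_of_mean_subject_is_zero(self, rng):
        L = simple_structure()
        X, _ = hierarchical_sample(rng, 3000, L, np.array([0.8, 0.7, 0.6, 0.5]))
        res = HierarchicalFactorModel(X, n_factors=4, seed=0).fit()
        assert res.score(res.x_mean[None, :])[0] == pytest.approx(0.0, abs=1e-10)

    def test_monotone_in_scores_for_positive_weights(self, rng):
        L = simple_structure()
        X, _ = hierarchical_sample(rng, 3000, L, np.array([0.8, 0.7, 0.6, 0.5]))
        res = HierarchicalFactorModel(X, n_factors=4, seed=0).fit()
        if np.all(res.scoring_weights > 0):
            lo = res.score(res.x_mean[None, :] - res.x_sd)
            hi = res.score(res.x_mean[None, :] + res.x_sd)
            assert hi[0] > lo[0]

    def test_train_scaling_used_for_new_subjects(self, rng):
        L = simple_structure()
        X, _ = hierarchical_sample(rng, 3000, L, np.array([0.8, 0.7, 0.6, 0.5]))
        res = HierarchicalFactorModel(X, n_factors=4, seed=0).fit()
        shifted = X[:100] + 5.0
        np.testing.assert_allclose(
            res.score(shifted),
            res.score(X[:100]) + res.score(res.x_mean[None, :] + 5.0)[0],
            atol=1e-8,
        )


class TestFitIndicesEdgeCases:
    def test_saturated_model_limits(self, rng):
        """A model reproducing S exactly yields chi2=0, CFI=1, RMSEA=0,
        SRMR=0."""
        L = simple_structure()
        gamma = np.array([0.8, 0.7, 0.6, 0.5])
        phi = np.outer(gamma, gamma) + np.diag(1 - gamma**2)
        uniq = 1 - np.sum(L**2, axis=1)
        S = L @ phi @ L.T + np.diag(uniq)
        fi = HierarchicalFactorModel._fit_indices(L, gamma, uniq, S, 5000, 48)
        assert fi.chi2 == pytest.approx(0.0, abs=1e-8)
        assert fi.cfi == pytest.approx(1.0)
        assert fi.rmsea == pytest.approx(0.0)
        assert fi.srmr == pytest.approx(0.0, abs=1e-12)

    def test_close_fit_at_large_n(self):
        rng = np.random.default_rng(7)
        L = simple_structure()
        X, _ = hierarchical_sample(rng, 50_000, L, np.array([0.8, 0.7, 0.6, 0.5]))
        res = HierarchicalFactorModel(X, n_factors=4, seed=0).fit()
        assert res.fit.rmsea <= 0.05


class TestEfaAnchors:
    def test_oblimin_recovers_simple_structure(self, rng):
        L = simple_structure()
        X, _ = hierarchical_sample(rng, 10_000, L, np.array([0.8, 0.7, 0.6, 0.5]))
        load = efa_oblimin(X, 4)
        # each variable's dominant loading is on its own factor cluster
        dominant = np.argmax(np.abs(load), axis=0)
        assert len(set(dominant % 4)) == 4

    def test_anchor_assignment_distinct(self):
        load = np.array([[0.9, 0.1], [0.8, 0.2], [0.3, 0.7], [0.2, 0.6]])
        anchors = pick_anchors(load)
        assert sorted(anchors.tolist()) == sorted(set(anchors.tolist()))
        assert anchors[0] == 0 and anchors[1] == 2

    def test_anchor_conflict_resolved_without_reuse(self):
        load = np.array([[0.9, 0.85], [0.8, 0.2], [0.3, 0.7]])
        anchors = pick_anchors(load)
        assert len(set(anchors.tolist())) == 2
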