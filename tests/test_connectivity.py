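"""Connectivity quantification: correlation, ridge partials, tangent space."""

import numpy as np
import pytest

from cogstack.connectivity import (
    TangentProjector,
    fisher_z,
    full_correlation,
    network_amplitudes,
    partial_correlation_ridge,
    select_fc_metric,
    vectorize_offdiag,
)


def _chain_ts(rng, T=50_000):
    """x -> y -> z chain: marginally correlated, conditionally independent."""
    x = rng.standard_normal(T)
    y = 0.7 * x + 0.7 * rng.standard_normal(T)
    z = 0.7 * y + 0.7 * rng.standard_normal(T)
    return np.column_stack([x, y, z])


class TestFullCorrelation:
    def test_identical_and_anticorrelated_nodes(self, rng):
        x = rng.standard_normal(1000)
        ts = np.column_stack([x, x + 0.0, -x])
        r = full_correlation(ts)
        assert r[0, 1] == pytest.approx(1.0)
        assert r[0, 2] == pytest.approx(-1.0)
        np.testing.assert_allclose(np.diag(r), 1.0)

    def test_independent_noise_near_zero(self, rng):
        r = full_correlation(rng.standard_normal((10_000, 6)))
        off = r[~np.eye(6, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_constant_node_rejected(self, rng):
        ts = rng.standard_normal((100, 3))
        ts[:, 1] = 2.0
        with pytest.raises(ValueError, match=r"\[1\]"):
            full_correlation(ts)


class TestPartialCorrelation:
    def test_diagonal_covariance_zero_partials(self, rng):
        ts = rng.standard_normal((20_000, 4)) * np.array([1.0, 2.0, 0.5, 3.0])
        pr = partial_correlation_ridge(ts, rho=0.5)
        off = pr[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_rho_zero_matches_precision_oracle(self, rng):
        ts = _chain_ts(rng, 5000)
        pr = partial_correlation_ridge(ts, rho=0.0)
        P = np.linalg.inv(np.cov(ts, rowvar=False, ddof=0))
        d = np.sqrt(np.diag(P))
        oracle = -P / np.outer(d, d)
        np.fill_diagonal(oracle, 1.0)
        np.testing.assert_allclose(pr, oracle, atol=1e-12)

    def test_chain_graph_partial_vanishes(self, rng):
        ts = _chain_ts(rng)
        fc = full_correlation(ts)
        pr_exact = partial_correlation_ridge(ts, rho=0.0)
        pr_ridge = partial_correlation_ridge(ts, rho=0.5)
        assert fc[0, 2] > 0.3
        # conditional independence is exact without regularization ...
        assert abs(pr_exact[0, 2]) < 0.02
        # ... and the regularized partial still shrinks the indirect edge
        # far below the marginal correlation
        assert abs(pr_ridge[0, 2]) < fc[0, 2] / 2

    def test_shrinkage_monotone_in_rho(self, rng):
        ts = _chain_ts(rng, 5000)
        mags = [
            np.abs(partial_correlation_ridge(ts, rho)[np.triu_indices(3, 1)]).sum()
            for rho in (0.0, 1.0, 10.0, 1000.0)
        ]
        assert mags[0] > mags[1] > mags[2] > mags[3]
        assert mags[-1] < 0.01

    def test_negative_rho_rejected(self, rng):
        with pytest.raises(ValueError, match="nonnegative"):
            partial_correlation_ridge(rng.standard_normal((50, 3)), rho=-1.0)


class TestFisherZ:
    def test_closed_form_values(self):
        assert fisher_z(np.array([0.0]))[0] == 0.0
        assert fisher_z(np.array([0.5]))[0] == pytest.approx(0.5493061443)

    def test_antisymmetry(self, rng):
        r = rng.uniform(-0.9, 0.9, size=(4, 4))
        np.testing.assert_allclose(fisher_z(-r), -fisher_z(r), atol=1e-14)

    def test_clipping_warns(self):
        with pytest.warns(UserWarning, match="clipping"):
            z = fisher_z(np.array([[1.0, 1.0], [1.0, 1.0]]))
        assert np.isfinite(z).all()


class TestTangent:
    def _subjects(self, rng, n=8, k=4, T=300):
        A = rng.standard_normal((k, k))
        return [rng.standard_normal((T, k)) @ (np.eye(k) + 0.1 * A) for _ in range(n)]

    def test_reference_projects_to_zero(self, rng):
        subs = self._subjects(rng)
        proj = TangentProjector.fit(subs)
        vals, vecs = np.linalg.eigh(proj.C_ref)
        # a synthetic subject whose LW covariance equals C_ref exactly
        M = proj.whitener @ proj.C_ref @ proj.whitener
        M = (M + M.T) / 2
        logvals = np.log(np.linalg.eigvalsh(M))
        assert np.abs(logvals).max() < 1e-8

    def test_whitener_defining_identity(self, rng):
        proj = TangentProjector.fit(self._subjects(rng))
        k = proj.C_ref.shape[0]
        np.testing.assert_allclose(
            proj.whitener @ proj.C_ref @ proj.whitener, np.eye(k), atol=1e-8
        )

    def test_ledoit_wolf_closed_form_k2(self, rng):
        """Hand-computed Ledoit-Wolf shrinkage on a 2-node example."""
        ts = rng.standard_normal((300, 2)) @ np.array([[1.0, 0.4], [0.0, 1.0]])
        z = (ts - ts.mean(0)) / ts.std(0)
        S = z.T @ z / len(z)
        mu = np.trace(S) / 2
        d2 = np.linalg.norm(S - mu * np.eye(2), "fro") ** 2 / 2
        b2 = min(
            np.mean([np.linalg.norm(np.outer(r, r) - S, "fro") ** 2 / 2 for r in z])
            / len(z),
            d2,
        )
        manual = (b2 / d2) * mu * np.eye(2) + (1 - b2 / d2) * S
        np.testing.assert_allclose(
            TangentProjector._lw_cov(ts), manual, atol=1e-10
        )

    def test_matrix_log_oracle(self, rng):
        from scipy.linalg import logm

        subs = self._subjects(rng)
        proj = TangentProjector.fit(subs)
        sig = TangentProjector._lw_cov(subs[0])
        M = proj.whitener @ sig @ proj.whitener
        direct = logm((M + M.T) / 2)
        np.testing.assert_allclose(
            proj.project(subs[0], vectorize=False), direct, atol=1e-10
        )

    def test_vectorization_excludes_diagonal(self, rng):
        subs = self._subjects(rng, k=5)
        proj = TangentProjector.fit(subs)
        v = proj.project(subs[0])
        assert v.shape == (5 * 4 // 2,)

    def test_node_permutation_equivariance(self, rng):
        subs = self._subjects(rng, k=4)
        perm = np.array([2, 0, 3, 1])
        proj = TangentProjector.fit(subs)
        proj_p = TangentProjector.fit([s[:, perm] for s in subs])
        T1 = proj.project(subs[0], vectorize=False)
        T2 = proj_p.project(subs[0][:, perm], vectorize=False)
        np.testing.assert_allclose(T2, T1[np.ix_(perm, perm)], atol=1e-8)

    def test_train_only_reference_is_leakage_guard(self, rng):
        subs = self._subjects(rng, n=10)
        train, test = subs[:6], subs[6:]
        proj_train = TangentProjector.fit(train)
        stored = [proj_train.project(t) for t in test]
        refit = TangentProjector.fit(train)  # same training set: identical
        for t, s in zip(test, stored):
            np.testing.assert_array_equal(refit.project(t), s)
        proj_leaky = TangentProjector.fit(train + test)
        assert not np.allclose(proj_leaky.project(test[0]), stored[0])

    def test_agrees_with_nilearn_given_same_reference(self, rng):
        """Independent cross-check: nilearn's tangent embedding with our
        reference matrix reproduces our projection."""
        from nilearn.connectome.connectivity_matrices import _map_eigenvalues

        subs = self._subjects(rng)
        proj = TangentProjector.fit(subs)
        sig = TangentProjector._lw_cov(subs[0])
        nilearn_style = _map_eigenvalues(
            np.log, proj.whitener @ sig @ proj.whitener
        )
        np.testing.assert_allclose(
            proj.project(subs[0], vectorize=False), nilearn_style, atol=1e-10
        )

    def test_needs_two_subjects(self, rng):
        with pytest.raises(ValueError, match="two training subjects"):
            TangentProjector.fit([rng.standard_normal((100, 3))])


class TestMetricSelectionAndAmplitude:
    def test_best_score_wins(self):
        assert select_fc_metric({"full": 0.05, "partial": 0.04, "tangent": 0.09}) == "tangent"
        assert select_fc_metric({"full": 0.08, "partial": 0.04, "tangent": 0.02}) == "full"

    def test_tie_goes_to_tangent(self):
        assert select_fc_metric({"full": 0.05, "partial": 0.05, "tangent": 0.05}) == "tangent"

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="no metric"):
            select_fc_metric({})

    def test_covariance_scale_signal_prefers_tangent_or_full(self):
        """When the predictive signal lives in covariance scale, inner-CV
        style scoring favours tangent/full over partial in most seeds."""
        from cogstack.plsr import PLSModel

        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            n_sub, k, T = 100, 10, 250
            # the trait scales the loading of a network-wide latent, so
            # the signal lives on covariance scale; conditioning on the
            # other nodes (partial correlation) suppresses it
            trait = rng.standard_normal(n_sub)
            subs = []
            for i in range(n_sub):
                a = 0.6 + 0.35 * np.tanh(trait[i])
                common = rng.standard_normal(T)
                subs.append(a * common[:, None] + rng.standard_normal((T, k)))
            proj = TangentProjector.fit(subs[:60])
            feats = {
                "full": np.array([vectorize_offdiag(full_correlation(s)) for s in subs]),
                "partial": np.array(
                    [vectorize_offdiag(partial_correlation_ridge(s)) for s in subs]
                ),
                "tangent": np.array([proj.project(s) for s in subs]),
            }
            scores = {}
            for name, X in feats.items():
                res = PLSModel(X[:60], trait[:60]).fit(2, strict=False)
                pred = res.predict(X[60:])
                scores[name] = np.corrcoef(pred, trait[60:])[0, 1]
            if select_fc_metric(scores) in ("tangent", "full"):
                wins += 1
        assert wins >= 8

    def test_network_amplitudes_are_node_sds(self, rng):
        ts = rng.standard_normal((500, 3)) * np.array([1.0, 2.0, 0.5])
        np.testing.assert_allclose(
            network_amplitudes(ts), ts.std(axis=0), atol=1e-12
        )
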