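"""Synthetic cohort generator: determinism, invariants, and agreement
between the closed-form ground truth and brute-force simulation."""

import numpy as np
import pandas as pd
import pytest

from cogstack.behavioral import REFUSAL_CODES, transform_cognitive
from cogstack.synthetic import (
    BlockSpec,
    GenerativeConfig,
    default_config,
    generate_cohort,
    make_fixture,
    theoretical_commonality,
)


def small_config(n=2000, seed=5, **kw):
    blocks = [
        BlockSpec("ba", "modA", 15, 0.6, 0.5, demo_loading=-0.3),
        BlockSpec("bb", "modB", 15, 0.5, 0.4, demo_loading=-0.2),
    ]
    cfg = GenerativeConfig(n_subjects=n, blocks=blocks, seed=seed, **kw)
    return cfg


class TestConfigValidation:
    def test_overlap_share_bounds(self):
        with pytest.raises(ValueError, match="overlap_share"):
            BlockSpec("x", "m", 5, 0.3, 1.2)

    def test_g_variance_budget_enforced(self):
        with pytest.raises(ValueError, match="variance of g"):
            GenerativeConfig(
                source_weights={"shared": 0.9, "mh_only": 0.5, "cognition_only": 0.5}
            )

    def test_block_latent_variance_enforced(self):
        with pytest.raises(ValueError, match="latent variance"):
            GenerativeConfig(
                blocks=[BlockSpec("x", "m", 5, 0.9, 0.5, demo_loading=0.6)]
            )

    def test_negative_n_rejected(self):
        with pytest.raises(ValueError, match="n_subjects"):
            GenerativeConfig(n_subjects=-1)


class TestDeterminism:
    def test_identical_seed_identical_cohort(self):
        a = generate_cohort(small_config())
        b = generate_cohort(small_config())
        pd.testing.assert_frame_equal(a.cognitive_raw, b.cognitive_raw)
        pd.testing.assert_frame_equal(a.mental_health_items, b.mental_health_items)
        for k in a.feature_blocks:
            pd.testing.assert_frame_equal(a.feature_blocks[k], b.feature_blocks[k])
        pd.testing.assert_frame_equal(a.confounds, b.confounds)

    def test_different_seed_differs(self):
        a = generate_cohort(small_config(seed=5))
        b = generate_cohort(small_config(seed=6))
        assert not a.cognitive_raw.equals(b.cognitive_raw)

    def test_tiny_fixture_roundtrip_bytes(self, tmp_path):
        make_fixture("tiny").write(tmp_path / "a")
        make_fixture("tiny").write(tmp_path / "b")
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()


class TestCohortStructure:
    def test_alignment_and_unique_ids(self):
        co = generate_cohort(small_config())
        ids = pd.Index(co.subject_ids)
        assert not ids.has_duplicates
        for tbl in [co.cognitive_raw, co.mental_health_items, co.confounds,
                    *co.feature_blocks.values()]:
            assert tbl.index.equals(ids)

    def test_refusal_codes_injected_at_configured_rate(self):
        cfg = small_config(n=4000)
        cfg.refusal_rate = 0.05
        co = generate_cohort(cfg)
        vals = co.mental_health_items.to_numpy()
        rate = np.isin(vals, REFUSAL_CODES).mean()
        assert rate == pytest.approx(0.05, abs=0.01)

    def test_raw_cognitive_scales_match_published_ranges(self):
        co = generate_cohort(small_config(n=5000))
        raw = co.cognitive_raw
        assert raw["fluid_intelligence"].between(0, 13).all()
        assert raw["numeric_memory"].between(2, 12).all()
        assert set(raw["prospective_memory"].unique()) <= {0.0, 1.0, 2.0, 3.0}
        assert (raw["reaction_time"] > 0).all()
        # log of the simulated reaction time matches the published scale
        logged = np.log(raw["reaction_time"])
        assert logged.mean() == pytest.approx(6.4, abs=0.05)
        assert logged.std() == pytest.approx(0.2, abs=0.05)

    def test_confound_table_layout(self):
        co = generate_cohort(small_config())
        assert set(co.confounds["sex"].unique()) <= {0, 1}
        assert co.confounds["site"].nunique() == 4


class TestGroundTruth:
    def test_no_shared_sources_no_block_mh_correlation(self):
        cfg = small_config(n=20000)
        cfg.source_weights = {"shared": 0.0, "mh_only": 0.0, "cognition_only": 0.8}
        cfg.confound_weights = {"age": 0.0, "sex": 0.0, "site": 0.0}
        cfg.mh_latent_weights = {"shared": 0.0, "mh_only": 0.6, "age": 0.0, "sex": 0.0}
        cfg.brain_weights = {b.name: 0.0 for b in cfg.blocks}
        for b in cfg.blocks:
            b.demo_loading = 0.0
            b.overlap_share = 0.0
        cfg.validate()
        co = generate_cohort(cfg)
        r = np.corrcoef(
            co.feature_blocks["ba"].iloc[:, 0],
            co.mental_health_items.iloc[:, 0],
        )[0, 1]
        assert abs(r) < 0.03
        assert co.truth.r2_mh_undefined

    def test_pct_undefined_flag_when_mh_r2_zero(self):
        cfg = small_config()
        cfg.mh_latent_weights = {"shared": 0.0, "mh_only": 0.6, "age": 0.0, "sex": 0.0}
        cfg.source_weights = {"shared": 0.0, "mh_only": 0.0, "cognition_only": 0.8}
        cfg.confound_weights = {"age": 0.0, "sex": 0.0, "site": 0.0}
        cfg.validate()
        gt = theoretical_commonality(cfg)
        assert gt.r2_mh_undefined
        assert np.isnan(gt.expected_pct_explained["ba"])

    def test_default_r_mh_target_monte_carlo_coverage(self):
        """Sample corr(observed-g BLP, item BLP) across replicates covers
        the configured population value of ~0.31."""
        target = theoretical_commonality(default_config(1)).expected_r_mh
        assert target == pytest.approx(0.31, abs=0.02)
        rs = []
        # n large enough that in-sample optimism (~(1-R2) p/n) is < 0.005
        for rep in range(3):
            cfg = default_config(25_000, seed=600 + rep)
            cfg.refusal_rate = 0.0
            co = generate_cohort(cfg)
            cog = transform_cognitive(co.cognitive_raw).to_numpy()
            ok = ~np.isnan(cog).any(axis=1)
            Z = (cog[ok] - cog[ok].mean(0)) / cog[ok].std(0)

            def blp(X, y):
                D = np.column_stack([np.ones(len(X)), X])
                b, *_ = np.linalg.lstsq(D, y, rcond=None)
                return D @ b

            g_obs = blp(Z, co.truth.g_true[ok])
            ghat = blp(co.mental_health_items.to_numpy()[ok], g_obs)
            rs.append(np.corrcoef(g_obs, ghat)[0, 1])
        # in-sample BLP at n=4000 is slightly optimistic; wide band
        assert np.mean(rs) == pytest.approx(target, abs=0.03)

    def test_theory_matches_brute_force_commonality(self):
        """Closed-form %-explained equals the simulation at large n."""
        cfg = small_config(n=150_000, seed=9)
        cfg.refusal_rate = 0.0
        co = generate_cohort(cfg)
        gt = co.truth
        cog = transform_cognitive(co.cognitive_raw).to_numpy()
        ok = ~np.isnan(cog).any(axis=1)
        Z = (cog[ok] - cog[ok].mean(0)) / cog[ok].std(0)

        def blp(X, y):
            D = np.column_stack([np.ones(len(X)), X])
            b, *_ = np.linalg.lstsq(D, y, rcond=None)
            return D @ b

        def r2(y, X):
            D = np.column_stack([np.ones(len(y)), X])
            b, *_ = np.linalg.lstsq(D, y, rcond=None)
            e = y - D @ b
            return 1 - e @ e / np.sum((y - y.mean()) ** 2)

        g_obs = blp(Z, gt.g_true[ok])
        ghat_mh = blp(co.mental_health_items.to_numpy()[ok], g_obs)
        conf = co.confounds.iloc[np.flatnonzero(ok)]
        D = np.column_stack(
            [
                pd.get_dummies(conf["site"], drop_first=True).to_numpy(float),
                conf["acquisition_date"].to_numpy(float),
            ]
        )
        Dd = np.column_stack([np.ones(len(D)), D])
        for name, tbl in co.feature_blocks.items():
            X = tbl.to_numpy()[ok]
            b, *_ = np.linalg.lstsq(Dd, X, rcond=None)
            ghat_b = blp(X - Dd @ b, g_obs)
            r2_mh = r2(g_obs, ghat_mh[:, None])
            r2_b = r2(g_obs, ghat_b[:, None])
            r2_j = r2(g_obs, np.column_stack([ghat_mh, ghat_b]))
            pct = 100 * (r2_mh + r2_b - r2_j) / r2_mh
            assert pct == pytest.approx(
                gt.expected_pct_explained[name], abs=1.5
            ), name

    def test_full_overlap_block_pct_near_hundred(self):
        """A block latent consisting purely of the mental-health-shared
        view captures all the MH signal the brain can see."""
        cfg = small_config()
        # make the brain view perfectly aligned and the MH latent purely shared
        cfg.brain_view_alignment = {"shared": 1.0, "age": 0.0, "sex": 0.0}
        cfg.mh_latent_weights = {"shared": 0.7, "mh_only": 0.0, "age": 0.0, "sex": 0.0}
        cfg.confound_weights = {"age": 0.0, "sex": 0.0, "site": 0.0}
        cfg.blocks[0].overlap_share = 1.0
        cfg.blocks[0].signal_strength = 0.99
        cfg.blocks[0].demo_loading = 0.0
        cfg.blocks[0].feature_loading = (0.7, 0.9)
        cfg.blocks[0].n_features = 60
        cfg.validate()
        gt = theoretical_commonality(cfg)
        assert gt.expected_pct_explained["ba"] > 95.0

    def test_pct_monotone_in_overlap_share(self):
        pcts = []
        for ov in (0.1, 0.4, 0.8):
            cfg = small_config()
            cfg.blocks[0].overlap_share = ov
            cfg.validate()
            pcts.append(theoretical_commonality(cfg).expected_pct_explained["ba"])
        assert pcts[0] < pcts[1] < pcts[2]

    def test_latent_moments_recovered_at_scale(self):
        """Sample variance of g and its correlation with the MH latent
        match the configured population values within Monte-Carlo error."""
        cfg = small_config(n=100_000)
        co = generate_cohort(cfg)
        src = co.truth.sources
        assert np.var(src["g_true"]) == pytest.approx(1.0, abs=0.02)
        gm = np.corrcoef(src["g_true"], src["mh_latent"])[0, 1]
        w = cfg._g_weights()
        m = cfg.mh_latent_weights
        expected = (
            w["shared"] * m["shared"]
            + w["mh_only"] * m["mh_only"]
            + w["age"] * m["age"]
            + w["sex"] * m["sex"]
        )
        assert gm == pytest.approx(expected, abs=3 / np.sqrt(cfg.n_subjects) + 0.01)


class TestFixtures:
    def test_unknown_fixture_rejected(self):
        with pytest.raises(ValueError, match="unknown fixture"):
            make_fixture("bogus")

    def test_null_fixture_truth_all_zero(self, null_cohort):
        t = null_cohort.truth
        assert t.r2_mh_undefined
        assert all(v < 1e-10 for v in t.expected_R2.values())

    def test_default_fixture_pct_monotone_in_overlap(self):
        cfg = default_config(100)
        gt = theoretical_commonality(cfg)
        shares = {b.name: b.signal_strength**2 * b.overlap_share for b in cfg.blocks}
        order_truth = sorted(shares, key=shares.get)
        order_pct = sorted(
            (b.name for b in cfg.blocks), key=gt.expected_pct_explained.get
        )
        assert order_truth == order_pct

    def test_write_reads_back(self, tmp_path, tiny_cohort):
        tiny_cohort.write(tmp_path)
        assert (tmp_path / "manifest.yaml").exists()
        cog = pd.read_csv(tmp_path / "cognitive_raw.tsv", sep="\t", index_col=0)
        assert cog.shape == tiny_cohort.cognitive_raw.shape
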