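"""Synthetic cohort generation: determinism, moment matching, and the
closed-form incremental-R2 oracle."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from cogreserve import synthetic as syn
from cogreserve.regression import ModelSpec, fit_hierarchical


def single_proxy_config(beta=1.0, residual_sd=0.0, n=50, seed=3):
    plan = syn.EffectPlan(
        beta_age={c: 0.0 for c in syn.COGNITION_NAMES},
        beta_sex={c: 0.0 for c in syn.COGNITION_NAMES},
        beta_brain={},
        beta_proxy={("p1", c): beta for c in syn.COGNITION_NAMES},
    )
    return syn.CohortConfig(
        n=n, seed=seed, proxy_names=("p1",), proxy_corr=np.eye(1),
        brain_names=syn.BRAIN_NAMES, cognition_names=syn.COGNITION_NAMES,
        age_range=(54, 88), sex_balance=0.5, effect_plan=plan,
        residual_sd={c: residual_sd for c in syn.COGNITION_NAMES},
    )


class TestDefaultConfig:
    def test_tilda_template_shape(self, tilda_config):
        assert len(tilda_config.proxy_names) == 7
        assert len(tilda_config.brain_names) == 3
        assert len(tilda_config.cognition_names) == 5

    def test_crrann_template_shape(self, crrann_config):
        assert len(crrann_config.proxy_names) == 5
        assert crrann_config.n == 234

    @pytest.mark.parametrize("template", ["tilda", "TILDA-like", "crrann", "CR/RANN"])
    def test_correlations_positive_semidefinite(self, template):
        cfg = syn.default_config(template)
        assert np.linalg.eigvalsh(cfg.proxy_corr).min() > 0

    def test_unknown_template_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            syn.default_config("ukbiobank")

    def test_signs_of_planted_effects(self, tilda_config):
        plan = tilda_config.effect_plan
        assert all(v < 0 for v in plan.beta_age.values())
        assert all(v > 0 for v in plan.beta_brain.values())


class TestGenerateCohort:
    def test_deterministic_for_same_seed(self):
        cfg = syn.default_config("tilda", n=60, seed=42)
        assert syn.generate_cohort(cfg).equals(syn.generate_cohort(cfg))

    def test_different_seed_differs(self):
        a = syn.generate_cohort(syn.default_config("tilda", n=60, seed=1))
        b = syn.generate_cohort(syn.default_config("tilda", n=60, seed=2))
        assert not a.equals(b)

    def test_noiseless_single_proxy_linear_map(self):
        df = syn.generate_cohort(single_proxy_config(beta=1.0, residual_sd=0.0))
        for c in syn.COGNITION_NAMES:
            assert np.allclose(df[c], df["p1"])

    def test_moment_matching_at_20000(self):
        cfg = syn.default_config("tilda", n=20000, seed=7)
        df = syn.generate_cohort(cfg)
        emp = df[list(cfg.proxy_names)].corr().to_numpy()
        assert np.abs(emp - cfg.proxy_corr).max() < 0.02
        means = {c: df[c].mean() for c in cfg.cognition_names}
        plan = cfg.effect_plan
        for c, m in means.items():
            expected = plan.beta_sex[c] * cfg.sex_balance  # only sex has nonzero mean
            assert abs(m - expected) < 0.05

    def test_age_and_sex_ranges(self, tilda_cohort, tilda_config):
        lo, hi = tilda_config.age_range
        assert tilda_cohort["age"].between(lo, hi).all()
        assert set(tilda_cohort["sex"].unique()) <= {0.0, 1.0}

    def test_brain_age_coupling_negative(self):
        cfg = syn.default_config("tilda", n=20000, seed=11)
        df = syn.generate_cohort(cfg)
        for b in cfg.brain_names:
            r = np.corrcoef(df["age_z"], df[b])[0, 1]
            assert abs(r - cfg.brain_age_loading) < 0.03

    def test_non_psd_matrix_rejected(self):
        cfg = syn.default_config("tilda", n=50)
        bad = np.array(cfg.proxy_corr)
        bad[0, 1] = bad[1, 0] = 0.999
        bad[0, 2] = bad[2, 0] = 0.999
        bad[1, 2] = bad[2, 1] = -0.999
        with pytest.raises(ValueError, match="semi-definite"):
            replace(cfg, proxy_corr=bad).validate()

    def test_tiny_cohort_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            syn.generate_cohort(syn.default_config("tilda", n=5))

    def test_missing_rate_produces_mcar_gaps(self):
        cfg = replace(syn.default_config("tilda", n=4000, seed=5), missing_rate=0.1)
        df = syn.generate_cohort(cfg)
        frac = df["education"].isna().mean()
        assert 0.07 < frac < 0.13
        assert df["age"].notna().all()

    def test_contamination_widens_tails(self):
        base = syn.default_config("tilda", n=4000, seed=9)
        heavy = replace(base, contamination_frac=0.1, contamination_scale=10.0)
        sd_clean = syn.generate_cohort(base)["global_cognition"].std()
        sd_heavy = syn.generate_cohort(heavy)["global_cognition"].std()
        assert sd_heavy > 1.5 * sd_clean


class TestPlantedDeltaR2:
    def test_zero_beta_gives_zero(self):
        cfg = single_proxy_config(beta=0.0, residual_sd=1.0)
        assert syn.planted_delta_r2(cfg, "p1", "global_cognition") == pytest.approx(0.0)

    def test_orthogonal_proxy_closed_form(self):
        # proxy independent of age/sex/brain: dR2 = b^2 Var(p) / Var(y)
        b, sd = 0.4, 0.8
        cfg = single_proxy_config(beta=b, residual_sd=sd)
        expected = b ** 2 / (b ** 2 + sd ** 2)
        got = syn.planted_delta_r2(cfg, "p1", "global_cognition",
                                   brain="grey_matter_volume")
        assert got == pytest.approx(expected, abs=1e-12)

    def test_matches_largescale_empirical_delta_r2(self, tilda_config):
        cfg = replace(tilda_config, n=200000)
        q = syn.planted_delta_r2(cfg, "verbal_intelligence", "global_cognition",
                                 brain="grey_matter_volume")
        df = syn.generate_cohort(cfg)
        res = fit_hierarchical(
            df, ModelSpec("tilda", "grey_matter_volume", "global_cognition"),
            "verbal_intelligence", robust=False)
        assert res.delta_r2_step2 == pytest.approx(q, abs=0.005)

    def test_nonzero_interaction_rejected(self):
        cfg = single_proxy_config(beta=0.3, residual_sd=1.0)
        plan = replace(cfg.effect_plan, beta_interaction={
            ("p1", "grey_matter_volume", "global_cognition"): 0.2})
        cfg = replace(cfg, effect_plan=plan)
        with pytest.raises(ValueError, match="moderation"):
            syn.planted_delta_r2(cfg, "p1", "global_cognition")

    def test_unknown_names_rejected(self, tilda_config):
        with pytest.raises(ValueError, match="unknown proxy"):
            syn.planted_delta_r2(tilda_config, "nope", "global_cognition")


class TestIO:
    def test_cohort_csv_roundtrip(self, tmp_path, tilda_cohort):
        path = tmp_path / "cohort.csv"
        syn.write_cohort(tilda_cohort, path)
        back = syn.read_cohort(path)
        pd.testing.assert_frame_equal(back, tilda_cohort, check_exact=False)

    def test_config_yaml_roundtrip(self, tmp_path, tilda_config):
        path = tmp_path / "config.yaml"
        syn.config_to_yaml(tilda_config, path)
        back = syn.config_from_yaml(path)
        assert back.n == tilda_config.n
        assert back.proxy_names == tilda_config.proxy_names
        assert np.allclose(back.proxy_corr, tilda_config.proxy_corr)
        assert back.effect_plan.beta_proxy == dict(tilda_config.effect_plan.beta_proxy)
        assert syn.generate_cohort(back).equals(syn.generate_cohort(tilda_config))
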