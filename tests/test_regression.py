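"""The hierarchical regression engine: OLS steps, partial F inference, and
the robust IRLS re-fit."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from cogreserve.regression import (CompleteReserveModel, ModelSpec,
                                   build_model_grid, fit_hierarchical,
                                   fit_irls_tukey, fit_ols, partial_f_test)


@pytest.fixture()
def design(rng):
    n = 200
    X = pd.DataFrame({
        "x1": rng.standard_normal(n),
        "x2": rng.standard_normal(n),
        "x3": rng.standard_normal(n),
    })
    y = 0.5 * X.x1 - 0.25 * X.x2 + rng.standard_normal(n)
    return y.to_numpy(), X


class TestModelGrid:
    def test_three_by_five(self):
        grid = build_model_grid(list("ABC"), list("vwxyz"), dataset="d")
        assert len(grid) == 15
        assert grid[0] == ModelSpec("d", "A", "v")
        assert [s.brain for s in grid[:5]] == ["A"] * 5  # brain-major order

    def test_degenerate_grid(self):
        assert len(build_model_grid(["A"], ["v"])) == 1

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            build_model_grid(["A", "A"], ["v"])


class TestFitOls:
    def test_perfect_fit(self, rng):
        X = pd.DataFrame({"x": rng.standard_normal(30)})
        fit = fit_ols(2.0 * X["x"] + 1.0, X)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.params["x"] == pytest.approx(2.0)

    def test_null_model_r2_small_and_ci_coverage(self):
        # under independence, the slope CI covers 0 at ~ the nominal rate
        rng = np.random.default_rng(99)
        n, reps, covered = 250, 600, 0
        r2s = []
        for _ in range(reps):
            X = pd.DataFrame({"x": rng.standard_normal(n)})
            fit = fit_ols(rng.standard_normal(n), X)
            r2s.append(fit.r_squared)
            half = stats.t.ppf(0.975, fit.df_resid) * fit.bse["x"]
            covered += abs(fit.params["x"]) <= half
        assert np.mean(r2s) < 0.02
        assert 0.92 <= covered / reps <= 0.98

    def test_rank_deficiency_names_offenders(self, rng):
        x = rng.standard_normal(50)
        X = pd.DataFrame({"x1": x, "x2": 2 * x})
        with pytest.raises(ValueError, match="x1|x2"):
            fit_ols(rng.standard_normal(50), X)

    def test_too_few_cases_rejected(self, rng):
        X = pd.DataFrame({"a": [1.0, 2.0], "b": [0.5, 0.1]})
        with pytest.raises(ValueError, match="complete cases"):
            fit_ols(np.array([1.0, 2.0]), X)

    def test_standardized_beta_matches_zscore_fit(self, design):
        y, X = design
        fit = fit_ols(y, X)
        zX = (X - X.mean()) / X.std(ddof=1)
        zy = (y - y.mean()) / y.std(ddof=1)
        zfit = sm.OLS(zy, sm.add_constant(zX)).fit()
        for name in X.columns:
            assert fit.beta[name] == pytest.approx(zfit.params[name], abs=1e-10)

    def test_scale_equivariance(self, design):
        y, X = design
        a, b = fit_ols(y, X), fit_ols(10.0 * y, X)
        assert np.allclose(b.params.values, 10.0 * a.params.values)
        assert b.r_squared == pytest.approx(a.r_squared)
        assert b.f_stat == pytest.approx(a.f_stat)


class TestPartialFTest:
    def test_no_improvement(self, design):
        y, X = design
        small = fit_ols(y, X[["x1", "x2"]])
        big = fit_ols(y, X)
        # an added term contributing nothing yields F = 0, p = 1
        from dataclasses import replace
        degenerate = replace(big, r_squared=small.r_squared)
        assert partial_f_test(small, degenerate) == (0.0, 1.0)

    def test_tsquared_equals_f_for_single_term(self, design):
        y, X = design
        small = fit_ols(y, X[["x1", "x2"]])
        big = fit_ols(y, X)
        f, p = partial_f_test(small, big)
        t = big.params["x3"] / big.bse["x3"]
        assert f == pytest.approx(t * t, abs=1e-10)
        assert p == pytest.approx(big.pvalues["x3"], abs=1e-12)

    def test_matches_ssr_oracle(self, rng):
        n = 120
        X = pd.DataFrame(rng.standard_normal((n, 4)), columns=list("abcd"))
        y = X["a"].to_numpy() + rng.standard_normal(n)
        small = fit_ols(y, X[["a", "b"]])
        big = fit_ols(y, X)
        f, p = partial_f_test(small, big)
        # brute-force residual-sum-of-squares formulation
        def ssr(cols):
            d = sm.add_constant(X[cols])
            r = y - d @ np.linalg.lstsq(d, y, rcond=None)[0]
            return r @ r
        m, df_big = 2, n - 5
        f_ssr = ((ssr(["a", "b"]) - ssr(list("abcd"))) / m) / (ssr(list("abcd")) / df_big)
        assert f == pytest.approx(f_ssr, rel=1e-10)
        assert p == pytest.approx(stats.f.sf(f_ssr, m, df_big), rel=1e-10)

    def test_non_nested_rejected(self, design):
        y, X = design
        with pytest.raises(ValueError, match="nested"):
            partial_f_test(fit_ols(y, X[["x1"]]), fit_ols(y, X[["x2", "x3"]]))


class TestIrlsTukey:
    def test_large_c_limit_equals_ols(self, design):
        y, X = design
        robust = fit_irls_tukey(y, X, c=1e8)
        ols = fit_ols(y, X)
        for name in ("const", "x1", "x2", "x3"):
            assert robust.params[name] == pytest.approx(ols.params[name], abs=1e-6)

    def test_gross_outlier_gets_zero_weight(self, rng):
        n = 80
        X = pd.DataFrame({"x": rng.standard_normal(n)})
        y = X["x"].to_numpy() + 0.3 * rng.standard_normal(n)
        y[0] += 100.0
        fit = fit_irls_tukey(y, X)
        assert fit.weights[0] == 0.0
        assert fit.converged

    def test_weights_in_unit_interval_and_decreasing_in_resid(self, rng):
        n = 150
        X = pd.DataFrame({"x": rng.standard_normal(n)})
        y = X["x"].to_numpy() + rng.standard_t(df=3, size=n)
        fit = fit_irls_tukey(y, X)
        assert np.all((fit.weights >= 0) & (fit.weights <= 1))
        design = np.column_stack([np.ones(n), X.to_numpy()])
        resid = np.abs(y - design @ fit.params.to_numpy())
        order = np.argsort(resid)
        assert np.all(np.diff(fit.weights[order]) <= 1e-12)

    def test_matches_statsmodels_rlm(self, rng):
        n = 200
        X = pd.DataFrame({"x1": rng.standard_normal(n), "x2": rng.standard_normal(n)})
        y = 1.0 + 0.5 * X.x1.to_numpy() + rng.standard_normal(n)
        y[:20] += 15.0 * rng.standard_normal(20)
        mine = fit_irls_tukey(y, X, scale_center="zero")
        ref = sm.RLM(y, sm.add_constant(X),
                     M=sm.robust.norms.TukeyBiweight()).fit(scale_est="mad")
        assert np.allclose(mine.params.values, ref.params, atol=1e-6)
        assert np.allclose(mine.bse.values, ref.bse, rtol=1e-4)

    def test_robust_beats_ols_under_contamination(self):
        rng = np.random.default_rng(55)
        wins = 0
        reps = 200
        for _ in range(reps):
            n = 100
            X = pd.DataFrame({"x": rng.standard_normal(n)})
            y = 1.5 * X["x"].to_numpy() + rng.standard_normal(n)
            # ~10% gross outliers from a corrupting process opposing the trend
            bad = rng.random(n) < 0.10
            y = np.where(bad, -15.0 * X["x"].to_numpy() + rng.normal(0, 5, n), y)
            robust = fit_irls_tukey(y, X).params["x"]
            ols = fit_ols(y, X).params["x"]
            wins += abs(robust - 1.5) < abs(ols - 1.5)
        assert wins / reps >= 0.90

    def test_scale_equivariance(self, design):
        y, X = design
        a = fit_irls_tukey(y, X)
        b = fit_irls_tukey(10.0 * y, X)
        assert np.allclose(b.params.values, 10.0 * a.params.values, rtol=1e-6)
        assert np.allclose(b.pvalues.values, a.pvalues.values, atol=1e-8)

    def test_zero_scale_rejected(self):
        # exactly representable fit: residuals identically zero, MAD scale 0
        X = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="scale"):
            fit_irls_tukey(np.array([1.0, 3.0, 5.0, 7.0]), X)

    def test_nonconvergence_flagged(self, rng):
        n = 60
        X = pd.DataFrame({"x": rng.standard_normal(n)})
        y = X["x"].to_numpy() + rng.standard_t(df=2, size=n)
        fit = fit_irls_tukey(y, X, max_iter=1)
        assert not fit.converged
        assert fit.n_iter == 1


class TestCompleteReserveModel:
    @pytest.fixture()
    def cell(self, tilda_cohort):
        model = CompleteReserveModel(
            tilda_cohort, brain="grey_matter_volume",
            cognition="global_cognition", proxy="verbal_intelligence",
            dataset="tilda")
        return model.fit()

    def test_r2_nondecreasing_and_deltas_nonnegative(self, cell):
        r2 = [f.r_squared for f in cell.step_fits]
        assert r2[0] <= r2[1] <= r2[2]
        assert cell.delta_r2_step2 >= 0
        assert cell.delta_r2_step3 >= 0

    def test_added_term_p_equals_partial_f_p(self, cell):
        f1, f2, f3 = cell.step_fits
        _, p2 = partial_f_test(f1, f2)
        _, p3 = partial_f_test(f2, f3)
        assert cell.p_added_step2 == pytest.approx(p2, abs=1e-10)
        assert cell.p_added_step3 == pytest.approx(p3, abs=1e-10)

    def test_planted_positive_proxy_detected(self, cell):
        assert cell.p_added_step2 < 1e-6
        assert cell.proxy_sign == 1
        assert cell.robust_p_step2 < 1e-6

    def test_summary_mentions_key_quantities(self, cell):
        text = cell.summary()
        assert "independent effect" in text
        assert "moderation effect" in text
        assert "verbal_intelligence" in text

    def test_proxy_equal_to_brain_rejected(self, tilda_cohort):
        df = tilda_cohort.assign(dup=tilda_cohort["grey_matter_volume"])
        model = CompleteReserveModel(df, brain="grey_matter_volume",
                                     cognition="global_cognition", proxy="dup")
        with pytest.raises(ValueError, match="rank deficient|collinear"):
            model.fit()

    def test_missing_column_rejected(self, tilda_cohort):
        with pytest.raises(ValueError, match="not found"):
            CompleteReserveModel(tilda_cohort, brain="nope",
                                 cognition="global_cognition", proxy="education")

    def test_complete_cases_only(self, tilda_cohort):
        df = tilda_cohort.copy()
        df.loc[:9, "verbal_intelligence"] = np.nan
        res = fit_hierarchical(
            df, ModelSpec("tilda", "grey_matter_volume", "global_cognition"),
            "verbal_intelligence", robust=False)
        assert res.n == len(df) - 10
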