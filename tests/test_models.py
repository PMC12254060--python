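"""Effort regressions, gVIF screen, AIC comparison, Tukey contrasts, seasonal LMM."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from polliturn.models import (
    RegressionSpec,
    compare_aic,
    fit_effort_regression,
    fit_seasonal_lmm,
    gvif,
    gvif_screen,
    orthogonal_poly,
    plot_count_contrasts,
)


def effort_frame(rng=None, n_weeks=20, noise=0.0, fn=None):
    """Synthetic aggregate table over a 6-level plot grid and a season."""
    rng = rng or np.random.default_rng(0)
    rows = []
    for w in range(n_weeks):
        day = 150.0 + 5 * w
        for n_plots in range(1, 7):
            y = fn(day, n_plots) if fn else 0.5
            rows.append({"day_mid": day, "n_plots": n_plots,
                         "beta_wn": y + (rng.normal(0, noise) if noise else 0.0)})
    return pd.DataFrame(rows)


class TestOrthogonalPoly:
    def test_orthonormal_and_centered(self):
        x = np.linspace(0, 9, 40)
        basis = orthogonal_poly(x, 2)
        assert np.allclose(basis.T @ basis, np.eye(2), atol=1e-10)
        assert np.allclose(basis.sum(axis=0), 0, atol=1e-10)


class TestEffortRegression:
    def test_noiseless_linear_recovery(self):
        data = effort_frame(fn=lambda d, k: 0.8 - 0.05 * k)
        fit = fit_effort_regression(
            data, RegressionSpec(day_degree=1, plots_degree=1, orthogonal=False)
        )
        assert fit.params["n_plots"] == pytest.approx(-0.05, abs=1e-10)
        assert fit.result.ssr == pytest.approx(0.0, abs=1e-18)

    def test_quadratic_recovery_within_3se(self):
        rng = np.random.default_rng(12)
        truth = lambda d, k: 0.9 - 0.004 * d + 8e-6 * d**2 - 0.03 * k
        data = effort_frame(rng=rng, noise=0.02, fn=truth)
        fit = fit_effort_regression(
            data, RegressionSpec(day_degree=2, plots_degree=1, orthogonal=False)
        )
        for term, true_val in [("day", -0.004), ("day^2", 8e-6), ("n_plots", -0.03)]:
            est, se = fit.params[term], fit.result.bse[term]
            assert abs(est - true_val) < 3 * se

    def test_duplicate_predictor_is_rank_error(self):
        data = effort_frame(fn=lambda d, k: 0.5)
        data["n_plots"] = 3  # constant -> aliased with intercept
        with pytest.raises(ValueError, match="rank|distinct"):
            fit_effort_regression(data, RegressionSpec(plots_degree=1, orthogonal=False))

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(2)
        data = effort_frame(rng=rng, noise=0.05, fn=lambda d, k: 0.6 - 0.02 * k)
        fit = fit_effort_regression(data, RegressionSpec())
        resid = fit.result.resid
        assert np.allclose(fit.design.T @ resid, 0, atol=1e-8)


class TestGvif:
    def test_orthogonal_predictors_unity(self):
        rng = np.random.default_rng(1)
        raw = rng.normal(size=(100, 4))
        X = np.linalg.qr(raw - raw.mean(axis=0))[0]  # centered => uncorrelated
        table = gvif(X, {"a": [0, 1], "b": [2], "c": [3]})
        assert np.allclose(table["gvif_adj"], 1.0, atol=1e-10)

    def test_matches_determinant_oracle(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=(200, 2))
        X = np.column_stack([base, base @ [0.7, 0.3] + 0.4 * rng.normal(size=200)])
        terms = {"t1": [0], "t2": [1], "t3": [2]}
        table = gvif(X, terms).set_index("term")
        R = np.corrcoef(X, rowvar=False)
        for name, cols in terms.items():
            others = [i for i in range(3) if i not in cols]
            expected = (
                np.linalg.det(R[np.ix_(cols, cols)])
                * np.linalg.det(R[np.ix_(others, others)])
                / np.linalg.det(R)
            )
            assert table.loc[name, "gvif"] == pytest.approx(expected)

    def test_single_term_screen_trivially_passes(self):
        # a model with one multi-column term only: build directly
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 2))
        table = gvif(X, {"only": [0, 1]})
        assert table["gvif_adj"].iloc[0] == pytest.approx(1.0, abs=1e-8)

    def test_raw_interaction_triggers_drop(self, reference_records):
        from polliturn.effort import aggregate_effort, effort_analysis

        agg = aggregate_effort(effort_analysis(
            [r for r in reference_records if r.year in (2015, 2016, 2017)]
        ))
        sub = agg[agg["method"] == "poisot"]
        fit = fit_effort_regression(
            sub, RegressionSpec(include_interaction=True, orthogonal=False)
        )
        decision = gvif_screen(fit)
        assert decision.before.set_index("term").loc["day:n_plots", "gvif_adj"] > 5
        assert decision.drop_interaction
        assert (decision.after["gvif_adj"] < 1.5).all()


class TestCompareAic:
    def test_identical_models_zero_delta(self):
        data = effort_frame(noise=0.01, rng=np.random.default_rng(3),
                            fn=lambda d, k: 0.5)
        f = fit_effort_regression(data, RegressionSpec())
        ranked = compare_aic([f, f])
        assert ranked["delta_aic"].iloc[1] == pytest.approx(0.0)

    def test_quadratic_truth_prefers_quadratic(self):
        rng = np.random.default_rng(9)
        truth = lambda d, k: 0.4 + 3e-5 * (d - 200) ** 2 - 0.02 * k
        data = effort_frame(rng=rng, noise=0.02, fn=truth)
        lin = fit_effort_regression(data, RegressionSpec(day_degree=1, plots_degree=1))
        quad = fit_effort_regression(data, RegressionSpec(day_degree=2, plots_degree=2))
        ranked = compare_aic([lin, quad])
        assert "2" in ranked["spec"].iloc[0]

    def test_aic_invariant_to_centering(self):
        rng = np.random.default_rng(14)
        data = effort_frame(rng=rng, noise=0.03, fn=lambda d, k: 0.6 - 0.01 * k)
        raw = fit_effort_regression(data, RegressionSpec(orthogonal=False))
        orth = fit_effort_regression(data, RegressionSpec(orthogonal=True))
        assert raw.aic == pytest.approx(orth.aic, abs=1e-8)

    def test_noise_penalty_bound(self):
        """On pure noise the richer model cannot beat the simpler one by
        more than the AIC parameter penalty, on average over seeds."""
        deltas = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            data = effort_frame(rng=rng, noise=0.1, fn=lambda d, k: 0.5, n_weeks=34)
            lin = fit_effort_regression(data, RegressionSpec(day_degree=1, plots_degree=1))
            quad = fit_effort_regression(data, RegressionSpec(day_degree=2, plots_degree=2))
            deltas.append(lin.aic - quad.aic)
        assert np.mean(deltas) < 2 * 2  # two extra parameters

    def test_different_observations_rejected(self):
        d1 = effort_frame(noise=0.01, rng=np.random.default_rng(1), fn=lambda d, k: 0.5)
        d2 = effort_frame(noise=0.01, rng=np.random.default_rng(2), fn=lambda d, k: 0.5)
        with pytest.raises(ValueError):
            compare_aic([fit_effort_regression(d1, RegressionSpec()),
                         fit_effort_regression(d2, RegressionSpec())])


class TestContrasts:
    def test_six_levels_fifteen_contrasts(self):
        rng = np.random.default_rng(10)
        data = effort_frame(rng=rng, noise=0.02, fn=lambda d, k: 0.6 - 0.03 * k)
        fit = fit_effort_regression(data, RegressionSpec())
        table = plot_count_contrasts(fit)
        assert len(table) == 15
        assert ((table["p_tukey"] >= 0) & (table["p_tukey"] <= 1)).all()

    def test_two_levels_matches_unadjusted_t(self):
        rng = np.random.default_rng(21)
        rows = []
        for w in range(25):
            day = 150.0 + 4 * w
            for n_plots in (1, 2):
                rows.append({"day_mid": day, "n_plots": n_plots,
                             "beta_wn": 0.5 - 0.04 * n_plots + rng.normal(0, 0.05)})
        data = pd.DataFrame(rows)
        fit = fit_effort_regression(data, RegressionSpec(plots_degree=1))
        table = plot_count_contrasts(fit)
        assert len(table) == 1
        # refit the categorical model directly for the unadjusted p-value
        from polliturn.models import orthogonal_poly
        X = np.column_stack([
            np.ones(len(data)),
            orthogonal_poly(data["day_mid"].to_numpy(float), 2),
            (data["n_plots"] == 2).to_numpy(float),
        ])
        res = sm.OLS(data["beta_wn"], X).fit()
        assert table["p_tukey"].iloc[0] == pytest.approx(res.pvalues.iloc[3], rel=1e-6)

    def test_type_one_error_controlled(self):
        """Equal true level means: the familywise minimum adjusted p stays
        above 0.05 in at least the nominal share of replicates."""
        hits = 0
        n_rep = 100
        for seed in range(n_rep):
            rng = np.random.default_rng(1000 + seed)
            data = effort_frame(rng=rng, noise=0.05, fn=lambda d, k: 0.5, n_weeks=15)
            fit = fit_effort_regression(data, RegressionSpec())
            if plot_count_contrasts(fit)["p_tukey"].min() > 0.05:
                hits += 1
        assert hits >= 92  # binomial margin around 95/100

    def test_symmetric_under_relabeling(self):
        rng = np.random.default_rng(17)
        data = effort_frame(rng=rng, noise=0.03, fn=lambda d, k: 0.6 - 0.02 * k)
        fit = fit_effort_regression(data, RegressionSpec())
        table = plot_count_contrasts(fit).set_index(["level_1", "level_2"])
        flipped = data.assign(n_plots=7 - data["n_plots"])
        fit2 = fit_effort_regression(flipped, RegressionSpec())
        table2 = plot_count_contrasts(fit2).set_index(["level_1", "level_2"])
        for (i, j), row in table.iterrows():
            mirror = table2.loc[(7 - j, 7 - i)]
            assert row["estimate"] == pytest.approx(-mirror["estimate"], rel=1e-6)
            assert row["p_tukey"] == pytest.approx(mirror["p_tukey"], rel=1e-4)


def lmm_frame(rng, year_sd=0.1, resid_sd=0.05, n_years=8, n_weeks=15,
              day_lin=0.0, day_quad=0.0):
    rows = []
    for y in range(n_years):
        b0 = rng.normal(0, year_sd)
        for w in range(n_weeks):
            day = 150.0 + 7 * w
            d = day - 199.0
            rows.append({
                "year": 2015 + y,
                "day_mid": day,
                "beta_wn": 0.5 + b0 + day_lin * d + day_quad * d**2
                + rng.normal(0, resid_sd),
            })
    return pd.DataFrame(rows)


class TestSeasonalLmm:
    def test_zero_year_variance_boundary(self):
        rng = np.random.default_rng(31)
        fit = fit_seasonal_lmm(lmm_frame(rng, year_sd=0.0))
        assert fit.re_variance < 1e-4

    def test_variance_component_recovery(self):
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            fit = fit_seasonal_lmm(lmm_frame(rng, year_sd=0.1, resid_sd=0.05))
            errs.append(abs(np.sqrt(fit.re_variance) - 0.1) / 0.1)
        assert np.median(errs) < 0.5

    def test_negative_day_slope_recovered(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            fit = fit_seasonal_lmm(lmm_frame(rng, day_lin=-0.002))
            hits += fit.fe_params["day"] < 0
        assert hits >= 18

    def test_matches_ols_when_no_year_effect(self):
        rng = np.random.default_rng(8)
        data = lmm_frame(rng, year_sd=0.0, day_lin=-0.001, day_quad=-1e-5)
        fit = fit_seasonal_lmm(data)
        d = data["day_mid"] - data["day_mid"].mean()
        X = sm.add_constant(np.column_stack([d, d**2]))
        ols = sm.OLS(data["beta_wn"], X).fit()
        assert np.allclose(fit.fe_params, ols.params, atol=1e-3)

    def test_single_year_rejected(self):
        rng = np.random.default_rng(1)
        with pytest.raises(ValueError, match="ordinary regression"):
            fit_seasonal_lmm(lmm_frame(rng, n_years=1))

    def test_too_few_rows_rejected(self):
        rng = np.random.default_rng(1)
        with pytest.raises(ValueError, match="10"):
            fit_seasonal_lmm(lmm_frame(rng, n_years=2, n_weeks=2))
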