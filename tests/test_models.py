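"""Statistical layer: OLS equation development, the time-after-eating
mixed model, through-origin evaluation, residual-vs-DIM diagnostics."""

import numpy as np
import pandas as pd
import pytest

from entch4 import models, synthdata as sd
from entch4.formulas import load_equations


def ols_normal_equations(X, y):
    """Independent oracle: solve (X'X) b = X'y directly."""
    Xc = np.column_stack([np.ones(len(X)), X])
    return np.linalg.solve(Xc.T @ Xc, Xc.T @ y)


class TestFitEquation:
    def test_agrees_with_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = int(rng.integers(8, 21))
            p = int(rng.integers(1, 4))
            X = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            df = pd.DataFrame(X, columns=[f"x{j}" for j in range(p)])
            df["y"] = y
            # covariate-key validation is for cow panels; bypass via rename
            df = df.rename(columns={f"x{j}": c for j, c in enumerate(["LW", "DMI", "ECM"][:p])})
            covs = ["LW", "DMI", "ECM"][:p]
            fit = models.fit_equation(df, "y", covs)
            oracle = ols_normal_equations(df[covs].to_numpy(), y)
            got = np.array([fit.spec.intercept] + [fit.spec.coefficients[c] for c in covs])
            np.testing.assert_allclose(got, oracle, rtol=1e-8)

    def test_recovers_generating_equation(self):
        # panel simulated from the published LW+ECM+ratio equation with
        # its reported residual scale; the refit must land within
        # Monte-Carlo error of the generating coefficients
        cfg = sd.PanelConfig(n=10000, r_lw_dmi=0.0, r_dmi_ecm=0.0, seed=20210930)
        panel = sd.gen_cow_panel(cfg)
        fit = models.fit_equation(panel, "CH4", ["LW", "ECM", "CH4CO2"])
        eq2 = load_equations()["eq2"]
        for cov, truth in eq2.coefficients.items():
            est = fit.spec.coefficients[cov]
            se = fit.spec.coefficient_se[cov]
            assert abs(est - truth) < 3 * se
        assert fit.rmse == pytest.approx(40.8, rel=0.03)

    def test_noise_free_fit_is_exact(self):
        cfg = sd.PanelConfig(n=200, noise_sd=1e-9, seed=2)
        panel = sd.gen_cow_panel(cfg)
        fit = models.fit_equation(panel, "CH4", ["LW", "ECM", "CH4CO2"])
        assert np.allclose(fit.residuals, 0.0, atol=1e-6)
        assert fit.adj_r2 == pytest.approx(1.0)

    def test_collinear_design_rejected(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"LW": rng.normal(650, 50, 50)})
        df["DMI"] = 2.0 * df["LW"]
        df["y"] = rng.normal(size=50)
        with pytest.raises(models.CollinearityError):
            models.fit_equation(df, "y", ["LW", "DMI"])

    def test_rmse_identity_and_vif_floor(self):
        cfg = sd.PanelConfig(n=500, seed=9)
        panel = sd.gen_cow_panel(cfg)
        fit = models.fit_equation(panel, "CH4", ["LW", "DMI", "ECM", "CH4CO2"])
        p = 4
        assert fit.rmse**2 * (fit.n - p - 1) == pytest.approx(np.sum(fit.residuals**2))
        assert all(v >= 1.0 for v in fit.vif.values())

    def test_vif_of_orthogonal_covariates_is_one(self):
        n = 64
        t = np.arange(n)
        df = pd.DataFrame(
            {"LW": np.cos(2 * np.pi * t / n), "DMI": np.sin(2 * np.pi * t / n)}
        )
        df["y"] = df["LW"] + np.random.default_rng(0).normal(0, 0.1, n)
        fit = models.fit_equation(df, "y", ["LW", "DMI"])
        assert fit.vif["LW"] == pytest.approx(1.0, abs=1e-9)
        assert fit.vif["DMI"] == pytest.approx(1.0, abs=1e-9)

    def test_missing_values_rejected(self):
        df = pd.DataFrame({"LW": [1.0, np.nan, 3.0], "y": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="missing"):
            models.fit_equation(df, "y", ["LW"])


class TestTimeModel:
    def test_recovers_generating_slope_and_diet_effects(self):
        panel = sd.gen_visit_panel(sd.VisitPanelConfig(seed=20210930))
        fit = models.fit_time_model(panel)
        assert abs(fit.coef("time") - (-0.0034)) < 2 * fit.se("time")
        assert abs(fit.coef("diet:LF") - (-0.026)) < 2 * fit.se("diet:LF")
        assert abs(fit.coef("diet:MF") - (-0.016)) < 2 * fit.se("diet:MF")
        assert fit.converged

    def test_reference_level_is_high_fibre(self):
        panel = sd.gen_visit_panel()
        fit = models.fit_time_model(panel)
        assert fit.reference_diet == "HF"
        assert "diet:HF" not in fit.fixed.index
        assert {"intercept", "time", "diet:LF", "diet:MF", "time:LF", "time:MF"} == set(
            fit.fixed.index
        )

    def test_zero_noise_zero_random_effects_exact(self):
        cfg = sd.VisitPanelConfig(
            square_sd=0.0, cow_sd=0.0, residual_sd=1e-12, visits_per_cow_diet=20, seed=6
        )
        panel = sd.gen_visit_panel(cfg)
        fit = models.fit_time_model(panel, random_effects=False)
        assert fit.coef("time") == pytest.approx(cfg.time_slope, abs=1e-8)
        assert fit.coef("diet:LF") == pytest.approx(cfg.diet_offsets["LF"], abs=1e-8)
        assert fit.coef("intercept") == pytest.approx(cfg.intercept, abs=1e-8)

    def test_single_diet_reduces_to_time_model(self):
        cfg = sd.VisitPanelConfig(diets=("HF",), seed=7)
        panel = sd.gen_visit_panel(cfg)
        fit = models.fit_time_model(panel)
        assert set(fit.fixed.index) == {"intercept", "time"}
        # reduced-model oracle: plain OLS slope on the same rows
        b = np.polyfit(panel["time"], panel["ratio"], 1)[0]
        assert fit.coef("time") == pytest.approx(b, abs=2e-4)

    def test_ols_limit_matches_dummy_variable_oracle(self):
        panel = sd.gen_visit_panel(sd.VisitPanelConfig(seed=8, visits_per_cow_diet=10))
        fit = models.fit_time_model(panel, random_effects=False)
        # oracle: normal equations on the explicit dummy design
        d_lf = (panel["diet"] == "LF").to_numpy(float)
        d_mf = (panel["diet"] == "MF").to_numpy(float)
        t = panel["time"].to_numpy()
        X = np.column_stack([t, t * d_lf, t * d_mf, d_lf, d_mf])
        Xc = np.column_stack([np.ones(len(X)), X])
        beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ panel["ratio"].to_numpy())
        np.testing.assert_allclose(
            [fit.coef("intercept"), fit.coef("time"), fit.coef("time:LF"),
             fit.coef("time:MF"), fit.coef("diet:LF"), fit.coef("diet:MF")],
            beta,
            rtol=1e-8,
        )

    def test_reml_close_to_ols_when_no_random_effects_generated(self):
        cfg = sd.VisitPanelConfig(square_sd=0.0, cow_sd=0.0, seed=10)
        panel = sd.gen_visit_panel(cfg)
        reml = models.fit_time_model(panel, random_effects=True)
        ols = models.fit_time_model(panel, random_effects=False)
        assert reml.coef("time") == pytest.approx(ols.coef("time"), abs=1e-4)
        assert reml.boundary  # variance components collapse to ~0

    def test_variance_components_recovered(self):
        cfg = sd.VisitPanelConfig(visits_per_cow_diet=120, cows_per_square=4, seed=12)
        panel = sd.gen_visit_panel(cfg)
        fit = models.fit_time_model(panel)
        assert np.sqrt(fit.variance_components["residual"]) == pytest.approx(
            cfg.residual_sd, rel=0.1
        )
        assert np.sqrt(fit.variance_components["cow"]) == pytest.approx(cfg.cow_sd, rel=0.6)

    def test_coefficient_bias_shrinks_with_n(self):
        biases = []
        for visits in (30, 240):
            cfg = sd.VisitPanelConfig(visits_per_cow_diet=visits, seed=13)
            fit = models.fit_time_model(sd.gen_visit_panel(cfg))
            biases.append(abs(fit.coef("time") - cfg.time_slope))
        assert biases[1] < biases[0] + 5e-5

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing column"):
            models.fit_time_model(pd.DataFrame({"ratio": [1.0]}))


class TestThroughOrigin:
    def test_exact_line(self):
        fit = models.regress_through_origin([1.0, 2.0], [2.0, 4.0])
        assert fit.slope == 2.0 and fit.rmse == 0.0

    def test_matches_closed_form_exactly(self, rng):
        x = rng.uniform(1, 10, 200)
        y = 0.8 * x + rng.normal(0, 0.5, 200)
        fit = models.regress_through_origin(x, y)
        assert fit.slope == float(x @ y) / float(x @ x)

    def test_monte_carlo_slope_recovery(self, rng):
        x = rng.uniform(0.05, 0.15, 1000)
        y = 0.81 * x + rng.normal(0, 0.005, 1000)
        fit = models.regress_through_origin(x, y)
        assert 0.79 <= fit.slope <= 0.83

    def test_orthogonal_vectors_give_zero_slope(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        assert models.regress_through_origin(x, y).slope == 0.0

    def test_zero_x_rejected(self):
        with pytest.raises(ValueError):
            models.regress_through_origin(np.zeros(5), np.ones(5))


class TestResidualDimDiagnostic:
    def test_zero_residuals_flat_line(self):
        dim = np.linspace(10, 300, 30)
        obs = np.full(30, 500.0)
        diag = models.residual_dim_diagnostic(obs, obs, dim)
        assert diag.slope == pytest.approx(0.0, abs=1e-12)
        assert not diag.outside.any()

    def test_early_lactation_overestimation_detected(self, rng):
        dim = rng.uniform(5, 300, 200)
        obs = np.full(200, 500.0)
        pred = obs + np.where(dim < 60, 80.0, 0.0) + rng.normal(0, 5, 200)
        diag = models.residual_dim_diagnostic(obs, pred, dim)
        assert diag.slope > 0  # residuals rise with DIM when early cows are overpredicted

    def test_prediction_band_coverage(self, rng):
        # ~95% of Gaussian residuals should fall inside the 95% band
        hits = []
        for _ in range(40):
            dim = rng.uniform(5, 300, 150)
            resid = rng.normal(0, 30, 150)
            diag = models.residual_dim_diagnostic(resid, np.zeros(150), dim)
            hits.append(1.0 - diag.outside.mean())
        assert np.mean(hits) == pytest.approx(0.95, abs=0.02)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            models.residual_dim_diagnostic([1, 2, 3], [1, 2, 3], [1, 2, 3])


class TestEvaluatePredictions:
    def test_perfect_and_scaled_predictions(self, rng):
        obs = rng.uniform(400, 800, 50)
        table = models.evaluate_predictions(
            obs, {"perfect": obs.copy(), "low": 0.9 * obs}
        )
        assert table.loc["perfect", "slope"] == pytest.approx(1.0)
        assert table.loc["perfect", "rmse"] == pytest.approx(0.0, abs=1e-9)
        assert table.loc["low", "slope"] == pytest.approx(0.9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            models.evaluate_predictions([1.0, 2.0], {"p": np.array([1.0])})

    def test_attenuated_ratio_orders_methods(self, rng):
        # AMS ratios attenuated by 0.81 relative to head-box ratios must
        # produce a lower through-origin slope for AMS-based predictions
        obs = rng.uniform(450, 750, 18)
        hb_pred = obs * rng.normal(1.0, 0.02, 18)
        ams_pred = 0.81 * obs * rng.normal(1.0, 0.02, 18)
        table = models.evaluate_predictions(obs, {"headbox": hb_pred, "ams": ams_pred})
        assert table.loc["ams", "slope"] < table.loc["headbox", "slope"]
        assert table.loc["ams", "slope"] == pytest.approx(0.81, abs=0.02)
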