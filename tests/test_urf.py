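import numpy as np
import pandas as pd
import pytest

from clonegxe import build_urf_design, fit_urf, predict_surface
from clonegxe.synthetic import generate_site_climate
from clonegxe.urf import SingularDesignError, URFFit


def climate_tables(n_clusters=20, n_sites=6, seed=0):
    rng = np.random.default_rng(seed)
    origins = pd.DataFrame(
        {
            "cluster": [f"C{i+1:02d}" for i in range(n_clusters)],
            "tmax": rng.uniform(12.0, 20.0, n_clusters),
            "precipitation": rng.uniform(600.0, 2000.0, n_clusters),
        }
    )
    sites = generate_site_climate(n_sites, seed=seed)
    perf = origins.merge(sites, how="cross", suffixes=("_o", "_s"))
    perf = pd.DataFrame(
        {"cluster": perf["cluster"], "site": perf["site_id"], "performance": 0.0}
    )
    return perf, origins, sites


def design_with_known_truth(b, noise_sd=0.0, seed=0, **kw):
    perf, origins, sites = climate_tables(seed=seed, **kw)
    d0 = build_urf_design(perf, origins, sites, ["tmax", "precipitation"])
    A = np.column_stack([np.ones(len(d0.y)), d0.X])
    rng = np.random.default_rng(seed + 1)
    y = A @ b + noise_sd * rng.standard_normal(len(A))
    perf = perf.assign(performance=y)
    return build_urf_design(perf, origins, sites, ["tmax", "precipitation"]), y


class TestBuildDesign:
    def test_single_variable_gives_five_regressors(self):
        perf, origins, sites = climate_tables()
        d = build_urf_design(perf.assign(performance=np.arange(len(perf))), origins, sites, ["tmax"])
        assert len(d.columns) == 5
        assert d.columns == ["tmax_origin", "tmax_origin_sq", "tmax_site", "tmax_site_sq",
                             "tmax_origin_x_site"]

    def test_two_variables_give_ten_regressors_no_cross_products(self):
        d, _ = design_with_known_truth(np.arange(11.0))
        assert len(d.columns) == 10
        assert not any("tmax" in c and "precip" in c for c in d.columns)

    def test_four_site_climates_cannot_identify_site_polynomial(self):
        """Four distinct site climates cannot support four site-level
        polynomial terms plus an intercept — the singularity failure mode
        of response surfaces fitted on few sites."""
        perf, origins, sites = climate_tables(n_sites=4)
        with pytest.raises(SingularDesignError, match="site"):
            build_urf_design(
                perf.assign(performance=1.0 + np.arange(len(perf))), origins, sites,
                ["tmax", "precipitation"],
            )

    def test_missing_variable_errors(self):
        perf, origins, sites = climate_tables()
        with pytest.raises(ValueError, match="windiness"):
            build_urf_design(perf, origins, sites, ["windiness"])


class TestFit:
    def test_noiseless_exact_recovery(self):
        b = np.array([120.0, 15.0, 40.0, -480.0, 1150.0, 36.0, 22.0, 10.0, -970.0, -870.0, 27.0])
        d, _ = design_with_known_truth(b)
        fit = fit_urf(d)
        np.testing.assert_allclose(fit.coef, b, atol=1e-8)
        assert abs(fit.r2 - 1.0) < 1e-10

    def test_matches_least_squares_oracle(self):
        d, y = design_with_known_truth(np.linspace(-2, 2, 11), noise_sd=5.0, seed=3)
        fit = fit_urf(d)
        A = np.column_stack([np.ones(len(y)), d.X])
        oracle, *_ = np.linalg.lstsq(A, d.y, rcond=None)
        np.testing.assert_allclose(fit.coef, oracle, atol=1e-8)

    def test_matches_statsmodels_inference(self):
        import statsmodels.api as sm

        d, y = design_with_known_truth(np.linspace(1, 3, 11), noise_sd=8.0, seed=4)
        fit = fit_urf(d)
        ref = sm.OLS(d.y, sm.add_constant(d.X)).fit()
        np.testing.assert_allclose(fit.coef, ref.params, atol=1e-8)
        np.testing.assert_allclose(fit.se, ref.bse, atol=1e-8)
        np.testing.assert_allclose(fit.p, ref.pvalues, atol=1e-8)
        assert fit.r2 == pytest.approx(ref.rsquared, abs=1e-10)

    def test_coefficient_recovery_within_three_se(self):
        b = np.array([100.0, 12.0, 30.0, -80.0, 60.0, 9.0, 18.0, 7.0, -90.0, -50.0, 11.0])
        d, _ = design_with_known_truth(b, noise_sd=4.0, seed=7)
        fit = fit_urf(d)
        assert np.all(np.abs(fit.coef - b) < 3.0 * fit.se)

    def test_marginal_r2_is_squared_correlation(self):
        d, y = design_with_known_truth(np.linspace(0, 5, 11), noise_sd=3.0, seed=5)
        fit = fit_urf(d)
        j = d.columns.index("tmax_site")
        r = np.corrcoef(d.X[:, j], d.y)[0, 1]
        assert fit.term_r2["tmax_site"] == pytest.approx(r * r, abs=1e-12)

    def test_r2_invariant_to_affine_rescaling_of_regressor(self):
        perf, origins, sites = climate_tables(seed=9)
        rng = np.random.default_rng(2)
        perf = perf.assign(performance=rng.normal(150, 30, len(perf)))
        f1 = fit_urf(build_urf_design(perf, origins, sites, ["tmax", "precipitation"]))
        origins2 = origins.assign(tmax=origins["tmax"] * 1.8 + 32)  # Fahrenheit
        sites2 = sites.assign(tmax=sites["tmax"] * 1.8 + 32)
        f2 = fit_urf(build_urf_design(perf, origins2, sites2, ["tmax", "precipitation"]))
        assert f1.r2 == pytest.approx(f2.r2, abs=1e-9)

    def test_singular_normal_equations_error_not_silent_pinv(self):
        d, _ = design_with_known_truth(np.zeros(11))
        d.X = np.column_stack([d.X, d.X[:, 0]])  # duplicated column
        d.columns = d.columns + ["dup"]
        with pytest.raises(SingularDesignError):
            fit_urf(d)


class TestPredictSurface:
    def fitted(self, seed=0):
        b = np.array([150.0, 10.0, 20.0, -60.0, 45.0, 5.0, 15.0, 8.0, -70.0, -40.0, 6.0])
        d, _ = design_with_known_truth(b, noise_sd=2.0, seed=seed)
        return d, fit_urf(d)

    def test_training_point_reproduces_fitted_value(self):
        d, fit = self.fitted()
        perf, origins, sites = climate_tables()
        row = d.rows.iloc[5]
        oc = origins.set_index("cluster").loc[row["cluster"]]
        sc = sites.set_index("site_id").loc[row["site"]]
        grid = pd.DataFrame({"lon": [0.0], "lat": [0.0], "tmax": [sc["tmax"]],
                             "precipitation": [sc["precipitation"]]})
        surf = predict_surface(fit, grid, {"tmax": oc["tmax"], "precipitation": oc["precipitation"]})
        fitted_value = d.y[5] - fit.residuals[5]
        assert surf["predicted"].iloc[0] == pytest.approx(fitted_value, abs=1e-9)
        assert not surf["extrapolated"].iloc[0]

    def test_constant_grid_gives_constant_surface(self):
        _, fit = self.fitted()
        grid = pd.DataFrame({"lon": [0, 1, 2.0], "lat": [0, 0, 0.0],
                             "tmax": [15.0] * 3, "precipitation": [1400.0] * 3})
        surf = predict_surface(fit, grid, {"tmax": 16.0, "precipitation": 1200.0})
        assert surf["predicted"].nunique() == 1

    def test_out_of_range_cells_are_flagged_never_clipped(self):
        d, fit = self.fitted()
        lo, hi = fit.train_ranges["tmax_site"]
        grid = pd.DataFrame({"lon": [0, 1.0], "lat": [0, 0.0],
                             "tmax": [(lo + hi) / 2, hi + 10.0],
                             "precipitation": [1400.0, 1400.0]})
        surf = predict_surface(fit, grid, {"tmax": 16.0, "precipitation": 1200.0})
        assert surf["extrapolated"].tolist() == [False, True]
        assert np.isfinite(surf["predicted"]).all()

    def test_missing_grid_variable_errors(self):
        _, fit = self.fitted()
        grid = pd.DataFrame({"lon": [0.0], "lat": [0.0], "tmax": [15.0]})
        with pytest.raises(ValueError, match="precipitation"):
            predict_surface(fit, grid, {"tmax": 16.0, "precipitation": 1200.0})

    def test_fit_json_round_trip_predicts_identically(self, tmp_path):
        _, fit = self.fitted()
        p = tmp_path / "urf.json"
        fit.to_json(p)
        back = URFFit.from_json(p)
        grid = pd.DataFrame({"lon": [0.0, 1.0], "lat": [0.0, 1.0],
                             "tmax": [14.0, 16.0], "precipitation": [1000.0, 1800.0]})
        oc = {"tmax": 15.0, "precipitation": 1300.0}
        pd.testing.assert_frame_equal(predict_surface(fit, grid, oc), predict_surface(back, grid, oc))
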