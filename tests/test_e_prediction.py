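"""Tests of the transformation, metrics, model suite and bootstrap loop."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phenotherm.e_prediction import (
    ConstantInputError,
    EPredictor,
    ModelSpec,
    OrderNorm,
    bootstrap_evaluate,
    evaluate_transfer,
    evaluation_metrics,
    mape,
    nested_model_chi2,
    r_squared,
    rmse,
)


class TestOrderNorm:
    def test_three_value_scores(self):
        on = OrderNorm().fit([10.0, 20.0, 30.0, 40.0, 50.0])
        # five values: scores Phi^-1((r - 0.5)/5)
        expected = stats.norm.ppf((np.arange(1, 6) - 0.5) / 5)
        np.testing.assert_allclose(on.transform([10, 20, 30, 40, 50]), expected, atol=1e-12)
        assert on.transform(30.0) == 0.0  # middle rank maps exactly to 0

    def test_scores_symmetric_with_zero_mean(self, rng):
        x = np.sort(rng.uniform(0, 10, 21))
        s = OrderNorm().fit(x).transform(x)
        assert abs(s.mean()) < 1e-12
        np.testing.assert_allclose(s, -s[::-1], atol=1e-12)

    def test_round_trip_on_training_points(self, rng):
        x = rng.uniform(0, 5, 40)
        on = OrderNorm().fit(x)
        np.testing.assert_allclose(on.inverse_transform(on.transform(x)), x, atol=1e-9)

    def test_extrapolation_is_linear_and_monotone(self, rng):
        x = rng.uniform(1, 2, 20)
        on = OrderNorm().fit(x)
        grid = np.linspace(0.0, 3.0, 50)
        s = on.transform(grid)
        assert np.all(np.diff(s) > 0)

    def test_constant_input_rejected(self):
        with pytest.raises(ConstantInputError):
            OrderNorm().fit(np.full(10, 3.0))


class TestMetrics:
    def test_perfect_prediction(self):
        assert mape([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_single_term_mape(self):
        assert mape([2.0], [1.0]) == 50.0

    def test_mape_direct_summation_oracle(self):
        assert mape([1.0, 2.0, 4.0], [2.0, 1.0, 5.0]) == pytest.approx(
            (100.0 + 50.0 + 25.0) / 3.0, abs=1e-12
        )

    def test_zero_actuals_excluded_with_warning(self):
        with pytest.warns(UserWarning):
            out = mape([0.0, 2.0], [1.0, 1.0])
        assert out == 50.0

    def test_metrics_match_brute_force(self, rng):
        a = rng.uniform(0.5, 5.0, 200)
        f = a + rng.normal(0, 0.3, 200)
        m = evaluation_metrics(a, f)
        assert m["rmse"] == pytest.approx(np.sqrt(np.mean((a - f) ** 2)), abs=1e-10)
        assert m["mape"] == pytest.approx(np.mean(np.abs((a - f) / a)) * 100, abs=1e-10)
        assert m["r2"] == pytest.approx(stats.pearsonr(a, f)[0] ** 2, abs=1e-10)
        sse = np.sum((a - f) ** 2)
        sst = np.sum((a - a.mean()) ** 2)
        assert m["r2_ss"] == pytest.approx(1 - sse / sst, abs=1e-10)

    def test_r2_nan_for_constant_actual(self):
        assert np.isnan(r_squared(np.ones(5), np.arange(5.0)))


def _linear_table(rng, n=60, noise=0.0):
    ctd = rng.uniform(-6, 0, n)
    e = 2.0 - 0.5 * ctd + rng.normal(0, noise, n)
    return pd.DataFrame({"CTD": ctd, "E": e, "genotype": "B104"})


class TestModels:
    def test_noiseless_linear_coefficients_recovered_exactly(self, rng):
        df = _linear_table(rng)
        spec = ModelSpec(
            "linear_index", ["CTD"], transform_predictors=False, transform_response=False
        )
        model = EPredictor(spec, seed=0).fit(df)
        assert model._estimator.coef_[0] == pytest.approx(-0.5, abs=1e-9)
        assert model._estimator.intercept_ == pytest.approx(2.0, abs=1e-9)

    def test_noiseless_linear_predictions_exact_under_ordernorm(self, rng):
        # a strictly monotone noiseless link survives the rank transform:
        # both variables map to mirrored normal scores, so training and
        # out-of-sample predictions invert exactly onto the true line
        df = _linear_table(rng)
        model = EPredictor(ModelSpec("linear_index", ["CTD"]), seed=0).fit(df)
        np.testing.assert_allclose(model.predict(df), df["E"], atol=1e-9)

    def test_unpenalised_fit_rejects_p_ge_n(self, rng):
        df = pd.DataFrame(rng.normal(size=(5, 6)), columns=[f"x{i}" for i in range(6)])
        df["E"] = rng.uniform(1, 2, 5)
        spec = ModelSpec("linear", [f"x{i}" for i in range(6)])
        with pytest.raises(ValueError, match="penal"):
            EPredictor(spec).fit(df)

    def test_lasso_keeps_signal_and_drops_noise(self):
        rng = np.random.default_rng(8)
        n = 50
        X = rng.normal(size=(n, 25))
        beta = np.zeros(25)
        beta[:5] = [2.0, -1.5, 1.0, 2.5, -2.0]
        y = X @ beta + rng.normal(0, 0.3, n)
        df = pd.DataFrame(X, columns=[f"x{i}" for i in range(25)])
        df["E"] = y - y.min() + 0.5
        spec = ModelSpec("lasso", list(df.columns[:-1]), transform_predictors=False)
        model = EPredictor(spec, seed=0).fit(df)
        kept = set(model.selected_variables)
        assert {f"x{i}" for i in range(5)} <= kept
        noise_kept = len(kept - {f"x{i}" for i in range(5)})
        assert noise_kept <= 4  # >= 80% of the 20 noise predictors dropped

    def test_rf_interpolates_step_function(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 1, 120)
        y = np.where(x > 0.5, 4.0, 1.0) + rng.normal(0, 0.01, 120)
        df = pd.DataFrame({"x": x, "E": y})
        model = EPredictor(ModelSpec("rf", ["x"]), seed=0).fit(df)
        assert r_squared(df["E"], model.predict(df)) > 0.95

    def test_stepwise_selects_true_predictors(self):
        rng = np.random.default_rng(10)
        n = 80
        df = pd.DataFrame(rng.normal(size=(n, 6)), columns=[f"x{i}" for i in range(6)])
        df["E"] = 3.0 + 2.0 * df["x0"] - 1.0 * df["x1"] + rng.normal(0, 0.1, n)
        model = EPredictor(
            ModelSpec("stepwise", [f"x{i}" for i in range(6)], transform_predictors=False)
        ).fit(df)
        assert {"x0", "x1"} <= set(model.selected_variables)

    def test_nested_chi2_detects_added_signal(self):
        rng = np.random.default_rng(11)
        n = 60
        df = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        df["E"] = 1.0 + df["a"] + 0.8 * df["b"] + rng.normal(0, 0.2, n)
        out = nested_model_chi2(df, ["a"], ["a", "b"])
        assert out["p"] < 1e-6
        null = nested_model_chi2(df.assign(c=rng.normal(size=n)), ["a", "b"], ["a", "b", "c"])
        assert null["p"] > 0.01


class TestBootstrap:
    def test_perfect_model_has_zero_error(self, rng):
        df = _linear_table(rng, n=40)
        spec = ModelSpec("linear_index", ["CTD"])
        ev = bootstrap_evaluate(spec, df, n_boot=10, seed=0)
        assert ev.medians["rmse"] == pytest.approx(0.0, abs=1e-6)
        assert ev.medians["mape"] == pytest.approx(0.0, abs=1e-4)
        assert ev.medians["r2"] == pytest.approx(1.0, abs=1e-6)

    def test_median_test_rmse_approaches_noise_floor(self):
        rng = np.random.default_rng(12)
        sigma = 0.3
        df = _linear_table(rng, n=400, noise=sigma)
        spec = ModelSpec("linear_index", ["CTD"], transform_predictors=False)
        ev = bootstrap_evaluate(spec, df, n_boot=30, seed=0)
        assert ev.medians["rmse"] == pytest.approx(sigma, rel=0.10)

    def test_seeded_determinism(self, rng):
        df = _linear_table(rng, n=50, noise=0.2)
        spec = ModelSpec("linear_index", ["CTD"])
        a = bootstrap_evaluate(spec, df, n_boot=8, seed=3)
        b = bootstrap_evaluate(spec, df, n_boot=8, seed=3)
        pd.testing.assert_frame_equal(a.per_boot, b.per_boot)

    def test_evaluation_invariant_to_transformed_scale(self):
        """Scaling the normal-score space must not change original-scale RMSE."""
        rng = np.random.default_rng(13)
        df = _linear_table(rng, n=60, noise=0.2)
        spec = ModelSpec("linear_index", ["CTD"], transform_predictors=False)
        model = EPredictor(spec, seed=0).fit(df)
        base = evaluation_metrics(df["E"], model.predict(df))
        scaled = EPredictor(spec, seed=0)
        scaled._y_transformer = OrderNorm(scale=3.0).fit(df["E"].to_numpy())
        y = scaled._y_transformer.transform(df["E"].to_numpy())
        from sklearn.linear_model import LinearRegression

        scaled._x_transformers = model._x_transformers
        scaled._estimator = LinearRegression().fit(df[["CTD"]].to_numpy(), y)
        out = evaluation_metrics(df["E"], scaled.predict(df))
        assert out["rmse"] == pytest.approx(base["rmse"], abs=1e-8)


class TestTransfer:
    def test_self_transfer_equals_training_metrics(self, rng):
        df = _linear_table(rng, n=50, noise=0.2)
        spec = ModelSpec("linear_index", ["CTD"])
        model = EPredictor(spec, seed=0).fit(df)
        transfer = evaluate_transfer(model, df)
        direct = evaluation_metrics(df["E"], model.predict(df))
        assert transfer["rmse"].iloc[0] == pytest.approx(direct["rmse"], abs=1e-12)

    def test_shifted_relationship_raises_transfer_error(self):
        rng = np.random.default_rng(14)
        a = _linear_table(rng, n=80, noise=0.1)
        b = a.copy()
        b["genotype"] = "H99"
        b["E"] = 4.0 - 0.9 * b["CTD"] + rng.normal(0, 0.1, len(b))  # shifted link
        model = EPredictor(ModelSpec("linear_index", ["CTD"]), seed=0).fit(a)
        transfer = evaluate_transfer(model, pd.concat([a, b])).set_index("genotype")
        assert transfer.loc["H99", "rmse"] > transfer.loc["B104", "rmse"]

    def test_constant_response_genotype_flagged(self, rng):
        a = _linear_table(rng, n=40, noise=0.1)
        b = pd.DataFrame({"CTD": rng.uniform(-6, 0, 10), "E": 2.0, "genotype": "CONST"})
        model = EPredictor(ModelSpec("linear_index", ["CTD"]), seed=0).fit(a)
        transfer = evaluate_transfer(model, pd.concat([a, b])).set_index("genotype")
        assert np.isnan(transfer.loc["CONST", "r2"])
        assert np.isfinite(transfer.loc["CONST", "rmse"])
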