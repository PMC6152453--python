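"""GEP_d linear models: predictor building, fit statistics, validation."""

import numpy as np
import pandas as pd
import pytest

from cropflux.regression import (
    GEPRegression,
    ModelSpec,
    build_predictor,
    fit_model,
    model_table,
    predict_and_validate,
)


def daily_frame(n=20, seed=0, crop="wheat"):
    rng = np.random.default_rng(seed)
    lai = np.linspace(0.5, 4.0, n)
    ndvi = 0.9 - 0.75 * np.exp(-0.9 * lai)
    par_d = rng.uniform(400, 900, n)
    gep_d = 4.9 * ndvi * lai + 0.6 + rng.normal(0, 0.8, n)
    return pd.DataFrame(
        {
            "date": pd.date_range("2012-04-01", periods=n, freq="5D"),
            "crop": crop,
            "gep_d": gep_d,
            "lai": lai,
            "ndvi": ndvi,
            "savi": ndvi * 0.5,
            "swdrvi": (ndvi + 1) / 2,
            "pri": -0.19 + 0.01 * lai,
            "par_d": par_d,
        }
    )


class TestModelSpec:
    def test_vi_required_for_models_2_to_4(self):
        with pytest.raises(ValueError):
            ModelSpec(2)
        assert ModelSpec(1).label == "LAI"
        assert ModelSpec(4, "NDVI").label == "NDVI*LAI"

    def test_bad_model_id(self):
        with pytest.raises(ValueError):
            ModelSpec(5, "NDVI")


class TestBuildPredictor:
    def test_each_formulation(self):
        df = pd.DataFrame(
            {"gep_d": [10.0], "lai": [3.0], "ndvi": [0.8], "par_d": [600.0]}
        )
        x1, _, _ = build_predictor(df, ModelSpec(1))
        x2, _, _ = build_predictor(df, ModelSpec(2, "NDVI"))
        x3, _, _ = build_predictor(df, ModelSpec(3, "NDVI"))
        x4, _, _ = build_predictor(df, ModelSpec(4, "NDVI"))
        assert x1.iloc[0] == 3.0
        assert x2.iloc[0] == 0.8
        assert x3.iloc[0] == pytest.approx(480.0)
        assert x4.iloc[0] == pytest.approx(2.4)

    def test_missing_components_dropped_and_counted(self):
        df = daily_frame(10)
        df.loc[3, "lai"] = np.nan
        df.loc[5, "gep_d"] = np.nan
        x, y, dropped = build_predictor(df, ModelSpec(4, "NDVI"))
        assert dropped == 2
        assert len(x) == len(y) == 8
        # the same rows survive for model 2 except the missing-LAI one
        x2, _, d2 = build_predictor(df, ModelSpec(2, "NDVI"))
        assert d2 == 1 and len(x2) == 9


class TestFitModel:
    def test_exact_line(self):
        x = np.linspace(0, 5, 10)
        fit = fit_model(x, 2.0 * x + 1.0)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.rmse == pytest.approx(0.0, abs=1e-10)

    def test_constant_response(self):
        fit = fit_model(np.linspace(0, 5, 10), np.full(10, 3.0))
        assert fit.r2 == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 4, 10)
        y = 3.0 * x + rng.normal(0, 1, 10)
        fit = fit_model(x, y)
        sxx = np.sum((x - x.mean()) ** 2)
        slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
        intercept = y.mean() - slope * x.mean()
        resid = y - slope * x - intercept
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-10)
        assert fit.rmse == pytest.approx(np.sqrt(np.mean(resid**2)), abs=1e-10)
        assert fit.r2 == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2, abs=1e-10)

    def test_nrmse_range_normalization_identity(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 4, 15)
        y = 2.0 * x + rng.normal(0, 0.5, 15)
        fit = fit_model(x, y)
        assert fit.rmse / fit.nrmse * 100.0 == pytest.approx(np.ptp(y), rel=1e-12)

    def test_order_invariance(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 4, 12)
        y = 2.0 * x + rng.normal(0, 0.5, 12)
        perm = rng.permutation(12)
        a, b = fit_model(x, y), fit_model(x[perm], y[perm])
        assert a.slope == pytest.approx(b.slope)
        assert a.rmse == pytest.approx(b.rmse)

    def test_degenerate_predictor(self):
        with pytest.raises(ValueError):
            fit_model(np.full(5, 1.0), np.arange(5.0))


class TestModelTable:
    def test_linear_truth_gives_unit_r2_row(self):
        df = daily_frame()
        df["gep_d"] = 5.0 * df["ndvi"] * df["lai"] + 1.0  # exact model 4
        table = model_table(df)
        row = table[(table.predictor == "NDVI*LAI") & (table.dataset == "wheat")]
        assert row["r2"].iloc[0] == pytest.approx(1.0)
        assert row["slope"].iloc[0] == pytest.approx(5.0)

    def test_groups_with_missing_lai_lack_lai_models(self):
        df = daily_frame()
        df["lai"] = np.nan
        table = model_table(df)
        assert not (table["predictor"].str.contains("LAI")).any()
        assert (table["predictor"] == "NDVI").any()

    def test_default_grouping_includes_pooled_set(self):
        df = pd.concat([daily_frame(crop="wheat"), daily_frame(seed=1, crop="rye")])
        table = model_table(df)
        assert {"wheat", "rye", "all crops"} <= set(table["dataset"])


class TestValidation:
    def test_perfect_predictions(self):
        df = daily_frame()
        df["gep_d"] = 5.0 * df["ndvi"] * df["lai"] + 1.0
        fit = GEPRegression.from_dataframe(df, ModelSpec(4, "NDVI")).fit()
        (val,) = predict_and_validate(fit, df)
        assert val.bias_percent == pytest.approx(0.0, abs=1e-9)
        assert val.slope == pytest.approx(1.0)
        assert not val.bias_exceeds_25

    def test_doubled_predictions_are_100_percent_bias(self):
        df = daily_frame()
        df["gep_d"] = 5.0 * df["ndvi"] * df["lai"] + 1.0
        fit = GEPRegression.from_dataframe(df, ModelSpec(4, "NDVI")).fit()
        doubled = fit
        doubled.slope *= 2.0
        doubled.intercept *= 2.0
        (val,) = predict_and_validate(doubled, df)
        assert val.bias_percent == pytest.approx(100.0, abs=1e-9)
        assert val.bias_exceeds_25

    def test_hysteresis_free_seasons_validate_within_25_percent(self):
        """Pooled NDVI*LAI model applied per crop stays within the 25% bias
        bound when no phase-dependent saturation is present."""
        from cropflux.synthetic import SeasonConfig, generate_season

        frames = []
        for i, (crop, lai_max) in enumerate(
            [("wheat", 3.3), ("barley", 4.0), ("potato", 3.4)]
        ):
            cfg = SeasonConfig.hysteresis_free(
                seed=20 + i, crop_label=crop, lai_max=lai_max,
                refl_noise_sd=0.01, weather_noise=0.2,
            )
            daily = generate_season(cfg).daily.iloc[::7]
            frames.append(daily.rename(columns={"crop": "crop"}))
        pooled = pd.concat(frames).reset_index(drop=True)
        fit = GEPRegression.from_dataframe(pooled, ModelSpec(4, "NDVI")).fit()
        results = predict_and_validate(fit, pooled)
        assert len(results) == 3
        assert all(abs(v.bias_percent) < 25 for v in results)

    def test_summary_mentions_fit_statistics(self):
        fit = fit_model(np.linspace(0, 5, 10), 2.0 * np.linspace(0, 5, 10) + 1)
        text = fit.summary()
        assert "R2" in text and "RMSE" in text and "n = 10" in text
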