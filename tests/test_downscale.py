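"""Split/fit/evaluate contracts and the mass-balance adjustment."""

import numpy as np
import pandas as pd
import pytest

from cropcarbon.downscale import (
    DownscaleError,
    adjust_to_provincial,
    evaluate,
    fit,
    predict_counties,
    r2_rmse,
    split_data,
)


def provincial_rows(rng, n=100, slope=3.0, noise=0.0):
    x = rng.uniform(0, 10, n)
    return pd.DataFrame(
        {"region_id": "P", "year": np.arange(n), "x1": x,
         "target": slope * x + noise * rng.normal(size=n)}
    )


class TestSplitData:
    def test_ten_percent_of_100_rows(self, rng):
        train, test = split_data(provincial_rows(rng), test_frac=0.10, seed=0)
        assert (len(train), len(test)) == (90, 10)

    def test_same_seed_same_partition(self, rng):
        rows = provincial_rows(rng)
        a = split_data(rows, seed=5)
        b = split_data(rows, seed=5)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_partition_is_disjoint_and_exhaustive(self, rng):
        rows = provincial_rows(rng, n=20)
        train, test = split_data(rows, test_frac=0.10, seed=1)
        assert (len(train), len(test)) == (18, 2)
        restored = sorted(train["year"].tolist() + test["year"].tolist())
        assert restored == rows["year"].tolist()

    def test_too_few_rows_is_hard_error(self, rng):
        with pytest.raises(DownscaleError, match="at least 10"):
            split_data(provincial_rows(rng, n=5))

    def test_bad_fraction_is_hard_error(self, rng):
        with pytest.raises(DownscaleError, match="test_frac"):
            split_data(provincial_rows(rng), test_frac=1.5)


class TestFit:
    def test_constant_target_predicts_constant(self, rng):
        rows = provincial_rows(rng).assign(target=7.0)
        model = fit(rows, ["x1"], n_trees=20, cv_folds=2)
        assert model.diagnostics["train_rmse"] == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(model.predict(rows), 7.0)

    def test_noiseless_signal_is_interpolated(self, rng):
        """y = 3*x on n=1000: the forest reproduces training targets."""
        rows = provincial_rows(rng, n=1000)
        model = fit(rows, ["x1"], n_trees=100, cv_folds=2)
        assert model.diagnostics["train_r2"] > 0.99

    def test_permuted_target_has_no_cv_skill(self):
        """Target shuffled against covariates: cross-validated R2 shows no
        skill (a null forest overfits noise, so its CV R2 is at or below 0)."""
        r2s = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            rows = provincial_rows(r, n=200, noise=0.0)
            rows["target"] = r.permutation(rows["target"].to_numpy())
            model = fit(rows, ["x1"], n_trees=50, seed=seed, cv_folds=5)
            r2s.append(model.diagnostics["cv_r2_mean"])
        assert np.mean(r2s) < 0.05
        assert all(r2 > -2.0 for r2 in r2s)

    def test_loo_mode_populates_diagnostics(self, rng):
        rows = provincial_rows(rng, n=30)
        model = fit(rows, ["x1"], n_trees=10, cv="loo")
        assert model.diagnostics["cv_folds"] == 30
        assert model.diagnostics["cv_rmse_mean"] >= 0

    def test_nan_rows_are_named_in_error(self, rng):
        rows = provincial_rows(rng, n=20)
        rows.loc[3, "x1"] = np.nan
        with pytest.raises(DownscaleError, match=r"NaN.*\[3\]"):
            fit(rows, ["x1"], n_trees=5)


class TestEvaluate:
    def test_perfect_fit(self, rng):
        rows = provincial_rows(rng, n=50)
        model = fit(rows, ["x1"], n_trees=50, cv_folds=2)
        r2, rmse = r2_rmse(rows["target"], rows["target"])
        assert (r2, rmse) == (1.0, 0.0)

    def test_mean_prediction_gives_zero_r2(self, rng):
        y = rng.normal(size=100)
        r2, _ = r2_rmse(y, np.full(100, y.mean()))
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_example(self):
        r2, rmse = r2_rmse([1.0, 2.0, 3.0], [1.0, 2.0, 4.0])
        assert rmse == pytest.approx(np.sqrt(1 / 3), rel=1e-12)
        assert r2 == pytest.approx(0.5, rel=1e-12)

    def test_zero_variance_target_flags_r2(self):
        r2, rmse = r2_rmse([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        assert np.isnan(r2)
        assert rmse == pytest.approx(np.sqrt(2 / 3), rel=1e-12)

    def test_evaluate_records_labelled_diagnostics(self, rng):
        rows = provincial_rows(rng, n=50)
        model = fit(rows, ["x1"], n_trees=20, cv_folds=2)
        r2, rmse = evaluate(model, rows, label="test")
        assert model.diagnostics["test_r2"] == r2
        assert model.diagnostics["test_rmse"] == rmse


def county_table(rng, model_rows, n=50):
    return pd.DataFrame(
        {
            "county_id": [f"C{i}" for i in range(n)],
            "province_id": "P",
            "year": 2000,
            "area_km2": rng.uniform(100, 1000, n),
            "x1": rng.uniform(model_rows["x1"].min(), model_rows["x1"].max(), n),
        }
    )


class TestPredictCounties:
    def test_predictions_bounded_by_training_targets(self, rng):
        rows = provincial_rows(rng, n=200, noise=1.0)
        model = fit(rows, ["x1"], n_trees=50, cv_folds=2)
        counties = county_table(rng, rows, n=1000)
        est = predict_counties(model, counties)
        assert est["raw_intensity"].min() >= rows["target"].min() - 1e-9
        assert est["raw_intensity"].max() <= rows["target"].max() + 1e-9

    def test_identical_rows_identical_predictions(self, rng):
        rows = provincial_rows(rng, n=50)
        model = fit(rows, ["x1"], n_trees=20, cv_folds=2)
        counties = county_table(rng, rows, n=10).assign(x1=5.0)
        est = predict_counties(model, counties)
        assert est["raw_intensity"].nunique() == 1

    def test_missing_province_is_hard_error(self, rng):
        rows = provincial_rows(rng, n=50)
        model = fit(rows, ["x1"], n_trees=10, cv_folds=2)
        counties = county_table(rng, rows, n=5).assign(province_id=np.nan)
        with pytest.raises(DownscaleError, match="province"):
            predict_counties(model, counties)


def estimates_frame(raw, areas, province="P", year=2000):
    return pd.DataFrame(
        {
            "county_id": [f"C{i}" for i in range(len(raw))],
            "province_id": province,
            "year": year,
            "area_km2": areas,
            "raw_intensity": raw,
        }
    )


def provincial_frame(total, province="P", year=2000):
    return pd.DataFrame(
        [{"region_id": province, "year": year, "total_co2e_t": total}]
    )


class TestAdjustToProvincial:
    def test_forced_arithmetic(self):
        est = estimates_frame([2.0, 3.0, 5.0], [10.0, 10.0, 10.0])
        out = adjust_to_provincial(est, provincial_frame(200.0))
        assert out["scaling_factor"].tolist() == [2.0, 2.0, 2.0]
        assert out["adjusted_intensity"].tolist() == [4.0, 6.0, 10.0]

    def test_matching_total_is_identity(self):
        est = estimates_frame([2.0, 3.0, 5.0], [10.0, 10.0, 10.0])
        out = adjust_to_provincial(est, provincial_frame(100.0))
        np.testing.assert_allclose(out["adjusted_intensity"], est["raw_intensity"])
        np.testing.assert_allclose(out["scaling_factor"], 1.0)

    def test_conservation_on_seeded_fixtures(self):
        """Adjusted county emissions reproduce provincial totals exactly."""
        for seed in range(100):
            r = np.random.default_rng(seed)
            est = estimates_frame(r.uniform(0.1, 10, 8), r.uniform(10, 100, 8))
            total = float(r.uniform(100, 5000))
            out = adjust_to_provincial(est, provincial_frame(total))
            got = float((out["adjusted_intensity"] * out["area_km2"]).sum())
            assert got == pytest.approx(total, rel=1e-9)

    def test_rank_preservation(self, rng):
        raw = rng.uniform(0, 10, 20)
        est = estimates_frame(raw, rng.uniform(10, 100, 20))
        out = adjust_to_provincial(est, provincial_frame(1234.5))
        assert (np.argsort(out["adjusted_intensity"])
                == np.argsort(est["raw_intensity"])).all()

    def test_zero_target_zeroes_everything(self):
        est = estimates_frame([1.0, 2.0], [10.0, 10.0])
        out = adjust_to_provincial(est, provincial_frame(0.0))
        assert out["scaling_factor"].tolist() == [0.0, 0.0]
        assert out["adjusted_intensity"].tolist() == [0.0, 0.0]

    def test_zero_raw_sum_with_nonzero_target_is_error(self):
        est = estimates_frame([0.0, 0.0], [10.0, 10.0])
        with pytest.raises(DownscaleError, match="zero raw emission sum"):
            adjust_to_provincial(est, provincial_frame(100.0))

    def test_missing_provincial_total_is_error(self):
        est = estimates_frame([1.0], [10.0])
        with pytest.raises(DownscaleError, match="no provincial total"):
            adjust_to_provincial(est, provincial_frame(1.0, year=1999))
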