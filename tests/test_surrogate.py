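"""Surrogate-pipeline tests: splitting, scaling, selection, metrics, tuning."""

import numpy as np
import pandas as pd
import pytest

from batchtea.scenarios import FEATURE_COLUMNS
from batchtea.surrogate import (MODEL_NAMES, SearchSpace, SplitPlan,
                                apply_scaler, cross_validate_models, evaluate,
                                fit_scaler, inverse_scaler, learning_curve,
                                make_model, normalized_target_report,
                                regression_metrics, select_features,
                                split_train_test, train_models, tune_best)


class TestSplit:
    def test_proportions(self, small_dataset):
        train, test = split_train_test(small_dataset, SplitPlan(seed=1))
        assert len(train) == 320 and len(test) == 80

    def test_partition_is_disjoint_and_exhaustive(self, small_dataset):
        train, test = split_train_test(small_dataset, SplitPlan(seed=1))
        union = set(train.index) | set(test.index)
        assert union == set(small_dataset.frame.index)
        assert not set(train.index) & set(test.index)

    def test_seed_reproducible(self, small_dataset):
        a, _ = split_train_test(small_dataset, SplitPlan(seed=4))
        b, _ = split_train_test(small_dataset, SplitPlan(seed=4))
        assert list(a.index) == list(b.index)

    def test_tiny_dataset_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            split_train_test(small_dataset.frame.head(5), SplitPlan())


class TestScaler:
    def test_endpoints_map_to_unit_interval(self):
        df = pd.DataFrame({"a": [2.0, 4.0, 6.0], "b": [-1.0, 0.0, 3.0]})
        scaler = fit_scaler(df)
        scaled = apply_scaler(scaler, df)
        assert scaled.min().min() == 0.0 and scaled.max().max() == 1.0

    def test_round_trip(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        scaler = fit_scaler(df)
        back = inverse_scaler(scaler, apply_scaler(scaler, df))
        np.testing.assert_allclose(back.to_numpy(), df.to_numpy(), atol=1e-12)

    def test_constant_feature_passes_through_as_zero(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [0.0, 1.0, 2.0]})
        with pytest.warns(RuntimeWarning, match="constant"):
            scaler = fit_scaler(df)
        assert (apply_scaler(scaler, df)["a"] == 0.0).all()

    def test_out_of_range_data_not_clipped(self):
        train = pd.DataFrame({"a": [0.0, 10.0]})
        scaler = fit_scaler(train)
        out = apply_scaler(scaler, pd.DataFrame({"a": [-5.0, 15.0]}))
        assert out["a"].iloc[0] < 0.0 and out["a"].iloc[1] > 1.0

    def test_no_leakage_scaler_differs_when_fitted_on_more_rows(self, small_dataset):
        # fitting on the fold-train subset vs the whole fold must change the
        # parameters, i.e. the fold-validation rows carry information
        frame = small_dataset.frame[list(FEATURE_COLUMNS)]
        fold_train = frame.iloc[:300]
        scaler_fold = fit_scaler(fold_train)
        scaler_full = fit_scaler(frame)
        assert not np.allclose(scaler_fold.x_min, scaler_full.x_min) or \
            not np.allclose(scaler_fold.x_max, scaler_full.x_max)


class TestFeatureSelection:
    def test_planted_support_recovery(self):
        rng = np.random.default_rng(11)
        n, d = 400, 20
        x = rng.uniform(size=(n, d))
        y1 = 3.0 * x[:, 0] + 2.0 * x[:, 1] - 1.5 * x[:, 2] + rng.normal(0, 0.02, n)
        y2 = 1.0 * x[:, 0] - 2.0 * x[:, 1] + 2.5 * x[:, 2] + rng.normal(0, 0.02, n)
        cols = [f"f{i}" for i in range(d)]
        frame = pd.DataFrame(x, columns=cols)
        frame["upc"], frame["mpsp"] = y1, y2
        result = select_features(frame, seed=0, feature_columns=tuple(cols))
        assert set(result.selected) == {"f0", "f1", "f2"}

    def test_full_shrinkage_empties_the_selection(self, small_dataset):
        result = select_features(small_dataset.frame, alpha=1e6)
        assert result.selected == ()
        assert all(v == 0.0 for v in result.coefficients.values())

    def test_nonselected_coefficients_are_exactly_zero(self, small_dataset):
        result = select_features(small_dataset.frame, seed=1)
        for name, mag in result.coefficients.items():
            if name not in result.selected:
                assert mag == 0.0

    def test_constant_target_rejected(self, small_dataset):
        frame = small_dataset.frame.copy()
        frame["mpsp"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            select_features(frame)


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        m = regression_metrics(y, y)
        assert m["r2"] == 1.0 and m["rmse"] == 0.0 and m["mape"] == 0.0

    def test_mean_prediction_gives_zero_r2(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        m = regression_metrics(y, np.full_like(y, y.mean()))
        assert m["r2"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_example(self):
        y = np.array([100.0, 200.0, 300.0])
        pred = np.array([110.0, 190.0, 310.0])
        m = regression_metrics(y, pred)
        assert m["rmse"] == pytest.approx(10.0)
        # (10/100 + 10/200 + 10/300)/3 x 100
        assert m["mape"] == pytest.approx(6.1111, abs=1e-3)

    def test_zero_targets_excluded_from_mape(self):
        y = np.array([0.0, 100.0])
        m = regression_metrics(y, np.array([5.0, 110.0]))
        assert m["mape"] == pytest.approx(10.0)
        assert m["mape_excluded"] == 1


class TestModels:
    def test_all_six_predict_finite_values(self, small_dataset):
        train, test = split_train_test(small_dataset, SplitPlan(seed=2))
        feats = ("labor_rate", "quinaldine_cost", "irr", "annual_operation_time")
        models = train_models(train, feats, seed=2)
        assert set(models) == set(MODEL_NAMES)
        report = evaluate(models, test, feats)
        for name in MODEL_NAMES:
            for target in ("upc", "mpsp"):
                assert np.isfinite(list(report.per_target[name][target].values())[:3]).all()

    def test_linear_model_is_exact_on_linear_targets(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(size=(200, 3))
        frame = pd.DataFrame(x, columns=["a", "b", "c"])
        frame["upc"] = 2 * x[:, 0] - x[:, 1] + 5
        frame["mpsp"] = x[:, 2] + 1
        models = {"linear_regression": make_model("linear_regression")}
        models["linear_regression"].fit(frame[["a", "b", "c"]], frame[["upc", "mpsp"]])
        report = evaluate(models, frame, ("a", "b", "c"))
        assert report.per_target["linear_regression"]["upc"]["r2"] > 1 - 1e-9

    def test_too_few_features_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            train_models(small_dataset.frame, ("labor_rate",))

    def test_upc_predicted_more_accurately_than_mpsp(self, small_dataset):
        # the production cost is a near-direct function of the inputs while
        # the selling price is solved iteratively through the DCF, so every
        # model's relative error is smaller for UPC than for MPSP
        train, _ = split_train_test(small_dataset, SplitPlan(seed=2))
        feats = ("labor_rate", "quinaldine_cost", "isopropanol_cost",
                 "process_water_cost", "nitrogen_cost",
                 "annual_operation_time", "income_tax", "loan_period", "irr")
        report = cross_validate_models(train, feats, seed=2, folds=3)
        for name in MODEL_NAMES:
            assert (report.per_target[name]["upc"]["mape"]
                    <= report.per_target[name]["mpsp"]["mape"])


class TestNormalizedReport:
    def test_normalized_rmse_below_std_for_a_good_model(self, small_dataset):
        train, test = split_train_test(small_dataset, SplitPlan(seed=5))
        feats = ("labor_rate", "quinaldine_cost", "isopropanol_cost",
                 "annual_operation_time", "income_tax", "irr")
        model = make_model("xgboost", seed=5)
        model.fit(train[list(feats)], train[["upc", "mpsp"]])
        report = normalized_target_report(model, train, test, feats)
        assert (report["rmse_normalized"] < report["std_normalized"]).all()
        assert (report["rmse_normalized"] >= 0).all()


@pytest.fixture(scope="module")
def tuned(small_dataset):
    train, _ = split_train_test(small_dataset, SplitPlan(seed=6))
    feats = ("labor_rate", "quinaldine_cost", "isopropanol_cost",
             "annual_operation_time", "income_tax", "irr")
    space = SearchSpace(iterations=5, folds=3)
    best, table = tune_best(train, feats, space, seed=6)
    return train, feats, space, best, table


class TestTuning:
    def test_sampled_configurations_stay_inside_printed_bounds(self, tuned):
        _, _, space, _, table = tuned
        assert table["n_estimators"].between(*space.n_estimators).all()
        assert table["max_depth"].between(*space.max_depth).all()
        assert table["learning_rate"].between(*space.learning_rate).all()
        assert table["subsample"].between(*space.subsample).all()
        assert table["colsample_bytree"].between(*space.colsample_bytree).all()

    def test_search_is_deterministic_for_fixed_seed(self, tuned):
        train, feats, space, best, table = tuned
        best2, table2 = tune_best(train, feats, space, seed=6)
        pd.testing.assert_frame_equal(table, table2)

    def test_search_reports_cv_scores(self, tuned):
        _, _, space, _, table = tuned
        assert len(table) == space.iterations
        assert table["cv_r2"].is_monotonic_decreasing


class TestLearningCurve:
    def test_curve_shape_and_optimism(self, small_dataset):
        train, _ = split_train_test(small_dataset, SplitPlan(seed=8))
        feats = ("labor_rate", "quinaldine_cost", "annual_operation_time", "irr")
        model = make_model("xgboost", seed=8)
        curve = learning_curve(model, train, feats, sizes=[0.2, 0.5, 1.0],
                               seed=8, folds=3)
        assert len(curve) == 3
        # training score exceeds validation within one fold-std at every size
        assert (curve["train_r2"] + curve["train_r2_std"] + curve["validation_r2_std"]
                >= curve["validation_r2"]).all()
        # validation improves with data (monotone trend)
        from batchtea.uncertainty import spearman
        assert spearman(curve["n_train"], curve["validation_r2"]) > 0

    def test_too_few_sizes_rejected(self, small_dataset):
        train, _ = split_train_test(small_dataset, SplitPlan(seed=8))
        with pytest.raises(ValueError):
            learning_curve(make_model("knn"), train, ("labor_rate", "irr"),
                           sizes=[0.5, 1.0])
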