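"""Classifier harness: splits, cross-validation, reports, persistence."""

import numpy as np
import pandas as pd
import pytest

from vitalfield.classify import (
    ModelSpec,
    benchmark_all,
    cross_validate,
    load_model,
    split_stratified,
    train_and_evaluate,
)
from vitalfield.cohort import ValidationError
from vitalfield.features import FEATURE_COLUMNS, time_shift_augment


def synthetic_table(n=100, n_abnormal=30, seed=0):
    """A minimal random feature table with a prescribed class balance."""
    rng = np.random.default_rng(seed)
    table = pd.DataFrame(rng.normal(size=(n, len(FEATURE_COLUMNS))), columns=FEATURE_COLUMNS)
    table.insert(0, "t", np.arange(n))
    table.insert(0, "subject_id", "X0")
    state = np.array(["abnormal"] * n_abnormal + ["normal"] * (n - n_abnormal))
    rng.shuffle(state)
    table["state"] = state
    table["augmented"] = False
    return table


class TestSplitStratified:
    def test_exact_stratified_arithmetic(self):
        table = synthetic_table(100, 30)
        train, test = split_stratified(table, test_fraction=0.2, seed=1)
        assert len(test) == 20
        assert int((test.state == "abnormal").sum()) == 6
        assert len(train) == 80

    def test_degenerate_two_row_split(self):
        table = synthetic_table(2, 1)
        train, test = split_stratified(table, test_fraction=0.5, seed=1)
        assert len(train) == len(test) == 1
        assert set(train.state) != set(test.state) or len(set(table.state)) == 2

    def test_same_seed_gives_identical_split(self):
        table = synthetic_table(200, 60)
        _, t1 = split_stratified(table, 0.2, seed=3)
        _, t2 = split_stratified(table, 0.2, seed=3)
        assert list(t1.index) == list(t2.index)

    def test_single_class_is_rejected(self):
        table = synthetic_table(50, 0)
        with pytest.raises(ValidationError, match="single class"):
            split_stratified(table, 0.2, seed=1)

    def test_augmented_rows_never_reach_the_test_side(self, small_table):
        aug = time_shift_augment(small_table, [1])
        combined = pd.concat([small_table, aug], ignore_index=True)
        train, test = split_stratified(combined, 0.2, seed=5)
        assert not test["augmented"].any()
        assert int(train["augmented"].sum()) == len(aug)


class TestCrossValidate:
    def test_fold_count_and_sizes(self):
        table = synthetic_table(203, 61, seed=2)
        folds = cross_validate(table, ModelSpec("logistic_regression", seed=1), k=5)
        assert len(folds) == 5
        sizes = [f["n"] for f in folds]
        assert max(sizes) - min(sizes) <= 1

    def test_separable_toy_table_is_learned_perfectly(self):
        rng = np.random.default_rng(7)
        table = synthetic_table(40, 20, seed=7)
        hr = np.where(table.state == "abnormal", 130.0, 80.0) + rng.normal(0, 1, 40)
        table["HR_noisy"] = hr  # label = (HR_noisy > 100), linearly separable
        folds = cross_validate(table, ModelSpec("random_forest", {"n_estimators": 30}, seed=7), k=5)
        assert all(f["accuracy"] == 1.0 for f in folds)

    def test_k_beyond_minority_count_is_rejected(self):
        table = synthetic_table(30, 3)
        with pytest.raises(ValidationError, match="minority"):
            cross_validate(table, ModelSpec("logistic_regression"), k=10)


class TestTrainAndEvaluate:
    def test_unknown_model_name_lists_valid_names(self):
        with pytest.raises(ValidationError, match="logistic_regression"):
            ModelSpec("svm")

    def test_report_confusion_consistency(self, small_table):
        report = train_and_evaluate(
            small_table, ModelSpec("gradient_boosting", {"n_estimators": 40}, seed=3), seed=3
        )
        assert report.confusion.sum() == report.n_test
        acc_from_cm = np.trace(report.confusion) / report.confusion.sum()
        assert acc_from_cm == pytest.approx(report.accuracy, abs=1e-12)
        assert 0.0 <= report.f1 <= 1.0

    def test_fixed_seed_reports_are_identical(self, small_table):
        spec = ModelSpec("random_forest", {"n_estimators": 40}, seed=11)
        r1 = train_and_evaluate(small_table, spec, seed=11)
        r2 = train_and_evaluate(small_table, spec, seed=11)
        assert r1.accuracy == r2.accuracy
        np.testing.assert_array_equal(r1.confusion, r2.confusion)

    def test_cv_metrics_track_heldout_metric(self, small_table):
        report = train_and_evaluate(
            small_table,
            ModelSpec("gradient_boosting", {"n_estimators": 60}, seed=5),
            seed=5,
            run_cv=True,
        )
        cv_mean = np.mean([f["accuracy"] for f in report.per_fold_metrics])
        assert abs(cv_mean - report.accuracy) < 0.05

    def test_majority_baseline_accuracy_is_the_majority_rate(self):
        table = synthetic_table(200, 60, seed=9)

        class Majority:
            def fit(self, X, y):
                self.c = int(np.bincount(y).argmax())
                return self

            def predict(self, X):
                return np.full(len(X), self.c)

        train, test = split_stratified(table, 0.3, seed=9)
        model = Majority().fit(*_xy(train))
        X, y = _xy(test)
        assert (model.predict(X) == y).mean() == pytest.approx(0.7, abs=0.02)


def _xy(table):
    return table[FEATURE_COLUMNS], np.where(table.state == "abnormal", 1, 0)


FAST_SPECS = [
    ModelSpec("logistic_regression", seed=21),
    ModelSpec("knn", {"n_neighbors": 7}, seed=21),
    ModelSpec("random_forest", {"n_estimators": 60}, seed=21),
    ModelSpec("gradient_boosting", {"n_estimators": 60}, seed=21),
    ModelSpec("xgboost", {"n_estimators": 60}, seed=21),
    ModelSpec("mlp", {"max_iter": 300}, seed=21),
]


@pytest.fixture(scope="module")
def results(small_table):
    return benchmark_all(small_table, specs=FAST_SPECS, seed=21)


class TestBenchmark:

    def test_six_reports_with_metrics_and_confusions(self, results):
        reports, comparison = results
        ok = [r for r in reports if r.error is None]
        assert len(ok) == 6
        for r in ok:
            assert r.confusion.shape == (2, 2)
            assert 0.0 <= r.accuracy <= 1.0

    def test_comparison_table_header_is_exact(self, results):
        _, comparison = results
        assert list(comparison.columns) == ["Models", "Accuracy", "Precision", "Recall", "f1-Score"]
        assert len(comparison) == 6

    def test_tree_ensembles_beat_the_linear_baseline(self, results):
        reports, _ = results
        by_name = {r.model: r for r in reports if r.error is None}
        for name in ("random_forest", "gradient_boosting", "xgboost"):
            assert by_name[name].accuracy >= by_name["logistic_regression"].accuracy


class TestPersistence:
    def test_round_trip_and_manifest(self, small_table, tmp_path):
        path = tmp_path / "m.joblib"
        spec = ModelSpec("random_forest", {"n_estimators": 20}, seed=2)
        train_and_evaluate(small_table, spec, seed=2, model_path=str(path))
        model, manifest = load_model(str(path), expected_features=FEATURE_COLUMNS)
        assert manifest["model_name"] == "random_forest"
        assert manifest["feature_names"] == list(FEATURE_COLUMNS)
        pred = model.predict(small_table[FEATURE_COLUMNS].head(5))
        assert set(pred) <= {0, 1}

    def test_feature_manifest_mismatch_is_refused(self, small_table, tmp_path):
        path = tmp_path / "m.joblib"
        spec = ModelSpec("random_forest", {"n_estimators": 10}, seed=2)
        train_and_evaluate(small_table, spec, seed=2, model_path=str(path))
        with pytest.raises(ValidationError, match="manifest"):
            load_model(str(path), expected_features=["HR_noisy", "bogus"])
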