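"""Split arithmetic, confusion/sensitivity/MCC metrics and their brute-force oracles."""

import math

import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef

from isomir_gaselect import (
    FeatureSet,
    SplitSpec,
    average_mcc,
    confusion_and_sensitivity,
    confusion_summary,
    stratified_split,
    train_predict,
)
from isomir_gaselect.evaluate import RunResult


class TestStratifiedSplit:
    @pytest.mark.parametrize(
        "n,expected_train", [(4, 3), (35, 26), (2, 1), (100, 75), (7, 5)]
    )
    def test_per_class_floor_arithmetic(self, n, expected_train):
        labels = ["A"] * n + ["B"] * 8
        train, test = stratified_split(labels, SplitSpec(seed=0))
        n_train_a = int(np.sum(np.asarray(labels)[train] == "A"))
        assert n_train_a == expected_train

    def test_partitions_all_indices(self, rng):
        sizes = {"ACC": 79, "CHOL": 35, "DLBC": 46, "READ": 144, "UVM": 80}
        labels = [c for c, n in sizes.items() for _ in range(n)]
        train, test = stratified_split(labels, SplitSpec(seed=4))
        assert len(train) + len(test) == len(labels)
        assert set(train.tolist()) | set(test.tolist()) == set(range(len(labels)))
        assert set(train.tolist()) & set(test.tolist()) == set()
        # Re-summed per-class counts match the manifest totals.
        arr = np.asarray(labels)
        for cls, n in sizes.items():
            n_train = int(np.sum(arr[train] == cls))
            n_test = int(np.sum(arr[test] == cls))
            assert n_train == math.floor(0.75 * n)
            assert n_train + n_test == n

    def test_every_class_keeps_a_test_sample(self):
        labels = ["A"] * 2 + ["B"] * 3
        train, test = stratified_split(labels, SplitSpec(seed=1))
        arr = np.asarray(labels)
        assert set(arr[test]) == {"A", "B"}

    def test_singleton_class_is_fatal(self):
        with pytest.raises(ValueError, match="lonely"):
            stratified_split(["lonely"] + ["B"] * 5, SplitSpec(seed=0))

    def test_deterministic_under_seed(self):
        labels = ["A"] * 20 + ["B"] * 30
        a = stratified_split(labels, SplitSpec(seed=9))
        b = stratified_split(labels, SplitSpec(seed=9))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestTrainPredict:
    def test_separable_training_rows_predicted_perfectly(self, rng):
        y = np.repeat(["A", "B", "C"], 10)
        X = rng.normal(size=(30, 6))
        for i, cls in enumerate(("A", "B", "C")):
            X[y == cls, i] += 6
        X = np.abs(X)
        fs = FeatureSet(frozenset(range(6)))
        predicted = train_predict(X, y, X, fs, n_trees=100, seed=0)
        assert np.array_equal(predicted, y)

    def test_single_class_training_predicts_that_class(self, rng):
        X = np.abs(rng.normal(size=(5, 3)))
        predicted = train_predict(X, ["only"] * 5, X, FeatureSet(frozenset({0, 1})), n_trees=10)
        assert set(predicted) == {"only"}

    @pytest.mark.parametrize("kind", ["rf", "svm_linear"])
    def test_deterministic_under_seed(self, rng, kind):
        y = np.repeat(["A", "B"], 10)
        X = np.abs(rng.normal(size=(20, 4)) + (y == "B")[:, None])
        fs = FeatureSet(frozenset(range(4)))
        a = train_predict(X, y, X, fs, classifier_kind=kind, seed=3, n_trees=30)
        b = train_predict(X, y, X, fs, classifier_kind=kind, seed=3, n_trees=30)
        assert np.array_equal(a, b)

    def test_unknown_classifier_rejected(self, rng):
        X = np.abs(rng.normal(size=(4, 2)))
        with pytest.raises(ValueError, match="classifier_kind"):
            train_predict(X, ["A", "A", "B", "B"], X, FeatureSet(frozenset({0})), classifier_kind="knn")


class TestConfusionAndSensitivity:
    def test_perfect_prediction(self):
        actual = ["A", "B", "C", "A"]
        confusion, per_class, avg = confusion_and_sensitivity(actual, actual, ["A", "B", "C"])
        assert np.array_equal(confusion, np.diag([2, 1, 1]))
        assert per_class == {"A": 1.0, "B": 1.0, "C": 1.0}
        assert avg == 1.0

    def test_forced_arithmetic_two_classes(self):
        actual = ["A"] * 4 + ["B"] * 4
        predicted = ["A", "A", "A", "B"] + ["B"] * 4
        confusion, per_class, avg = confusion_and_sensitivity(actual, predicted, ["A", "B"])
        assert np.array_equal(confusion, [[3, 1], [0, 4]])
        assert per_class == {"A": 0.75, "B": 1.0}
        assert avg == 0.875

    def test_row_sums_equal_class_counts(self, rng):
        classes = ["A", "B", "C", "D"]
        actual = rng.choice(classes, size=200)
        predicted = rng.choice(classes, size=200)
        confusion, _, _ = confusion_and_sensitivity(actual, predicted, classes)
        for i, cls in enumerate(classes):
            assert confusion[i].sum() == int(np.sum(actual == cls))
        assert confusion.sum() == 200

    def test_random_labels_average_near_chance(self, rng):
        """Monte Carlo: macro sensitivity of random predictions ~ 1/k."""
        k, trials, total = 4, 1000, 0.0
        classes = [f"c{i}" for i in range(k)]
        for _ in range(trials):
            actual = rng.choice(classes, size=40)
            predicted = rng.choice(classes, size=40)
            _, _, avg = confusion_and_sensitivity(actual, predicted, classes)
            total += avg
        # SE ~ 0.0025; generous 8 SE band.
        assert total / trials == pytest.approx(1 / k, abs=0.02)

    def test_matches_brute_force_on_random_fixture(self, rng):
        classes = ["A", "B", "C"]
        actual = rng.choice(classes, size=120)
        predicted = rng.choice(classes, size=120)
        confusion, per_class, avg = confusion_and_sensitivity(actual, predicted, classes)
        sens = []
        for cls in classes:
            mask = actual == cls
            expected = float(np.mean(predicted[mask] == cls))
            assert per_class[cls] == pytest.approx(expected, abs=1e-12)
            sens.append(expected)
        assert avg == pytest.approx(float(np.mean(sens)), abs=1e-12)


class TestAverageMcc:
    def test_perfect_prediction_is_one(self):
        labels = ["A", "B", "A", "B", "C", "C"]
        assert average_mcc(labels, labels, ["A", "B", "C"]) == 1.0

    def test_constant_prediction_zero_by_convention(self):
        actual = ["A", "A", "B", "B"]
        predicted = ["A"] * 4
        assert average_mcc(actual, predicted, ["A", "B"]) == 0.0

    def test_matches_brute_force_and_sklearn_binary_mcc(self, rng):
        classes = ["A", "B", "C", "D"]
        actual = rng.choice(classes, size=150)
        predicted = rng.choice(classes, size=150)
        got = average_mcc(actual, predicted, classes)
        expected = []
        for cls in classes:
            tp = int(np.sum((actual == cls) & (predicted == cls)))
            fp = int(np.sum((actual != cls) & (predicted == cls)))
            fn = int(np.sum((actual == cls) & (predicted != cls)))
            tn = int(np.sum((actual != cls) & (predicted != cls)))
            denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
            value = 0.0 if denom == 0 else (tp * tn - fp * fn) / denom
            assert value == pytest.approx(
                matthews_corrcoef(actual == cls, predicted == cls), abs=1e-12
            )
            expected.append(value)
        assert got == pytest.approx(float(np.mean(expected)), abs=1e-12)

    def test_bounds(self, rng):
        classes = ["A", "B"]
        for _ in range(50):
            actual = rng.choice(classes, size=20)
            predicted = rng.choice(classes, size=20)
            assert -1.0 <= average_mcc(actual, predicted, classes) <= 1.0


def _result(confusion, order):
    confusion = np.asarray(confusion)
    return RunResult(
        selected=FeatureSet(frozenset({0})),
        class_order=order,
        confusion=confusion,
        per_class_sensitivity={},
        avg_sensitivity=0.0,
        avg_mcc=0.0,
        classifier_kind="rf",
        seed=0,
    )


class TestConfusionSummary:
    def test_single_perfect_run_gives_identity(self):
        summary = confusion_summary([_result(np.diag([3, 2]), ["A", "B"])])
        np.testing.assert_allclose(summary.values, np.eye(2))

    def test_two_runs_average_cellwise(self):
        r1 = _result([[2, 2], [0, 4]], ["A", "B"])
        r2 = _result([[4, 0], [2, 2]], ["A", "B"])
        summary = confusion_summary([r1, r2])
        np.testing.assert_allclose(summary.values, [[0.75, 0.25], [0.25, 0.75]])

    def test_rows_sum_to_one_on_random_fixtures(self, rng):
        order = ["A", "B", "C"]
        results = []
        for _ in range(10):
            confusion = rng.integers(1, 20, size=(3, 3))
            results.append(_result(confusion, order))
        summary = confusion_summary(results)
        np.testing.assert_allclose(summary.values.sum(axis=1), np.ones(3), atol=1e-12)
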