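"""Final-classifier training and multiclass evaluation.

Each run splits samples stratified by tumor type (75% train / 25% test by
default), trains the final classifier (random forest, or a linear-kernel SVM
for comparison) on the selected feature subset, and reports the confusion
matrix, per-class sensitivity (recall), the unweighted macro-average
sensitivity, and the average one-vs-rest Matthews correlation coefficient.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from .ga import FeatureSet

__all__ = [
    "SplitSpec",
    "RunResult",
    "stratified_split",
    "train_predict",
    "confusion_and_sensitivity",
    "average_mcc",
    "confusion_summary",
]


@dataclass(frozen=True)
class SplitSpec:
    """Stratified train/test split: per class, floor(train_fraction * n) train rows."""

    train_fraction: float = 0.75
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class RunResult:
    """One train/test run: selected features, confusion counts and metrics."""

    selected: FeatureSet
    class_order: list[str]
    confusion: np.ndarray  # rows = actual, columns = predicted
    per_class_sensitivity: dict[str, float]
    avg_sensitivity: float
    avg_mcc: float
    classifier_kind: str
    seed: int


def stratified_split(
    labels: Sequence[str],
    spec: SplitSpec,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class 75/25 (by default) split of row indices.

    Each class contributes floor(train_fraction * n) training rows; the floor
    guarantees at least one test row per class, and one training row is
    enforced for classes of size >= 2.  A single-sample class cannot be split
    and is a fatal error.
    """
    labels = np.asarray(labels)
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 2:
            raise ValueError(f"class {cls!r} has {len(idx)} sample(s); need >= 2 to split")
        n_train = math.floor(spec.train_fraction * len(idx))
        n_train = min(max(n_train, 1), len(idx) - 1)
        perm = rng.permutation(idx) if spec.stratified else idx
        train_idx.extend(perm[:n_train].tolist())
        test_idx.extend(perm[n_train:].tolist())
    return np.sort(np.array(train_idx)), np.sort(np.array(test_idx))


def train_predict(
    X_train: np.ndarray,
    y_train: Sequence[str],
    X_test: np.ndarray,
    fs: FeatureSet,
    classifier_kind: str = "rf",
    seed: int = 0,
    n_trees: int = 500,
) -> np.ndarray:
    """Fit the final classifier on the selected columns and predict the test rows.

    ``rf``: random forest with ``n_trees`` trees and the square-root feature
    subsampling rule.  ``svm_linear``: linear-kernel SVC (one-vs-one).
    """
    cols = fs.columns()
    y_train = np.asarray(y_train)
    if classifier_kind == "rf":
        clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    elif classifier_kind == "svm_linear":
        clf = SVC(kernel="linear", random_state=seed)
    else:
        raise ValueError(f"unknown classifier_kind {classifier_kind!r}")
    clf.fit(X_train[:, cols], y_train)
    return np.asarray(clf.predict(X_test[:, cols]))


def confusion_and_sensitivity(
    actual: Sequence[str],
    predicted: Sequence[str],
    class_order: Sequence[str],
) -> tuple[np.ndarray, dict[str, float], float]:
    """Confusion counts plus per-class and macro-averaged sensitivity.

    Row sums equal per-class test counts; sensitivity of class c is
    confusion[c, c] / row-sum(c); the average is the unweighted mean over
    classes present in the test set.  A predicted label outside
    ``class_order`` (possible when a class is absent from training) counts as
    a misclassification and is tallied in an extra column-less sense: it
    simply never lands on the diagonal.
    """
    actual = np.asarray(actual)
    predicted = np.asarray(predicted)
    if actual.shape != predicted.shape:
        raise ValueError("actual and predicted must have equal length")
    order = list(class_order)
    index = {c: i for i, c in enumerate(order)}
    confusion = np.zeros((len(order), len(order)), dtype=int)
    for a, p in zip(actual.tolist(), predicted.tolist()):
        if p not in index:
            warnings.warn(f"predicted label {p!r} outside class order", stacklevel=2)
            continue
        confusion[index[a], index[p]] += 1
    row_sums = np.bincount([index[a] for a in actual.tolist()], minlength=len(order))
    per_class: dict[str, float] = {}
    for c, i in index.items():
        if row_sums[i] > 0:
            per_class[c] = confusion[i, i] / row_sums[i]
    avg = float(np.mean(list(per_class.values()))) if per_class else 0.0
    return confusion, per_class, avg


def _binary_mcc(tp: int, fp: int, fn: int, tn: int) -> float:
    """MCC from a 2x2 table; 0 when any denominator factor is 0."""
    denom = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / denom


def average_mcc(
    actual: Sequence[str],
    predicted: Sequence[str],
    class_order: Sequence[str],
) -> float:
    """Mean one-vs-rest Matthews correlation coefficient across classes.

    Each class's 2x2 collapse of the confusion matrix yields a binary MCC
    (0 substituted when a denominator term vanishes); the unweighted mean
    across classes is returned.
    """
    actual = np.asarray(actual)
    predicted = np.asarray(predicted)
    values = []
    for cls in class_order:
        a = actual == cls
        p = predicted == cls
        tp = int(np.sum(a & p))
        fp = int(np.sum(~a & p))
        fn = int(np.sum(a & ~p))
        tn = int(np.sum(~a & ~p))
        values.append(_binary_mcc(tp, fp, fn, tn))
    return float(np.mean(values))


def confusion_summary(results: Sequence[RunResult]) -> pd.DataFrame:
    """Average row-normalized confusion matrix over runs.

    Cell (actual a, predicted p) is the mean over runs of
    confusion[a, p] / row-sum(a), skipping runs where class a had no test
    samples; each row of the summary sums to 1 over the runs that scored it.
    """
    if not results:
        raise ValueError("no results")
    order = results[0].class_order
    if any(r.class_order != order for r in results):
        raise ValueError("results do not share a class order")
    k = len(order)
    total = np.zeros((k, k))
    counts = np.zeros(k)
    for r in results:
        row_sums = r.confusion.sum(axis=1)
        scored = row_sums > 0
        normalized = np.zeros_like(total)
        normalized[scored] = r.confusion[scored] / row_sums[scored, None]
        total[scored] += normalized[scored]
        counts += scored
    with np.errstate(invalid="ignore"):
        mean = total / counts[:, None]
    return pd.DataFrame(mean, index=order, columns=order)
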