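"""Repeated GA/RF runs, selection-frequency importance, and reduced-set experiments.

The full experiment repeats the split -> GA search -> test evaluation cycle
``n_runs`` times with independent stratified splits.  A locus's importance is
how often it appears among the runs' optimal feature sets.  Under the null
that each run's set is a uniform random k-subset of the p candidates, a
given locus is selected per run with probability k/p, so its frequency is
Binomial(n_runs, k/p); the upper-tail probability, Bonferroni-multiplied by
the number of candidates, gives the adjusted p-value.  Reduced-set
experiments retrain the classifier on the top-k most frequent loci over many
fresh splits, optionally ablating chosen loci.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .evaluate import (
    RunResult,
    SplitSpec,
    average_mcc,
    confusion_and_sensitivity,
    stratified_split,
    train_predict,
)
from .ga import FeatureSet, GAConfig, evolve
from .matrix import ExpressionMatrix

__all__ = [
    "ExperimentConfig",
    "child_seed",
    "run_experiment",
    "count_frequencies",
    "null_frequency_pvalue",
    "reduced_set_evaluation",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Settings for the repeated-run experiment.

    Defaults are the full-scale protocol: 100 runs, 75/25 stratified splits,
    a frequency cutoff of 11 for flagging, and the 9-feature / 1000-split
    reduced-set experiment.
    """

    n_runs: int = 100
    ga: GAConfig = field(default_factory=GAConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    frequency_cutoff: int = 11
    reduced_k: int = 9
    reduced_reps: int = 1000
    eval_trees: int = 500
    classifier_kind: str = "rf"
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.reduced_k > self.ga.chromosome_length:
            raise ValueError("reduced_k cannot exceed chromosome_length")


def child_seed(master_seed: int, tag: str, index: int) -> int:
    """Deterministic sub-seed from (master seed, purpose tag, index), below 2^31."""
    digest = hashlib.blake2b(f"{master_seed}:{tag}:{index}".encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") % (2**31)


def run_single(
    matrix: ExpressionMatrix,
    config: ExperimentConfig,
    run_index: int,
) -> RunResult:
    """One independent run: stratified split, GA on the training partition,
    final-classifier evaluation on the test partition."""
    labels = np.asarray(matrix.labels)
    split_spec = replace(config.split, seed=child_seed(config.master_seed, "split", run_index))
    train_idx, test_idx = stratified_split(labels, split_spec)
    ga_cfg = replace(config.ga, rng_seed=child_seed(config.master_seed, "ga", run_index))
    trace = evolve(matrix.values[train_idx], labels[train_idx], ga_cfg)
    assert trace.best_set is not None
    eval_seed = child_seed(config.master_seed, "eval", run_index)
    predicted = train_predict(
        matrix.values[train_idx],
        labels[train_idx],
        matrix.values[test_idx],
        trace.best_set,
        classifier_kind=config.classifier_kind,
        seed=eval_seed,
        n_trees=config.eval_trees,
    )
    actual = labels[test_idx]
    order = matrix.class_order
    confusion, per_class, avg = confusion_and_sensitivity(actual, predicted, order)
    mcc = average_mcc(actual, predicted, order)
    return RunResult(
        selected=trace.best_set,
        class_order=order,
        confusion=confusion,
        per_class_sensitivity=per_class,
        avg_sensitivity=avg,
        avg_mcc=mcc,
        classifier_kind=config.classifier_kind,
        seed=eval_seed,
    )


def run_experiment(matrix: ExpressionMatrix, config: ExperimentConfig) -> list[RunResult]:
    """The repeated-run experiment; each run is independent and reproducible."""
    results = []
    for run_index in range(config.n_runs):
        try:
            results.append(run_single(matrix, config, run_index))
        except Exception as exc:  # noqa: BLE001 - abort with the failing run index
            raise RuntimeError(f"run {run_index} failed") from exc
    return results


def null_frequency_pvalue(
    frequency: int,
    n_runs: int,
    set_size: int,
    n_candidates: int,
) -> tuple[float, float]:
    """Upper-tail binomial p-value for a selection frequency, plus Bonferroni.

    Null: each run's set is a uniform random ``set_size``-subset of the
    ``n_candidates`` loci, so a given locus is selected independently per run
    with probability set_size/n_candidates and its total frequency is
    binomial.  Returns (P(X >= frequency), min(1, p * n_candidates)).
    """
    if not 0 <= frequency <= n_runs:
        raise ValueError("frequency must lie in [0, n_runs]")
    if set_size > n_candidates:
        raise ValueError("set_size cannot exceed n_candidates")
    p_select = set_size / n_candidates
    null_p = float(stats.binom.sf(frequency - 1, n_runs, p_select))
    return null_p, min(1.0, null_p * n_candidates)


def count_frequencies(
    results: Sequence[RunResult],
    n_candidates: int,
    frequency_cutoff: int = 11,
) -> pd.DataFrame:
    """Per-locus selection counts over all runs, with null and adjusted p-values.

    Returns a frame indexed by feature ID with columns ``frequency``,
    ``null_p``, ``adjusted_p`` and ``flagged`` (frequency >= cutoff), sorted
    by descending frequency then ascending feature ID.  Counts conserve mass:
    they sum to n_runs * chromosome cardinality.
    """
    if not results:
        raise ValueError("no results")
    cardinalities = {r.selected.cardinality for r in results}
    if len(cardinalities) != 1:
        raise ValueError("runs do not share a chromosome cardinality")
    (set_size,) = cardinalities
    counts = np.zeros(n_candidates, dtype=int)
    for r in results:
        for fid in r.selected.feature_ids:
            counts[fid] += 1
    n_runs = len(results)
    rows = []
    for fid in range(n_candidates):
        null_p, adj_p = null_frequency_pvalue(int(counts[fid]), n_runs, set_size, n_candidates)
        rows.append((fid, int(counts[fid]), null_p, adj_p, counts[fid] >= frequency_cutoff))
    frame = pd.DataFrame(rows, columns=["feature_id", "frequency", "null_p", "adjusted_p", "flagged"])
    frame = frame.sort_values(["frequency", "feature_id"], ascending=[False, True])
    return frame.set_index("feature_id")


def top_k_features(table: pd.DataFrame, k: int) -> FeatureSet:
    """The k most frequently selected loci; ties broken by feature ID order."""
    if k > len(table):
        raise ValueError("k exceeds the number of candidate loci")
    ordered = table.sort_values(["frequency", "feature_id"], ascending=[False, True])
    return FeatureSet(frozenset(ordered.index[:k].tolist()))


def reduced_set_evaluation(
    matrix: ExpressionMatrix,
    table: pd.DataFrame,
    k: int,
    reps: int,
    classifier_kind: str = "rf",
    drop_loci: Iterable[int] | None = None,
    n_trees: int = 500,
    master_seed: int = 0,
    split: SplitSpec | None = None,
) -> dict:
    """Classification with the top-k most frequent loci over many fresh splits.

    Optionally removes ``drop_loci`` from the top-k set (the ablation of
    features of interest); dropping a locus outside the top-k set is a fatal
    error.  For each rep a fresh stratified split is drawn, the classifier is
    trained and tested, and the macro-averaged sensitivity recorded.  Returns
    the selected set, all rep values, their mean and standard deviation.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    selected = top_k_features(table, k)
    if drop_loci is not None:
        drop = frozenset(int(f) for f in drop_loci)
        if not drop <= selected.feature_ids:
            raise ValueError(f"drop_loci {sorted(drop - selected.feature_ids)} not in the top-{k} set")
        selected = FeatureSet(selected.feature_ids - drop)
    labels = np.asarray(matrix.labels)
    order = matrix.class_order
    base_split = split if split is not None else SplitSpec()
    values = np.empty(reps)
    for rep in range(reps):
        spec = replace(base_split, seed=child_seed(master_seed, "reduced-split", rep))
        train_idx, test_idx = stratified_split(labels, spec)
        predicted = train_predict(
            matrix.values[train_idx],
            labels[train_idx],
            matrix.values[test_idx],
            selected,
            classifier_kind=classifier_kind,
            seed=child_seed(master_seed, "reduced-eval", rep),
            n_trees=n_trees,
        )
        _, _, avg = confusion_and_sensitivity(labels[test_idx], predicted, order)
        values[rep] = avg
    return {
        "feature_set": selected,
        "values": values,
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)) if reps > 1 else 0.0,
    }
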