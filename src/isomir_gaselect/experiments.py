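"""Desk-scale experiment protocols over the synthetic study conditions.

The full-scale analysis (32 tumor types, ~9000 samples, 50-feature
chromosomes, 100 runs of a 300-generation GA) is far beyond desk scale, so
the package ships a scaled-down protocol over the default synthetic design:
6 unbalanced classes, 300 candidate loci with 12 planted markers, 15-feature
chromosomes searched by a population of 20 for 30 generations, repeated for
10 independent runs.  Fitness forests use 25 trees and final-evaluation
forests 200 trees at this problem size.  These functions are the single
source of truth for those conditions; the analysis drivers, the test suite
and the acceptance script all call them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .evaluate import RunResult, SplitSpec
from .frequency import (
    ExperimentConfig,
    child_seed,
    count_frequencies,
    reduced_set_evaluation,
    run_experiment,
)
from .ga import GAConfig
from .matrix import ExpressionMatrix
from .simulate import GroundTruth, SyntheticConfig, generate_matrix

__all__ = [
    "TinyExperimentOutcome",
    "tiny_experiment_config",
    "run_tiny_experiment",
    "permuted_label_baseline",
    "truth_frequency_table",
    "ablation_experiment",
]


def tiny_experiment_config(master_seed: int, n_runs: int = 10) -> ExperimentConfig:
    """The scaled-down repeated-run protocol (10 runs by default)."""
    return ExperimentConfig(
        n_runs=n_runs,
        ga=GAConfig(
            chromosome_length=15,
            population_size=20,
            max_generations=30,
            fitness_trees=25,
        ),
        split=SplitSpec(),
        frequency_cutoff=3,
        reduced_k=9,
        reduced_reps=60,
        eval_trees=200,
        master_seed=master_seed,
    )


@dataclass
class TinyExperimentOutcome:
    """Everything the downstream analyses need from one tiny experiment."""

    config: SyntheticConfig
    matrix: ExpressionMatrix
    truth: GroundTruth
    results: list[RunResult]
    frequency_table: pd.DataFrame
    planted_mean_frequency: float
    noise_mean_frequency: float
    ranksum_p: float
    mean_sensitivity: float
    mean_mcc: float


def run_tiny_experiment(master_seed: int, n_runs: int = 10) -> TinyExperimentOutcome:
    """Generate the default synthetic dataset and run the repeated GA/RF protocol.

    Returns the per-run results, the selection-frequency table over all
    candidate loci, and the planted-vs-noise frequency comparison
    (one-sided Wilcoxon rank-sum, planted greater).
    """
    sim_config = SyntheticConfig(seed=child_seed(master_seed, "sim", 0))
    matrix, truth = generate_matrix(sim_config)
    exp_config = tiny_experiment_config(child_seed(master_seed, "exp", 0), n_runs=n_runs)
    results = run_experiment(matrix, exp_config)
    table = count_frequencies(
        results, n_candidates=matrix.n_features, frequency_cutoff=exp_config.frequency_cutoff
    )
    planted = sorted(truth.informative_ids())
    noise = [j for j in range(matrix.n_features) if j not in set(planted)]
    freq = table["frequency"]
    planted_freq = freq.loc[planted].to_numpy()
    noise_freq = freq.loc[noise].to_numpy()
    ranksum = stats.mannwhitneyu(planted_freq, noise_freq, alternative="greater")
    return TinyExperimentOutcome(
        config=sim_config,
        matrix=matrix,
        truth=truth,
        results=results,
        frequency_table=table,
        planted_mean_frequency=float(planted_freq.mean()),
        noise_mean_frequency=float(noise_freq.mean()),
        ranksum_p=float(ranksum.pvalue),
        mean_sensitivity=float(np.mean([r.avg_sensitivity for r in results])),
        mean_mcc=float(np.mean([r.avg_mcc for r in results])),
    )


def permuted_label_baseline(
    matrix: ExpressionMatrix, master_seed: int, n_runs: int = 6
) -> dict:
    """Chance baseline: the identical protocol on label-permuted data.

    Permuting the tumor-type labels destroys every genuine class signal, so
    the distribution of the resulting test sensitivities estimates the chance
    level (and its run-to-run spread) of the whole search-plus-evaluation
    procedure.
    """
    rng = np.random.default_rng(child_seed(master_seed, "permute", 0))
    permuted = ExpressionMatrix(
        matrix.values.copy(),
        list(matrix.sample_ids),
        [matrix.labels[i] for i in rng.permutation(matrix.n_samples)],
        list(matrix.loci),
    )
    exp_config = tiny_experiment_config(child_seed(master_seed, "perm-exp", 0), n_runs=n_runs)
    results = run_experiment(permuted, exp_config)
    values = np.array([r.avg_sensitivity for r in results])
    return {
        "values": values,
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)),
    }


def truth_frequency_table(truth: GroundTruth, n_features: int) -> pd.DataFrame:
    """A frequency table ranking the planted markers first (synthetic stand-in).

    Used by the ablation experiment to pin the reduced set to the known
    markers instead of re-running the full frequency pipeline; frequencies
    are descending ranks, so top-k selection is deterministic.
    """
    planted = sorted(truth.informative_ids())
    freq = {fid: 100 - i for i, fid in enumerate(planted)}
    rows = [(fid, freq.get(fid, 0)) for fid in range(n_features)]
    return pd.DataFrame(rows, columns=["feature_id", "frequency"]).set_index("feature_id")


def ablation_experiment(master_seed: int, reps: int = 60) -> dict:
    """Reduced-set ablation on data with redundant same-block marker copies.

    Nine markers over six classes, grouped so three classes carry a redundant
    same-block pair and three classes a single distinct-signal marker.  Three
    conditions are evaluated over fresh stratified splits: the full 9-marker
    set, the set minus the three distinct-signal singletons, and the set
    minus one redundant copy from each pair.  Removing a class's only marker
    should cost more sensitivity than removing redundant copies.
    """
    sim_config = SyntheticConfig(
        seed=child_seed(master_seed, "ablation-sim", 0),
        n_informative=9,
        informative_assignment="grouped",
        block_correlation=0.8,
    )
    matrix, truth = generate_matrix(sim_config)
    table = truth_frequency_table(truth, matrix.n_features)
    paired = [sorted(ids) for ids in truth.informative.values() if len(ids) == 2]
    singles = [next(iter(ids)) for ids in truth.informative.values() if len(ids) == 1]
    drop_redundant = {pair[0] for pair in paired}
    drop_distinct = set(singles)
    common = dict(k=9, reps=reps, n_trees=100, master_seed=child_seed(master_seed, "ablation", 0))
    full = reduced_set_evaluation(matrix, table, **common)
    no_distinct = reduced_set_evaluation(matrix, table, drop_loci=drop_distinct, **common)
    no_redundant = reduced_set_evaluation(matrix, table, drop_loci=drop_redundant, **common)
    return {
        "matrix": matrix,
        "truth": truth,
        "full": full,
        "drop_distinct": no_distinct,
        "drop_redundant": no_redundant,
    }
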