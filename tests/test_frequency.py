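"""Selection-frequency counting, the binomial/Bonferroni null, and reduced sets."""

import numpy as np
import pandas as pd
import pytest

from isomir_gaselect import (
    ExperimentConfig,
    FeatureSet,
    GAConfig,
    SplitSpec,
    count_frequencies,
    null_frequency_pvalue,
    reduced_set_evaluation,
    run_experiment,
)
from isomir_gaselect.evaluate import RunResult
from isomir_gaselect.frequency import child_seed, top_k_features
from isomir_gaselect.matrix import ExpressionMatrix
from isomir_gaselect.simulate import SyntheticConfig, generate_matrix

TINY_EXPERIMENT = ExperimentConfig(
    n_runs=2,
    ga=GAConfig(chromosome_length=6, population_size=6, max_generations=3, fitness_trees=15),
    split=SplitSpec(),
    reduced_k=6,
    eval_trees=30,
    master_seed=5,
)


def _fake_results(sets, n_total=20):
    return [
        RunResult(
            selected=FeatureSet(frozenset(s)),
            class_order=["A", "B"],
            confusion=np.eye(2, dtype=int),
            per_class_sensitivity={},
            avg_sensitivity=1.0,
            avg_mcc=1.0,
            classifier_kind="rf",
            seed=0,
        )
        for s in sets
    ]


class TestNullPvalue:
    def test_frequency_zero_covers_whole_sample_space(self):
        null_p, adjusted = null_frequency_pvalue(0, 100, 50, 2231)
        assert null_p == 1.0
        assert adjusted == 1.0

    def test_more_than_eleven_is_significant_at_full_scale(self):
        """Freq 12 of 100 runs with 50-sets over 2231 candidates: adjusted p <= 0.01."""
        null_p, adjusted = null_frequency_pvalue(12, 100, 50, 2231)
        assert adjusted <= 0.01
        # Frequency 11 itself should NOT pass the 'more than 11' argument scale-free:
        _, adjusted_11 = null_frequency_pvalue(11, 100, 50, 2231)
        assert adjusted_11 > adjusted

    def test_monotone_decreasing_in_frequency(self):
        values = [null_frequency_pvalue(f, 100, 50, 2231)[0] for f in range(0, 30)]
        assert all(b <= a for a, b in zip(values, values[1:]))

    def test_monotone_increasing_in_selection_probability(self):
        smaller = null_frequency_pvalue(5, 100, 20, 2231)[0]
        larger = null_frequency_pvalue(5, 100, 80, 2231)[0]
        assert larger >= smaller

    def test_bonferroni_is_exact_capped_product(self):
        null_p, adjusted = null_frequency_pvalue(3, 100, 50, 2231)
        assert adjusted == min(1.0, null_p * 2231)

    def test_matches_monte_carlo_of_random_subset_draws(self):
        """Analytic tail vs simulation of per-run random 50-subset membership."""
        rng = np.random.default_rng(17)
        n_rep, n_runs, set_size, n_cand = 200_000, 100, 50, 2231
        # Membership of a fixed locus in a uniform random 50-subset of 2231 is
        # Bernoulli(50/2231); verify that equivalence on real subset draws first.
        hits = sum(0 in frozenset(rng.choice(n_cand, size=set_size, replace=False)) for _ in range(2000))
        assert hits / 2000 == pytest.approx(set_size / n_cand, abs=4 * np.sqrt(0.0224 * 0.9776 / 2000))
        freq = (rng.random((n_rep, n_runs)) < set_size / n_cand).sum(axis=1)
        for f in range(1, 16):
            mc = float(np.mean(freq >= f))
            analytic = null_frequency_pvalue(f, n_runs, set_size, n_cand)[0]
            # SE under the hypothesis being tested; robust when mc sees 0 events.
            se = np.sqrt(analytic * (1 - analytic) / n_rep)
            assert abs(analytic - mc) <= 3 * se

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            null_frequency_pvalue(101, 100, 50, 2231)
        with pytest.raises(ValueError):
            null_frequency_pvalue(5, 100, 60, 50)


class TestCountFrequencies:
    def test_exact_counts_and_conservation(self):
        sets = [{0, 1, 2}, {0, 1, 3}, {0, 4, 5}]
        table = count_frequencies(_fake_results(sets), n_candidates=10, frequency_cutoff=2)
        assert table.loc[0, "frequency"] == 3
        assert table.loc[1, "frequency"] == 2
        assert table.loc[9, "frequency"] == 0
        assert table["frequency"].sum() == 3 * 3
        assert bool(table.loc[0, "flagged"]) and not bool(table.loc[4, "flagged"])

    def test_cutoff_flags_at_or_above(self):
        sets = [{0, 1}] * 11 + [{1, 2}] * 4
        table = count_frequencies(_fake_results(sets), n_candidates=5, frequency_cutoff=11)
        assert bool(table.loc[0, "flagged"])  # exactly 11
        assert bool(table.loc[1, "flagged"])  # 15
        assert not bool(table.loc[2, "flagged"])  # 4

    def test_mixed_cardinalities_rejected(self):
        with pytest.raises(ValueError, match="cardinality"):
            count_frequencies(_fake_results([{0, 1}, {0, 1, 2}]), n_candidates=5)

    def test_adjusted_p_relationship(self):
        table = count_frequencies(_fake_results([{0, 1, 2}] * 5), n_candidates=50)
        assert (table["adjusted_p"] >= table["null_p"]).all()
        assert ((table["null_p"] > 0) & (table["null_p"] <= 1)).all()


class TestRunExperiment:
    def test_deterministic_under_master_seed(self, tiny_dataset):
        _, matrix, _ = tiny_dataset
        a = run_experiment(matrix, TINY_EXPERIMENT)
        b = run_experiment(matrix, TINY_EXPERIMENT)
        assert [r.selected for r in a] == [r.selected for r in b]
        assert [r.avg_sensitivity for r in a] == [r.avg_sensitivity for r in b]
        assert np.array_equal(a[0].confusion, b[0].confusion)

    def test_different_master_seeds_differ(self, tiny_dataset):
        _, matrix, _ = tiny_dataset
        from dataclasses import replace

        a = run_experiment(matrix, TINY_EXPERIMENT)
        b = run_experiment(matrix, replace(TINY_EXPERIMENT, master_seed=99))
        assert [r.selected for r in a] != [r.selected for r in b]

    def test_confusion_rows_match_test_counts(self, tiny_dataset):
        _, matrix, _ = tiny_dataset
        results = run_experiment(matrix, TINY_EXPERIMENT)
        labels = np.asarray(matrix.labels)
        class_counts = {c: int(np.sum(labels == c)) for c in matrix.class_order}
        for r in results:
            for i, cls in enumerate(r.class_order):
                n = class_counts[cls]
                assert r.confusion[i].sum() == n - int(0.75 * n)


class TestChildSeed:
    def test_deterministic_and_distinct(self):
        assert child_seed(1, "split", 0) == child_seed(1, "split", 0)
        seeds = {child_seed(1, "split", i) for i in range(100)}
        assert len(seeds) == 100
        assert all(0 <= s < 2**31 for s in seeds)
        assert child_seed(1, "split", 0) != child_seed(1, "ga", 0)


class TestReducedSet:
    @staticmethod
    def _table(frequencies: dict[int, int], n_candidates: int) -> pd.DataFrame:
        rows = [(fid, frequencies.get(fid, 0)) for fid in range(n_candidates)]
        frame = pd.DataFrame(rows, columns=["feature_id", "frequency"])
        return frame.set_index("feature_id")

    def test_top_k_tie_break_by_feature_id(self):
        table = self._table({3: 5, 1: 5, 2: 7}, 10)
        assert top_k_features(table, 2).feature_ids == frozenset({2, 1})

    def test_full_feature_set_on_separable_data_near_perfect(self, tiny_dataset):
        _, matrix, truth = tiny_dataset
        informative = sorted(truth.informative_ids())
        table = self._table({fid: 100 - i for i, fid in enumerate(informative)}, matrix.n_features)
        out = reduced_set_evaluation(matrix, table, k=len(informative), reps=5, n_trees=60, master_seed=2)
        assert out["mean"] >= 0.9

    def test_single_rep_reproducible(self, tiny_dataset):
        _, matrix, truth = tiny_dataset
        informative = sorted(truth.informative_ids())
        table = self._table({fid: 50 for fid in informative}, matrix.n_features)
        a = reduced_set_evaluation(matrix, table, k=6, reps=1, n_trees=40, master_seed=7)
        b = reduced_set_evaluation(matrix, table, k=6, reps=1, n_trees=40, master_seed=7)
        assert a["values"][0] == b["values"][0]
        assert a["feature_set"] == b["feature_set"]

    def test_drop_outside_top_k_is_fatal(self, tiny_dataset):
        _, matrix, truth = tiny_dataset
        informative = sorted(truth.informative_ids())
        table = self._table({fid: 50 for fid in informative}, matrix.n_features)
        outside = max(informative) + 1
        with pytest.raises(ValueError, match="drop_loci"):
            reduced_set_evaluation(matrix, table, k=6, reps=1, drop_loci={outside}, master_seed=0)

    def test_dropping_informative_loci_lowers_sensitivity(self):
        """Ablating a class's only marker hurts more than ablating a redundant copy."""
        config = SyntheticConfig(seed=23, n_informative=9, informative_assignment="grouped")
        matrix, truth = generate_matrix(config)
        informative = sorted(truth.informative_ids())
        table = self._table({fid: 100 - i for i, fid in enumerate(informative)}, matrix.n_features)
        paired = [sorted(v) for v in truth.informative.values() if len(v) == 2]
        single = [sorted(v)[0] for v in truth.informative.values() if len(v) == 1]
        drop_redundant = {p[0] for p in paired}
        drop_distinct = set(single)
        kw = dict(k=9, reps=8, n_trees=60, master_seed=3)
        full = reduced_set_evaluation(matrix, table, **kw)
        no_distinct = reduced_set_evaluation(matrix, table, drop_loci=drop_distinct, **kw)
        no_redundant = reduced_set_evaluation(matrix, table, drop_loci=drop_redundant, **kw)
        assert no_distinct["mean"] < full["mean"]
        assert no_distinct["mean"] < no_redundant["mean"]
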