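"""Genetic-algorithm search over fixed-cardinality feature subsets.

A "chromosome" is a set of exactly ``chromosome_length`` feature IDs (matrix
column indices); fitness is the macro-averaged per-class sensitivity of a
random forest restricted to those columns, estimated without touching any
held-out test data — by default from the forest's out-of-bag predictions on
the training rows, optionally by stratified internal cross-validation.
Evolution is tournament selection, set-valued uniform crossover with repair,
per-gene replacement mutation and elitism, run for a fixed number of
generations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_predict

__all__ = [
    "FeatureSet",
    "GAConfig",
    "GATrace",
    "init_population",
    "fitness",
    "crossover",
    "mutate",
    "evolve",
]


@dataclass(frozen=True)
class FeatureSet:
    """A fixed-cardinality set of feature IDs — one GA chromosome."""

    feature_ids: frozenset[int]

    @property
    def cardinality(self) -> int:
        return len(self.feature_ids)

    def columns(self) -> list[int]:
        return sorted(self.feature_ids)


@dataclass(frozen=True)
class GAConfig:
    """GA and fitness-classifier settings.

    Defaults mirror the full-scale analysis: 50-feature chromosomes, a
    population of 50, 300 generations.  The operator parameters (tournament
    size 3, crossover probability 0.9, per-gene mutation rate 0.02, one
    elite) are conventional wrapper-selection settings.
    """

    chromosome_length: int = 50
    population_size: int = 50
    max_generations: int = 300
    mutation_rate: float = 0.02
    crossover_prob: float = 0.9
    tournament_size: int = 3
    elitism_count: int = 1
    rng_seed: int = 0
    fitness_mode: str = "oob"  # "oob" | "internal_cv"
    fitness_trees: int = 100
    internal_cv_folds: int = 3

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0 <= self.elitism_count < self.population_size:
            raise ValueError("elitism_count must be in [0, population_size)")
        if self.fitness_mode not in ("oob", "internal_cv"):
            raise ValueError(f"unknown fitness_mode {self.fitness_mode!r}")


@dataclass
class GATrace:
    """Per-generation fitness trace and the best set ever seen."""

    best_fitness: list[float] = field(default_factory=list)
    mean_fitness: list[float] = field(default_factory=list)
    best_set: FeatureSet | None = None
    best_set_fitness: float = float("-inf")

    def write_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            handle.write("generation\tbest_fitness\tmean_fitness\n")
            for g, (b, m) in enumerate(zip(self.best_fitness, self.mean_fitness)):
                handle.write(f"{g}\t{b:.6f}\t{m:.6f}\n")


def init_population(config: GAConfig, n_features: int, rng: np.random.Generator) -> list[FeatureSet]:
    """Uniform random size-k subsets, duplicates across the population allowed."""
    if n_features < config.chromosome_length:
        raise ValueError(
            f"chromosome_length {config.chromosome_length} exceeds feature count {n_features}"
        )
    return [
        FeatureSet(frozenset(rng.choice(n_features, size=config.chromosome_length, replace=False).tolist()))
        for _ in range(config.population_size)
    ]


def _macro_sensitivity_from_predictions(y: np.ndarray, pred: np.ndarray, valid: np.ndarray) -> float:
    """Unweighted mean of per-class recall over classes with scored samples."""
    sens = []
    for cls in np.unique(y):
        mask = (y == cls) & valid
        n = int(mask.sum())
        if n == 0:
            warnings.warn(f"class {cls!r} has no scored samples in fitness", stacklevel=3)
            continue
        sens.append(float(np.mean(pred[mask] == cls)))
    return float(np.mean(sens)) if sens else 0.0


def fitness(fs: FeatureSet, X: np.ndarray, y: np.ndarray, config: GAConfig, seed: int) -> float:
    """Leakage-free fitness of one feature set on the training partition.

    ``oob``: fit a random forest on the training rows restricted to the set's
    columns and score the out-of-bag predictions.  Samples that never fall
    out of bag (possible with few trees) are excluded from scoring.
    ``internal_cv``: stratified K-fold cross-validated predictions instead.
    Returns macro-averaged per-class sensitivity in [0, 1].
    """
    Xs = X[:, fs.columns()]
    y = np.asarray(y)
    if config.fitness_mode == "oob":
        clf = RandomForestClassifier(
            n_estimators=config.fitness_trees, oob_score=True, random_state=seed, n_jobs=1
        )
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message="Some inputs do not have OOB scores")
            clf.fit(Xs, y)
        votes = clf.oob_decision_function_
        valid = ~np.isnan(votes).any(axis=1) & (votes.sum(axis=1) > 0)
        pred = np.asarray(clf.classes_)[np.argmax(np.nan_to_num(votes), axis=1)]
        return _macro_sensitivity_from_predictions(y, pred, valid)
    clf = RandomForestClassifier(n_estimators=config.fitness_trees, random_state=seed, n_jobs=1)
    cv = StratifiedKFold(n_splits=config.internal_cv_folds, shuffle=True, random_state=seed)
    pred = cross_val_predict(clf, Xs, y, cv=cv)
    return _macro_sensitivity_from_predictions(y, pred, np.ones(len(y), dtype=bool))


def crossover(
    parent_a: FeatureSet,
    parent_b: FeatureSet,
    n_features: int,
    rng: np.random.Generator,
) -> tuple[FeatureSet, FeatureSet]:
    """Set-valued uniform crossover with cardinality repair.

    Genes shared by both parents are inherited by both children; each
    non-shared gene goes to one child uniformly at random.  Children are then
    repaired to the exact cardinality: undersized children draw first from
    the parents' union, then from the global feature pool; oversized children
    drop random non-shared genes.
    """
    if parent_a.cardinality != parent_b.cardinality:
        raise ValueError("parents must share cardinality")
    k = parent_a.cardinality
    shared = parent_a.feature_ids & parent_b.feature_ids
    non_shared = sorted((parent_a.feature_ids | parent_b.feature_ids) - shared)
    union = parent_a.feature_ids | parent_b.feature_ids
    child_a, child_b = set(shared), set(shared)
    for gene in non_shared:
        (child_a if rng.random() < 0.5 else child_b).add(gene)

    def repair(child: set[int]) -> frozenset[int]:
        while len(child) > k:
            extras = sorted(child - shared)
            child.discard(extras[rng.integers(len(extras))])
        while len(child) < k:
            pool = sorted(union - child)
            if not pool:
                pool = [g for g in range(n_features) if g not in child]
            child.add(pool[rng.integers(len(pool))])
        return frozenset(child)

    return FeatureSet(repair(child_a)), FeatureSet(repair(child_b))


def mutate(fs: FeatureSet, rate: float, n_features: int, rng: np.random.Generator) -> FeatureSet:
    """Replace each member independently with probability ``rate`` by a random non-member."""
    members = set(fs.feature_ids)
    for gene in sorted(fs.feature_ids):
        if rng.random() < rate:
            replacement = int(rng.integers(n_features))
            while replacement in members:
                replacement = int(rng.integers(n_features))
            members.discard(gene)
            members.add(replacement)
    return FeatureSet(frozenset(members))


def _tournament(
    population: list[FeatureSet],
    fitnesses: list[float],
    size: int,
    rng: np.random.Generator,
) -> FeatureSet:
    # Ties go to the first-encountered contestant under the run's RNG order.
    idx = rng.integers(len(population), size=size)
    best = idx[0]
    for i in idx[1:]:
        if fitnesses[i] > fitnesses[best]:
            best = i
    return population[best]


def evolve(X: np.ndarray, y: np.ndarray, config: GAConfig) -> GATrace:
    """Run the GA on a training partition and return the trace and best set.

    Fully deterministic under ``config.rng_seed``.  Fitness values are cached
    by feature set, so converged populations re-evaluate cheaply.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n_features = X.shape[1]
    rng = np.random.default_rng(config.rng_seed)
    fit_seed = int(rng.integers(2**31))
    cache: dict[frozenset[int], float] = {}

    def scored(fs: FeatureSet) -> float:
        key = fs.feature_ids
        if key not in cache:
            cache[key] = fitness(fs, X, y, config, fit_seed)
        return cache[key]

    population = init_population(config, n_features, rng)
    trace = GATrace()
    for _generation in range(config.max_generations + 1):
        fits = [scored(fs) for fs in population]
        gen_best = int(np.argmax(fits))
        trace.best_fitness.append(fits[gen_best])
        trace.mean_fitness.append(float(np.mean(fits)))
        if fits[gen_best] > trace.best_set_fitness:
            trace.best_set_fitness = fits[gen_best]
            trace.best_set = population[gen_best]
        if _generation == config.max_generations:
            break
        elite_idx = np.argsort(fits)[::-1][: config.elitism_count]
        next_population = [population[i] for i in elite_idx]
        while len(next_population) < config.population_size:
            pa = _tournament(population, fits, config.tournament_size, rng)
            pb = _tournament(population, fits, config.tournament_size, rng)
            if rng.random() < config.crossover_prob:
                ca, cb = crossover(pa, pb, n_features, rng)
            else:
                ca, cb = pa, pb
            for child in (ca, cb):
                if len(next_population) < config.population_size:
                    next_population.append(mutate(child, config.mutation_rate, n_features, rng))
        population = next_population
    return trace
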