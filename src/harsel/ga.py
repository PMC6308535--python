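"""Genetic algorithm for simultaneous feature selection and classifier
parameter optimization.

Each candidate solution is a binary chromosome: one bit per available
feature (1 = feature used) concatenated with a classifier-specific
parameter substring (KNN 5 bits, FNN 3, SVM 6, DT 0).  Fitness (lower is
better) combines total validation accuracy with a class-balance penalty:

    fitness = 1 − acc + 0.3 × (max_a acc_a − min_a acc_a)

where acc is the overall validation accuracy and acc_a the per-activity
accuracies, all in [0, 1]; a chromosome selecting no features receives
the worst possible value, 1.3, without training.

One generation: roulette-wheel parent selection (selection weight
worst − fitness + ε, so better fitness → strictly higher probability),
population/2 couples producing population children by four-point
crossover (probability 1 by default), per-individual mutation (with
probability p one uniformly chosen bit flips; a per-bit mode is
available), then elitist truncation of parents ∪ children back to the
population size — which makes the best-so-far fitness monotonically
non-increasing.  Stops at ``max_iterations`` or after
``plateau_patience`` generations without improvement.

Library-scale defaults (population 400, 30 iterations) match an
overnight-run regime; tests and examples use reduced configurations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from . import classifiers as clf
from .dataset import FeatureTable, KEY_COLUMNS

WORST_FITNESS = 1.3  # assigned to all-zero feature masks
BALANCE_PENALTY = 0.3
ROULETTE_EPS = 1e-9


@dataclass
class Chromosome:
    feature_bits: np.ndarray  # uint8, one per available feature
    param_bits: np.ndarray    # uint8, classifier-specific length
    fitness: float | None = None

    def __post_init__(self) -> None:
        self.feature_bits = np.asarray(self.feature_bits, dtype=np.uint8)
        self.param_bits = np.asarray(self.param_bits, dtype=np.uint8)
        if self.fitness is not None and not (0 <= self.fitness <= WORST_FITNESS):
            raise ValueError(f"fitness must be in [0, {WORST_FITNESS}]")

    @property
    def bits(self) -> np.ndarray:
        return np.concatenate([self.feature_bits, self.param_bits])

    @property
    def n_selected(self) -> int:
        return int(self.feature_bits.sum())

    def split_like(self, bits: np.ndarray) -> "Chromosome":
        nf = len(self.feature_bits)
        return Chromosome(bits[:nf].copy(), bits[nf:].copy())

    def copy(self) -> "Chromosome":
        return Chromosome(self.feature_bits.copy(), self.param_bits.copy(),
                          self.fitness)


@dataclass
class FitnessComponents:
    acc: float
    acc_activity: dict[int, float]
    fitness: float


@dataclass
class GaConfig:
    population_size: int = 400
    max_iterations: int = 30
    plateau_patience: int = 15
    crossover_cut_points: int = 4
    crossover_probability: float = 1.0
    mutation_probability: float = 0.2
    mutation_mode: str = "per_individual"  # or "per_bit"
    seed: int = 0
    svm_gaussian_scale: float = clf.DEFAULT_SVM_GAUSSIAN_SCALE
    fnn_max_iter: int = clf.DEFAULT_FNN_MAX_ITER

    def __post_init__(self) -> None:
        if self.population_size < 2 or self.population_size % 2:
            raise ValueError("population_size must be even and >= 2")
        for p in (self.crossover_probability, self.mutation_probability):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must be in [0, 1]")
        if self.mutation_mode not in ("per_individual", "per_bit"):
            raise ValueError("mutation_mode must be 'per_individual' or 'per_bit'")


def fitness_value(acc: float, acc_activity: Sequence[float]) -> float:
    """The balance-penalized fitness from accuracies in [0, 1]."""
    acc_activity = np.asarray(list(acc_activity), dtype=float)
    return 1.0 - acc + BALANCE_PENALTY * (acc_activity.max() - acc_activity.min())


def evaluate_fitness(
    chrom: Chromosome,
    kind: str,
    training: FeatureTable,
    validation: FeatureTable,
    seed: int = 0,
    svm_gaussian_scale: float = clf.DEFAULT_SVM_GAUSSIAN_SCALE,
    fnn_max_iter: int = clf.DEFAULT_FNN_MAX_ITER,
) -> FitnessComponents:
    """Train on the selected columns and score on the validation table."""
    if chrom.n_selected == 0:
        chrom.fitness = WORST_FITNESS
        return FitnessComponents(0.0, {}, WORST_FITNESS)
    names = [n for n, b in zip(training.feature_names, chrom.feature_bits) if b]
    params = clf.decode_params(kind, chrom.param_bits, len(training), len(names))
    model = clf.train(kind, params, training.select_features(names), seed=seed,
                      svm_gaussian_scale=svm_gaussian_scale,
                      fnn_max_iter=fnn_max_iter)
    pred = clf.predict(model, validation.select_features(names))
    truth = validation.y
    acc = float(np.mean(pred == truth))
    per_activity = {
        int(a): float(np.mean(pred[truth == a] == a)) for a in np.unique(truth)
    }
    fit = fitness_value(acc, list(per_activity.values()))
    chrom.fitness = fit
    return FitnessComponents(acc, per_activity, fit)


def roulette_select(
    population: Sequence[Chromosome], n_parents: int, rng: np.random.Generator
) -> list[Chromosome]:
    """Fitness-proportional sampling (with replacement) for a minimized
    fitness: weight = worst − fitness + ε, normalized."""
    if not population:
        raise ValueError("population is empty")
    fit = np.array([c.fitness for c in population], dtype=float)
    if np.any(np.isnan(fit)):
        raise ValueError("all fitness values must be set before selection")
    weights = fit.max() - fit + ROULETTE_EPS
    weights /= weights.sum()
    idx = rng.choice(len(population), size=n_parents, replace=True, p=weights)
    return [population[i] for i in idx]


def crossover(
    p1: Chromosome, p2: Chromosome, rng: np.random.Generator, cut_points: int = 4
) -> tuple[Chromosome, Chromosome]:
    """Multi-point crossover over the full concatenated bit string.

    ``cut_points`` distinct positions are drawn; alternating segments are
    exchanged between the parents.
    """
    b1, b2 = p1.bits, p2.bits
    if len(b1) != len(b2):
        raise ValueError("parents must have equal chromosome length")
    if len(b1) < cut_points + 1:
        raise ValueError(f"chromosome too short for {cut_points} cut points")
    cuts = np.sort(rng.choice(np.arange(1, len(b1)), size=cut_points, replace=False))
    c1, c2 = b1.copy(), b2.copy()
    swap = False
    bounds = [0, *cuts.tolist(), len(b1)]
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if swap:
            c1[lo:hi], c2[lo:hi] = b2[lo:hi], b1[lo:hi]
        swap = not swap
    return p1.split_like(c1), p2.split_like(c2)


def mutate(
    chrom: Chromosome,
    p: float,
    rng: np.random.Generator,
    mode: str = "per_individual",
) -> Chromosome:
    """Bit-flip mutation.

    ``per_individual`` (default): with probability p exactly one uniformly
    chosen bit flips.  ``per_bit``: every bit flips independently with
    probability p.
    """
    if not (0 <= p <= 1):
        raise ValueError("p must be in [0, 1]")
    bits = chrom.bits.copy()
    if mode == "per_individual":
        if rng.random() < p:
            i = rng.integers(len(bits))
            bits[i] ^= 1
    elif mode == "per_bit":
        flips = rng.random(len(bits)) < p
        bits[flips] ^= 1
    else:
        raise ValueError("mode must be 'per_individual' or 'per_bit'")
    return chrom.split_like(bits)


def run_ga(
    kind: str,
    training: FeatureTable,
    validation: FeatureTable,
    config: GaConfig | None = None,
) -> tuple[Chromosome, list[float]]:
    """Evolve a population; returns the best chromosome ever seen and the
    per-generation best-fitness history (element 0 = initial population)."""
    config = config or GaConfig()
    if len(training) == 0 or len(validation) == 0:
        raise ValueError("training and validation tables must be non-empty")
    if kind not in clf.CLASSIFIER_KINDS:
        raise ValueError(f"unknown classifier kind {kind!r}")
    rng = np.random.default_rng(config.seed)
    n_features = len(training.feature_names)
    n_param = clf.PARAM_BITS[kind]
    # tiny problems cannot host the full cut count
    n_cuts = min(config.crossover_cut_points, n_features + n_param - 1)
    cache: dict[bytes, float] = {}

    def evaluate(c: Chromosome) -> None:
        key = c.bits.tobytes()
        if key in cache:
            c.fitness = cache[key]
            return
        evaluate_fitness(c, kind, training, validation, seed=config.seed,
                         svm_gaussian_scale=config.svm_gaussian_scale,
                         fnn_max_iter=config.fnn_max_iter)
        cache[key] = c.fitness

    population = [
        Chromosome(rng.integers(0, 2, n_features, dtype=np.uint8),
                   rng.integers(0, 2, n_param, dtype=np.uint8))
        for _ in range(config.population_size)
    ]
    for c in population:
        evaluate(c)
    population.sort(key=lambda c: c.fitness)
    best = population[0].copy()
    history = [best.fitness]
    stall = 0

    for _ in range(config.max_iterations):
        parents = roulette_select(population, config.population_size, rng)
        children: list[Chromosome] = []
        for i in range(0, len(parents), 2):
            pa, pb = parents[i], parents[i + 1]
            if rng.random() < config.crossover_probability:
                ca, cb = crossover(pa, pb, rng, n_cuts)
            else:
                ca, cb = pa.copy(), pb.copy()
            children.append(mutate(ca, config.mutation_probability, rng,
                                   config.mutation_mode))
            children.append(mutate(cb, config.mutation_probability, rng,
                                   config.mutation_mode))
        for c in children:
            evaluate(c)
        pool = population + children
        pool.sort(key=lambda c: c.fitness)
        population = [c.copy() for c in pool[: config.population_size]]
        if population[0].fitness < best.fitness:
            best = population[0].copy()
            stall = 0
        else:
            stall += 1
        history.append(best.fitness)
        if stall >= config.plateau_patience:
            break
    return best, history


def selected_feature_names(chrom: Chromosome, feature_names: Sequence[str]) -> list[str]:
    return [n for n, b in zip(feature_names, chrom.feature_bits) if b]


class GASearchClassifier(BaseEstimator, ClassifierMixin):
    """sklearn-style estimator wrapping the GA wrapper search.

    ``fit(X, y)`` evolves feature masks and classifier parameters against
    a validation table (by default the training data itself; pass
    ``X_val``/``y_val`` for the study protocol where the validation pool
    contains all windows), then refits the winning configuration.

    Fitted attributes: ``best_chromosome_``, ``best_fitness_``,
    ``history_``, ``support_`` (boolean feature mask),
    ``selected_features_``, ``model_`` and ``classes_``.
    """

    def __init__(
        self,
        classifier: str = "svm",
        population_size: int = 40,
        max_iterations: int = 15,
        plateau_patience: int = 15,
        crossover_cut_points: int = 4,
        crossover_probability: float = 1.0,
        mutation_probability: float = 0.2,
        mutation_mode: str = "per_individual",
        svm_gaussian_scale: float = clf.DEFAULT_SVM_GAUSSIAN_SCALE,
        fnn_max_iter: int = clf.DEFAULT_FNN_MAX_ITER,
        random_state: int = 0,
    ):
        self.classifier = classifier
        self.population_size = population_size
        self.max_iterations = max_iterations
        self.plateau_patience = plateau_patience
        self.crossover_cut_points = crossover_cut_points
        self.crossover_probability = crossover_probability
        self.mutation_probability = mutation_probability
        self.mutation_mode = mutation_mode
        self.svm_gaussian_scale = svm_gaussian_scale
        self.fnn_max_iter = fnn_max_iter
        self.random_state = random_state

    def _config(self) -> GaConfig:
        return GaConfig(
            population_size=self.population_size,
            max_iterations=self.max_iterations,
            plateau_patience=self.plateau_patience,
            crossover_cut_points=self.crossover_cut_points,
            crossover_probability=self.crossover_probability,
            mutation_probability=self.mutation_probability,
            mutation_mode=self.mutation_mode,
            seed=self.random_state,
            svm_gaussian_scale=self.svm_gaussian_scale,
            fnn_max_iter=self.fnn_max_iter,
        )

    @staticmethod
    def _as_table(X, y) -> FeatureTable:
        if isinstance(X, FeatureTable):
            return X
        Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(
            np.asarray(X, dtype=float),
            columns=[f"f{i}" for i in range(np.asarray(X).shape[1])],
        )
        y = np.asarray(y, dtype=int)
        keys = pd.DataFrame({
            "subject": np.zeros(len(y), dtype=int),
            "activity": y,
            "repetition": np.zeros(len(y), dtype=int),
            "window": np.arange(len(y)),
        })[list(KEY_COLUMNS)]
        return FeatureTable(Xdf, y, keys)

    def fit(self, X, y=None, X_val=None, y_val=None):
        training = self._as_table(X, y)
        validation = training if X_val is None else self._as_table(X_val, y_val)
        best, history = run_ga(self.classifier, training, validation,
                               self._config())
        self.best_chromosome_ = best
        self.best_fitness_ = best.fitness
        self.history_ = history
        self.support_ = best.feature_bits.astype(bool)
        self.selected_features_ = selected_feature_names(
            best, training.feature_names)
        params = clf.decode_params(self.classifier, best.param_bits,
                                   len(training), len(self.selected_features_))
        self.decoded_params_ = params
        self.model_ = clf.train(
            self.classifier, params,
            training.select_features(self.selected_features_),
            seed=self.random_state,
            svm_gaussian_scale=self.svm_gaussian_scale,
            fnn_max_iter=self.fnn_max_iter,
        )
        self.classes_ = self.model_.classes
        self.n_features_in_ = len(training.feature_names)
        self.feature_names_in_ = np.array(training.feature_names)
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("fit must be called before predict")
        if isinstance(X, FeatureTable):
            table = X
        else:
            table = self._as_table(X, np.zeros(np.asarray(X).shape[0], dtype=int))
        return clf.predict(self.model_,
                           table.select_features(self.selected_features_))
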