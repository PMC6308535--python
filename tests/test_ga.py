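"""Genetic algorithm: fitness, operators, and full runs."""

import numpy as np
import pytest

from harsel.classifiers import PARAM_BITS
from harsel.ga import (WORST_FITNESS, Chromosome, GaConfig, GASearchClassifier,
                       crossover, evaluate_fitness, fitness_value, mutate,
                       roulette_select, run_ga)

from conftest import make_table


def chrom(feature_bits, param_bits=(), fitness=None):
    return Chromosome(np.array(feature_bits, dtype=np.uint8),
                      np.array(param_bits, dtype=np.uint8), fitness)


# ---------------------------------------------------------------------------
# fitness
# ---------------------------------------------------------------------------

def test_fitness_is_zero_at_perfect_balanced_accuracy():
    assert fitness_value(1.0, [1.0, 1.0, 1.0]) == 0.0


def test_fitness_combines_error_and_balance_penalty():
    assert fitness_value(0.9, [0.95, 0.9, 0.85]) == pytest.approx(0.13)


def test_fitness_penalty_vanishes_for_equal_activities():
    assert fitness_value(0.8, [0.8, 0.8]) == pytest.approx(0.20)


def test_all_zero_feature_mask_gets_worst_fitness_without_training():
    table = make_table(np.random.default_rng(0).normal(size=(10, 3)),
                       [3, 4] * 5)
    c = chrom([0, 0, 0])
    comp = evaluate_fitness(c, "dt", table, table)
    assert comp.fitness == WORST_FITNESS == 1.3
    assert c.fitness == WORST_FITNESS


def test_evaluate_fitness_trains_on_selected_columns_only():
    rng = np.random.default_rng(1)
    y = np.array([3] * 20 + [4] * 20)
    informative = np.where(y == 3, 0.0, 5.0) + rng.normal(0, 0.1, 40)
    noise = rng.normal(size=40)
    table = make_table(np.column_stack([informative, noise]), y)
    good = evaluate_fitness(chrom([1, 0]), "dt", table, table)
    assert good.fitness == 0.0
    assert good.acc == 1.0
    assert good.acc_activity == {3: 1.0, 4: 1.0}


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def test_better_fitness_has_higher_selection_probability():
    pop = [chrom([1], fitness=0.1), chrom([0], fitness=0.5)]
    rng = np.random.default_rng(0)
    picks = roulette_select(pop, 2000, rng)
    n_better = sum(1 for c in picks if c.fitness == 0.1)
    assert n_better > 1000


def test_equal_fitness_gives_uniform_selection():
    pop = [chrom([1], fitness=0.3), chrom([0], fitness=0.3)]
    rng = np.random.default_rng(1)
    picks = roulette_select(pop, 4000, rng)
    n_first = sum(1 for c in picks if c.feature_bits[0] == 1)
    assert abs(n_first - 2000) < 3 * np.sqrt(4000 * 0.25)


def test_empirical_selection_frequencies_match_weights():
    """Monte-Carlo check of the worst-minus-fitness weighting."""
    fits = [0.1, 0.2, 0.4]
    pop = [chrom([i], fitness=f) for i, f in enumerate(fits)]
    w = np.array([0.4 - f + 1e-9 for f in fits])
    w /= w.sum()
    rng = np.random.default_rng(2)
    n = 100_000
    picks = roulette_select(pop, n, rng)
    counts = np.bincount([c.feature_bits[0] for c in picks], minlength=3)
    for k in range(3):
        sigma = np.sqrt(n * w[k] * (1 - w[k]))
        assert abs(counts[k] - n * w[k]) < 3 * sigma


def test_empty_population_rejected():
    with pytest.raises(ValueError):
        roulette_select([], 1, np.random.default_rng(0))


# ---------------------------------------------------------------------------
# crossover / mutation
# ---------------------------------------------------------------------------

def test_crossover_conserves_total_bit_count():
    rng = np.random.default_rng(3)
    p1 = chrom([1] * 20, [1] * 5)
    p2 = chrom([0] * 20, [0] * 5)
    c1, c2 = crossover(p1, p2, rng)
    assert int(c1.bits.sum() + c2.bits.sum()) == 25
    assert len(c1.bits) == len(c2.bits) == 25


def test_crossover_of_identical_parents_returns_identical_children():
    rng = np.random.default_rng(4)
    p = chrom([1, 0, 1, 0, 1, 1, 0], [1, 0])
    c1, c2 = crossover(p, p, rng)
    assert np.array_equal(c1.bits, p.bits)
    assert np.array_equal(c2.bits, p.bits)


def test_every_child_bit_traces_to_exactly_one_parent():
    """Segment bookkeeping: at every position the two children carry the
    two parent bits (in one order or the other)."""
    rng = np.random.default_rng(5)
    for _ in range(50):
        b1 = rng.integers(0, 2, 30, dtype=np.uint8)
        b2 = rng.integers(0, 2, 30, dtype=np.uint8)
        p1, p2 = chrom(b1[:25], b1[25:]), chrom(b2[:25], b2[25:])
        c1, c2 = crossover(p1, p2, rng)
        for i in range(30):
            assert {c1.bits[i], c2.bits[i]} == {b1[i], b2[i]}


def test_too_short_chromosome_rejected():
    rng = np.random.default_rng(6)
    with pytest.raises(ValueError):
        crossover(chrom([1, 0]), chrom([0, 1]), rng)


def test_mutation_p0_is_identity_and_p1_flips_exactly_one_bit():
    rng = np.random.default_rng(7)
    c = chrom([1, 0, 1, 1, 0, 0], [1, 0])
    same = mutate(c, 0.0, rng)
    assert np.array_equal(same.bits, c.bits)
    for _ in range(20):
        flipped = mutate(c, 1.0, rng)
        assert int(np.sum(flipped.bits != c.bits)) == 1


def test_empirical_per_individual_mutation_rate():
    rng = np.random.default_rng(8)
    c = chrom([1] * 10)
    n = 10_000
    mutated = sum(
        1 for _ in range(n) if not np.array_equal(mutate(c, 0.2, rng).bits, c.bits)
    )
    assert abs(mutated / n - 0.2) < 0.02


def test_per_bit_mode_flips_bits_independently():
    rng = np.random.default_rng(9)
    c = chrom([0] * 1000)
    flipped = mutate(c, 0.2, rng, mode="per_bit").bits.sum()
    assert abs(flipped / 1000 - 0.2) < 0.05


# ---------------------------------------------------------------------------
# full runs
# ---------------------------------------------------------------------------

def _toy_tables(seed=0):
    """Two informative features, perfectly separable three-class problem."""
    rng = np.random.default_rng(seed)
    y = np.repeat([3, 4, 5], 20)
    X = np.column_stack([
        np.repeat([0.0, 5.0, 10.0], 20) + rng.normal(0, 0.2, 60),
        np.repeat([0.0, 5.0, 0.0], 20) + rng.normal(0, 0.2, 60),
    ])
    return make_table(X, y)


def test_ga_solves_separable_toy_problem_exactly():
    table = _toy_tables()
    config = GaConfig(population_size=8, max_iterations=3, plateau_patience=3,
                      seed=0)
    best, history = run_ga("dt", table, table, config)
    assert best.fitness == 0.0


def test_best_fitness_history_is_monotone_non_increasing():
    table = _toy_tables(1)
    config = GaConfig(population_size=8, max_iterations=5, plateau_patience=5,
                      seed=1)
    _, history = run_ga("knn", table, table, config)
    assert all(a >= b for a, b in zip(history[:-1], history[1:]))


def test_ga_is_seed_deterministic():
    table = _toy_tables(2)
    config = GaConfig(population_size=8, max_iterations=3, plateau_patience=3,
                      seed=7)
    b1, h1 = run_ga("dt", table, table, config)
    b2, h2 = run_ga("dt", table, table, config)
    assert np.array_equal(b1.bits, b2.bits)
    assert h1 == h2


def test_returned_fitness_matches_fresh_reevaluation():
    table = _toy_tables(3)
    config = GaConfig(population_size=8, max_iterations=3, plateau_patience=3,
                      seed=3)
    best, _ = run_ga("dt", table, table, config)
    fresh = evaluate_fitness(best.copy(), "dt", table, table, seed=config.seed)
    assert fresh.fitness == best.fitness


def test_chromosome_lengths_are_constant_and_decodable():
    table = _toy_tables(4)
    for kind in ("dt", "knn"):
        config = GaConfig(population_size=6, max_iterations=2,
                          plateau_patience=2, seed=4)
        best, _ = run_ga(kind, table, table, config)
        assert len(best.feature_bits) == 2
        assert len(best.param_bits) == PARAM_BITS[kind]


def test_config_validation():
    with pytest.raises(ValueError):
        GaConfig(population_size=5)  # odd
    with pytest.raises(ValueError):
        GaConfig(mutation_probability=1.5)
    with pytest.raises(ValueError):
        GaConfig(mutation_mode="sometimes")


def test_sklearn_estimator_wrapper_fit_predict():
    table = _toy_tables(5)
    est = GASearchClassifier(classifier="dt", population_size=8,
                             max_iterations=3, plateau_patience=3,
                             random_state=0)
    est.fit(table.X, table.y)
    assert est.best_fitness_ == 0.0
    assert est.support_.shape == (2,)
    pred = est.predict(table.X)
    assert np.mean(pred == table.y) == 1.0
    # params round-trip, sklearn-style
    assert est.get_params()["classifier"] == "dt"
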