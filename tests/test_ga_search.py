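"""The genetic search: sizing rules, operators, fitness, full runs."""

import numpy as np
import pytest

from gaeoc.ensemble_core import ConfusionMatrix, mcc
from gaeoc.folds_models import ClassifierSpec, FoldSplit, ModelStore
from gaeoc.ga_search import (EmptyEnsembleError, FitnessEvaluator, GAConfig,
                             Individual, decode_individual, evaluate_fitness,
                             exhaustive_best, mutate, mutation_rate,
                             next_generation, population_size, run_ga,
                             tournament_select, uniform_crossover)
from gaeoc.synthetic import gen_mock_pool, gen_planted_mock_pool


class TestSizingRules:
    @pytest.mark.parametrize("k,expected", [(20, 100), (2, 10), (1, 5)])
    def test_population_size(self, k, expected):
        assert population_size(k) == expected

    @pytest.mark.parametrize("n,expected", [(100, 0.01), (50, 0.02),
                                            (1000, 0.01)])
    def test_mutation_rate(self, n, expected):
        assert mutation_rate(n) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            population_size(0)
        with pytest.raises(ValueError):
            mutation_rate(0)


def _pool(k):
    return [ClassifierSpec(f"c{i}", "tree", {"algorithm": "tree"})
            for i in range(k)]


class TestDecode:
    def test_endpoints(self):
        bits = [1] + [0] * 18 + [1]
        spec = decode_individual(Individual(tuple(bits)), _pool(20))
        assert spec.member_ids == ("c0", "c19")

    def test_all_ones(self):
        spec = decode_individual(Individual((1,) * 5), _pool(5))
        assert spec.member_ids == tuple(f"c{i}" for i in range(5))

    def test_all_zero_rejected(self):
        with pytest.raises(EmptyEnsembleError):
            decode_individual(Individual((0, 0, 0)), _pool(3))


def _constant_store(per_fold_confusions, member="m0"):
    """Single-member store whose fold predictions realise given confusions.

    Each entry (tp, fp, tn, fn) builds one fold of tp+fp+tn+fn samples.
    """
    labels, val_preds, validation = [], {}, []
    offset = 0
    for f, (tp, fp, tn, fn) in enumerate(per_fold_confusions):
        y = [1] * tp + [0] * fp + [0] * tn + [1] * fn
        p = [1] * tp + [1] * fp + [0] * tn + [0] * fn
        n = len(y)
        labels.extend(y)
        val_preds[(member, f)] = np.array(p)
        validation.append(np.arange(offset, offset + n))
        offset += n
    folds = FoldSplit(n_folds=len(per_fold_confusions),
                      validation_indices=validation, seed=0)
    store = ModelStore(pool_ids=[member], n_folds=folds.n_folds,
                       val_predictions=val_preds,
                       labels=np.array(labels), dataset_hash="mock", seed=0)
    return store, folds, np.array(labels)


class TestEvaluateFitness:
    def test_perfect_member_scores_one(self):
        store, folds, labels = _constant_store([(5, 0, 5, 0)] * 10)
        fit = evaluate_fitness(Individual((1,)), store, folds, labels,
                               np.random.default_rng(0))
        assert fit == 1.0

    def test_mean_of_planted_fold_mccs(self):
        """Folds engineered to MCC 0.8 (x5) and 0.6 (x5) average to 0.7."""
        good = (9, 1, 9, 1)    # (81-1)/sqrt(10^4) = 0.8 on 20 samples
        fair = (8, 2, 8, 2)    # (64-4)/sqrt(10^4) = 0.6
        assert mcc(ConfusionMatrix(*good)) == pytest.approx(0.8)
        assert mcc(ConfusionMatrix(*fair)) == pytest.approx(0.6)
        store, folds, labels = _constant_store([good] * 5 + [fair] * 5)
        fit = evaluate_fitness(Individual((1,)), store, folds, labels,
                               np.random.default_rng(0))
        assert fit == pytest.approx(0.7)

    def test_memoized_equals_recompute(self):
        mp = gen_mock_pool(4, 16, 10, [0.25] * 4, correlation=0.5, seed=2)
        store, folds, labels = mp.to_store()
        ev = FitnessEvaluator(store, folds, labels, tie_seed=3)
        ind = Individual((1, 0, 1, 1))
        first = ev.evaluate(ind)
        again = ev.evaluate(ind)  # cache hit
        fresh = FitnessEvaluator(store, folds, labels, tie_seed=3).evaluate(ind)
        assert first == again == fresh

    def test_empty_individual_rejected(self):
        store, folds, labels = _constant_store([(2, 0, 2, 0)] * 3)
        with pytest.raises(EmptyEnsembleError):
            evaluate_fitness(Individual((0,)), store, folds, labels,
                             np.random.default_rng(0))


class TestOperators:
    def test_full_tournament_returns_global_best(self):
        pop = [Individual((1, 0)), Individual((0, 1)), Individual((1, 1))]
        fits = [0.2, 0.9, 0.5]
        rng = np.random.default_rng(0)
        for _ in range(5):
            assert tournament_select(pop, fits, 3, rng) is pop[1]

    def test_tournament_of_one_is_uniform(self):
        pop = [Individual((1, 0)), Individual((0, 1)), Individual((1, 1))]
        fits = [0.5, 0.5, 0.5]
        rng = np.random.default_rng(1)
        counts = {0: 0, 1: 0, 2: 0}
        for _ in range(3000):
            winner = tournament_select(pop, fits, 1, rng)
            counts[pop.index(winner)] += 1
        for c in counts.values():
            assert abs(c - 1000) < 150  # ~5 sigma for multinomial(3000, 1/3)

    def test_crossover_identical_parents(self):
        p = Individual((1, 0, 1, 1))
        rng = np.random.default_rng(2)
        child = uniform_crossover(p, p, 1.0, rng)
        assert child.bits == p.bits

    def test_crossover_rate_zero_copies_fitter(self):
        p1, p2 = Individual((1, 1, 1)), Individual((0, 0, 1))
        rng = np.random.default_rng(3)
        assert uniform_crossover(p1, p2, 0.0, rng, f1=0.2, f2=0.9).bits == p2.bits
        assert uniform_crossover(p1, p2, 0.0, rng, f1=0.9, f2=0.2).bits == p1.bits

    def test_crossover_mixes_bits_evenly(self):
        """Complementary parents at rate 1: each bit ~50/50 per parent."""
        k = 10
        p1 = Individual((1,) * k)
        p2 = Individual((0,) * k)
        rng = np.random.default_rng(4)
        totals = np.zeros(k)
        trials = 4000
        for _ in range(trials):
            totals += uniform_crossover(p1, p2, 1.0, rng).as_array()
        np.testing.assert_allclose(totals / trials, 0.5, atol=0.05)

    def test_mutate_rate_zero_identity(self):
        ind = Individual((1, 0, 1))
        assert mutate(ind, 0.0, np.random.default_rng(5)).bits == ind.bits

    def test_mutate_rate_one_expected_hamming_half(self):
        """Replacement redraws bits, so rate 1 moves ~k/2 bits on average."""
        k = 20
        ind = Individual((1,) * k)
        rng = np.random.default_rng(6)
        distances = [sum(a != b for a, b in
                         zip(mutate(ind, 1.0, rng).bits, ind.bits))
                     for _ in range(2000)]
        assert np.mean(distances) == pytest.approx(k / 2, rel=0.05)

    def test_mutation_repairs_all_zero(self):
        ind = Individual((0, 0, 0, 1))
        for s in range(50):
            out = mutate(ind, 1.0, np.random.default_rng(s))
            assert sum(out.bits) >= 1


class TestNextGeneration:
    def _setup(self, k=4, seed=0):
        mp = gen_mock_pool(k, 16, 10, [0.3] * k, seed=seed)
        store, folds, labels = mp.to_store()
        ev = FitnessEvaluator(store, folds, labels)
        rng = np.random.default_rng(seed)
        pop = [Individual(tuple(rng.integers(0, 2, k))) for _ in range(8)]
        pop = [p if p.n_selected else Individual((1,) + (0,) * (k - 1))
               for p in pop]
        fits = [ev.evaluate(p) for p in pop]
        return pop, fits, ev

    def test_elite_is_promoted_verbatim(self):
        pop, fits, _ = self._setup()
        config = GAConfig(pool_size=4, population_size=8, tournament_size=4)
        new = next_generation(pop, fits, config, np.random.default_rng(1))
        assert len(new) == len(pop)
        assert new[0].bits == pop[int(np.argmax(fits))].bits

    def test_no_variation_stays_in_genotype_pool(self):
        pop, fits, _ = self._setup(seed=2)
        config = GAConfig(pool_size=4, population_size=8, tournament_size=4,
                          crossover_rate=0.0, mutation_rate_value=0.0)
        new = next_generation(pop, fits, config, np.random.default_rng(2))
        existing = {p.bits for p in pop}
        assert all(ind.bits in existing for ind in new)

    def test_seeded_replay_identical(self):
        pop, fits, _ = self._setup(seed=3)
        config = GAConfig(pool_size=4, population_size=8, tournament_size=4)
        g1 = next_generation(pop, fits, config, np.random.default_rng(7))
        g2 = next_generation(pop, fits, config, np.random.default_rng(7))
        assert [a.bits for a in g1] == [b.bits for b in g2]


class TestRunGA:
    def test_perfect_member_triggers_optimum(self):
        store, folds, labels = _constant_store([(5, 0, 5, 0)] * 10)
        config = GAConfig(pool_size=1, population_size=4, tournament_size=2,
                          elite_count=1, seed=0)
        result = run_ga(config, store, folds, labels)
        assert result.termination_reason == "optimum"
        assert result.best_fitness == 1.0
        assert result.per_fold_mcc == [1.0] * 10

    def test_matches_exhaustive_oracle_on_planted_pool(self):
        mp = gen_planted_mock_pool(8, seed=42)
        store, folds, labels = mp.to_store()
        config = GAConfig(pool_size=8, seed=7)
        result = run_ga(config, store, folds, labels)
        best, best_fit = exhaustive_best(store, folds, labels, tie_seed=0)
        assert result.best_fitness == pytest.approx(best_fit, abs=1e-12)
        assert best_fit == pytest.approx(mp.true_best_fitness, abs=1e-12)

    def test_flat_landscape_stops_by_stagnation(self):
        """All-identical members: every mask has equal fitness; stop at <= 51."""
        store, folds, labels = _constant_store([(3, 2, 3, 2)] * 10)
        config = GAConfig(pool_size=1, population_size=4, tournament_size=2,
                          stagnation_limit=50, seed=1)
        result = run_ga(config, store, folds, labels)
        assert result.termination_reason == "stagnation"
        assert result.generations_run <= 51

    def test_history_non_decreasing_and_replay_identical(self):
        mp = gen_mock_pool(6, 20, 10, [0.2, 0.3, 0.25, 0.35, 0.3, 0.4],
                           correlation=0.3, seed=9)
        store, folds, labels = mp.to_store()
        config = GAConfig(pool_size=6, seed=11)
        r1 = run_ga(config, store, folds, labels)
        r2 = run_ga(GAConfig(pool_size=6, seed=11), store, folds, labels)
        hist = np.array(r1.fitness_history)
        assert (np.diff(hist) >= -1e-15).all()
        assert r1.best.bits == r2.best.bits
        assert r1.fitness_history == r2.fitness_history
        assert r1.best_fitness == pytest.approx(np.mean(r1.per_fold_mcc))

    def test_evaluation_budget(self):
        mp = gen_mock_pool(6, 20, 10, [0.3] * 6, seed=13)
        store, folds, labels = mp.to_store()
        config = GAConfig(pool_size=6, seed=2)
        result = run_ga(config, store, folds, labels)
        budget = config.population_size * (result.generations_run + 1)
        assert result.n_evaluations <= min(budget, 2**6 - 1)
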