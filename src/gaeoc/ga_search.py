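"""Genetic-algorithm search over k-bit ensemble masks.

Each individual is a k-bit vector; bit i selects classifier i of the pool.
Fitness is the mean MCC of the decoded ensemble's majority vote over the
cross-validation folds, read from cached validation predictions — never a
retraining.  The search uses tournament selection (pool of 10), uniform
crossover at rate 0.60, random-bit-replacement mutation at max(0.01, 1/n),
single-individual elitism, and stops at 1000 generations, 50 stagnant
generations, or a perfect fitness of 1.0.

Population sizing follows min(5k, 12·2^k) — 100 individuals for the
default 20-classifier pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .ensemble_core import (ConfusionMatrix, EnsembleSpec, confusion,
                            ensemble_predict, mcc)
from .folds_models import ClassifierSpec, FoldSplit, ModelStore


class EmptyEnsembleError(ValueError):
    """An all-zero individual decodes to an empty (undefined) ensemble."""


@dataclass(frozen=True)
class Individual:
    """A fixed-length bitmask over the classifier pool."""

    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if not all(b in (0, 1) for b in self.bits):
            raise ValueError("bits must be 0/1")

    @classmethod
    def from_array(cls, arr) -> "Individual":
        return cls(tuple(int(b) for b in np.asarray(arr).ravel()))

    @property
    def k(self) -> int:
        return len(self.bits)

    @property
    def n_selected(self) -> int:
        return sum(self.bits)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.bits, dtype=np.int8)

    def mask_int(self) -> int:
        """Bit 0 of the pool = least-significant bit."""
        return int(sum(b << i for i, b in enumerate(self.bits)))

    def __str__(self) -> str:
        return "".join(str(b) for b in self.bits)


@dataclass
class GAConfig:
    """Search settings; all defaults are the study's standard values."""

    pool_size: int
    population_size: int | None = None      # default: min(5k, 12*2^k)
    crossover_rate: float = 0.60
    mutation_rate_value: float | None = None  # default: max(0.01, 1/pop)
    tournament_size: int = 10
    elite_count: int = 1
    max_generations: int = 1000
    stagnation_limit: int = 50
    optimum_fitness: float = 1.0
    seed: int = 0
    tie_seed: int = 0                       # vote-tie stream; independent of seed
    crossover_mode: str = "per_mating"      # or "per_gene"

    def __post_init__(self) -> None:
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        if self.population_size is None:
            self.population_size = population_size(self.pool_size)
        if self.mutation_rate_value is None:
            self.mutation_rate_value = mutation_rate(self.population_size)
        if not 0.0 <= self.crossover_rate <= 1.0:
            raise ValueError("crossover_rate must lie in [0, 1]")
        if not 0.0 <= self.mutation_rate_value <= 1.0:
            raise ValueError("mutation rate must lie in [0, 1]")
        if self.tournament_size > self.population_size:
            raise ValueError("tournament_size cannot exceed population_size")
        if self.elite_count >= self.population_size:
            raise ValueError("elite_count must be smaller than population_size")
        if self.crossover_mode not in ("per_mating", "per_gene"):
            raise ValueError(f"unknown crossover_mode {self.crossover_mode!r}")


@dataclass
class GAResult:
    """Outcome of one search run."""

    best: Individual
    best_fitness: float
    per_fold_mcc: list[float]
    generations_run: int
    fitness_history: list[float]            # best-so-far, one per generation
    termination_reason: str                 # max_generations|stagnation|optimum
    n_evaluations: int = 0


def population_size(k: int) -> int:
    """Population sizing rule: min(5k, 12·2^k).  k=20 gives 100."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return min(5 * k, 12 * 2**k)


def mutation_rate(n: int) -> float:
    """Mutation-rate rule: max(0.01, 1/n) for population size n."""
    if n < 1:
        raise ValueError("population size must be >= 1")
    return max(0.01, 1.0 / n)


def decode_individual(ind: Individual, pool: list[ClassifierSpec]) -> EnsembleSpec:
    """Map set bits to pool members, preserving pool order."""
    if ind.k != len(pool):
        raise ValueError(f"individual length {ind.k} != pool size {len(pool)}")
    members = tuple(pool[i].id for i, b in enumerate(ind.bits) if b)
    if not members:
        raise EmptyEnsembleError("all-zero individual selects no classifiers")
    return EnsembleSpec(member_ids=members)


def evaluate_fitness(ind: Individual, store: ModelStore, folds: FoldSplit,
                     labels: np.ndarray, tie_rng: np.random.Generator) -> float:
    """Mean per-fold MCC of the individual's ensemble (the fitness function).

    For each fold, the members' cached validation predictions are fused by
    majority vote and scored against that fold's validation labels; the
    fitness is the arithmetic mean over folds.
    """
    return _fitness_with_folds(ind, store, folds, labels, tie_rng)[0]


def _fitness_with_folds(ind, store, folds, labels, tie_rng):
    if ind.n_selected == 0:
        raise EmptyEnsembleError("cannot evaluate an empty ensemble")
    member_idx = [i for i, b in enumerate(ind.bits) if b]
    member_ids = [store.pool_ids[i] for i in member_idx]
    for m in member_ids:
        for f in range(folds.n_folds):
            if (m, f) not in store.val_predictions:
                raise ValueError(f"store is missing predictions for {(m, f)}")
    spec = EnsembleSpec(member_ids=tuple(member_ids))
    labels = np.asarray(labels)
    per_fold = []
    for f in range(folds.n_folds):
        val_idx = folds.validation_indices[f]
        preds = {m: store.val_predictions[(m, f)] for m in member_ids}
        fused = ensemble_predict(spec, preds, tie_rng)
        per_fold.append(mcc(confusion(labels[val_idx], fused)))
    return float(np.mean(per_fold)), per_fold


class FitnessEvaluator:
    """Memoized fitness with per-mask derived tie streams.

    The tie RNG for a mask is seeded from (tie_seed, mask_int), which makes
    the fitness a pure function of (store, mask, tie_seed): a cache hit is
    identical to a recomputation, and independent enumerations (e.g. the
    exhaustive oracle) can reproduce the exact same values.
    """

    def __init__(self, store: ModelStore, folds: FoldSplit,
                 labels: np.ndarray, tie_seed: int = 0):
        self.store = store
        self.folds = folds
        self.labels = np.asarray(labels)
        self.tie_seed = tie_seed
        self._cache: dict[tuple[int, ...], tuple[float, list[float]]] = {}
        self.n_evaluations = 0
        # per-fold (k, n_fold) prediction matrices in pool order, for the
        # vectorised path; semantics identical to evaluate_fitness()
        self._fold_preds = []
        self._fold_labels = []
        for f in range(folds.n_folds):
            self._fold_preds.append(np.stack(
                [np.asarray(store.val_predictions[(m, f)], dtype=np.int64)
                 for m in store.pool_ids], axis=0))
            self._fold_labels.append(self.labels[folds.validation_indices[f]])

    def tie_rng_for(self, ind: Individual) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([self.tie_seed, ind.mask_int()]))

    def evaluate(self, ind: Individual) -> float:
        return self.evaluate_with_folds(ind)[0]

    def evaluate_with_folds(self, ind: Individual) -> tuple[float, list[float]]:
        key = ind.bits
        if key not in self._cache:
            self.n_evaluations += 1
            self._cache[key] = self._evaluate_uncached(ind)
        return self._cache[key]

    def _evaluate_uncached(self, ind: Individual):
        if ind.n_selected == 0:
            raise EmptyEnsembleError("cannot evaluate an empty ensemble")
        sel = np.flatnonzero(ind.as_array())
        k = sel.size
        tie_rng = self.tie_rng_for(ind)
        per_fold = []
        for f in range(self.folds.n_folds):
            pos = self._fold_preds[f][sel].sum(axis=0)
            fused = np.where(2 * pos > k, 1, 0)
            ties = np.flatnonzero(2 * pos == k)
            if ties.size:
                fused[ties] = tie_rng.integers(0, 2, size=ties.size)
            y = self._fold_labels[f]
            tp = int(((y == 1) & (fused == 1)).sum())
            fp = int(((y == 0) & (fused == 1)).sum())
            tn = int(((y == 0) & (fused == 0)).sum())
            fn = int(((y == 1) & (fused == 0)).sum())
            per_fold.append(mcc(ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)))
        return float(np.mean(per_fold)), per_fold


def tournament_select(population: list[Individual], fitnesses,
                      tournament_size: int, rng: np.random.Generator) -> Individual:
    """Fittest of ``tournament_size`` distinct uniform draws (ties: lowest index)."""
    if not population:
        raise ValueError("empty population")
    if tournament_size > len(population):
        raise ValueError("tournament larger than population")
    fitnesses = np.asarray(fitnesses, dtype=float)
    entrants = rng.choice(len(population), size=tournament_size, replace=False)
    entrants = np.sort(entrants)  # ties resolve to the lowest population index
    winner = entrants[int(np.argmax(fitnesses[entrants]))]
    return population[int(winner)]


def uniform_crossover(p1: Individual, p2: Individual, rate: float,
                      rng: np.random.Generator,
                      f1: float = 0.0, f2: float = 0.0,
                      mode: str = "per_mating") -> Individual:
    """Uniform crossover at the given rate; one offspring per mating.

    ``per_mating`` (default): with probability ``rate`` the offspring takes
    each bit from either parent with probability 1/2; otherwise it is a copy
    of the fitter parent.  ``per_gene``: each bit independently comes from a
    random parent with probability ``rate`` and from the fitter parent
    otherwise.  Fitness ties favour p1.
    """
    if p1.k != p2.k:
        raise ValueError("parent lengths differ")
    fitter = p1 if f1 >= f2 else p2
    if mode == "per_mating":
        if rng.random() >= rate:
            return fitter
        take_p1 = rng.integers(0, 2, size=p1.k).astype(bool)
        bits = np.where(take_p1, p1.as_array(), p2.as_array())
        return Individual.from_array(bits)
    if mode == "per_gene":
        mix = rng.random(p1.k) < rate
        take_p1 = rng.integers(0, 2, size=p1.k).astype(bool)
        random_parent = np.where(take_p1, p1.as_array(), p2.as_array())
        bits = np.where(mix, random_parent, fitter.as_array())
        return Individual.from_array(bits)
    raise ValueError(f"unknown crossover mode {mode!r}")


def _repair(bits: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Ensure at least one bit is set (an empty ensemble is undefined)."""
    if bits.sum() == 0:
        bits = bits.copy()
        bits[int(rng.integers(0, bits.size))] = 1
    return bits


def mutate(ind: Individual, rate: float, rng: np.random.Generator) -> Individual:
    """Random bit replacement: each bit is redrawn uniformly w.p. ``rate``.

    Note the replacement draw may reproduce the old value, so at rate 1 the
    expected Hamming distance is k/2, not k.  An all-zero result is repaired
    by setting one uniformly chosen bit.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("mutation rate must lie in [0, 1]")
    bits = ind.as_array().copy()
    hit = rng.random(ind.k) < rate
    replacements = rng.integers(0, 2, size=ind.k)
    bits[hit] = replacements[hit]
    return Individual.from_array(_repair(bits, rng))


def next_generation(population: list[Individual], fitnesses,
                    config: GAConfig, rng: np.random.Generator) -> list[Individual]:
    """Elites + (tournament x2 -> crossover -> mutation -> repair) offspring."""
    fitnesses = np.asarray(fitnesses, dtype=float)
    n = len(population)
    # stable elite order: by descending fitness, ties towards the lowest index
    elite_order = sorted(range(n), key=lambda i: (-fitnesses[i], i))
    new_pop = [population[i] for i in elite_order[:config.elite_count]]

    fit_by_id = {id(population[i]): fitnesses[i] for i in range(n)}
    while len(new_pop) < n:
        p1 = tournament_select(population, fitnesses, config.tournament_size, rng)
        p2 = tournament_select(population, fitnesses, config.tournament_size, rng)
        child = uniform_crossover(
            p1, p2, config.crossover_rate, rng,
            f1=fit_by_id[id(p1)], f2=fit_by_id[id(p2)],
            mode=config.crossover_mode)
        child = mutate(child, config.mutation_rate_value, rng)
        new_pop.append(child)
    return new_pop


def _initial_population(config: GAConfig, rng: np.random.Generator):
    pop = []
    for _ in range(config.population_size):
        bits = rng.integers(0, 2, size=config.pool_size)
        pop.append(Individual.from_array(_repair(bits, rng)))
    return pop


def run_ga(config: GAConfig, store: ModelStore, folds: FoldSplit,
           labels: np.ndarray) -> GAResult:
    """Run the full search and return the fittest individual ever seen.

    Terminates on whichever comes first: a perfect fitness (optimum), no
    improvement of the best fitness for ``stagnation_limit`` consecutive
    generations, or ``max_generations`` generations.  The fitness history
    records the best-so-far value per generation and is non-decreasing by
    elitism.
    """
    if len(store.pool_ids) != config.pool_size:
        raise ValueError("config.pool_size does not match the store's pool")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    evaluator = FitnessEvaluator(store, folds, labels, tie_seed=config.tie_seed)

    population = _initial_population(config, rng)
    best_ind: Individual | None = None
    best_fit = -np.inf
    history: list[float] = []
    stagnant = 0
    reason = "max_generations"
    generation = 0

    while True:
        generation += 1
        fitnesses = [evaluator.evaluate(ind) for ind in population]
        gen_best = int(np.argmax(fitnesses))
        improved = fitnesses[gen_best] > best_fit + 1e-12
        if improved:
            best_fit = fitnesses[gen_best]
            best_ind = population[gen_best]
            stagnant = 0
        else:
            stagnant += 1
        history.append(best_fit)

        if best_fit >= config.optimum_fitness - 1e-12:
            reason = "optimum"
            break
        if stagnant >= config.stagnation_limit:
            reason = "stagnation"
            break
        if generation >= config.max_generations:
            reason = "max_generations"
            break
        population = next_generation(population, fitnesses, config, rng)

    _, per_fold = evaluator.evaluate_with_folds(best_ind)
    return GAResult(
        best=best_ind,
        best_fitness=best_fit,
        per_fold_mcc=[float(v) for v in per_fold],
        generations_run=generation,
        fitness_history=history,
        termination_reason=reason,
        n_evaluations=evaluator.n_evaluations,
    )


def exhaustive_best(store: ModelStore, folds: FoldSplit, labels: np.ndarray,
                    tie_seed: int = 0) -> tuple[Individual, float]:
    """Enumerate all 2^k - 1 non-empty masks; the oracle the GA is tested against.

    Uses the same per-mask tie-stream convention as :class:`FitnessEvaluator`
    so fitness values are directly comparable.  Ties on fitness go to the
    lowest mask integer.
    """
    k = len(store.pool_ids)
    if k > 16:
        raise ValueError("exhaustive enumeration capped at k = 16")
    evaluator = FitnessEvaluator(store, folds, labels, tie_seed=tie_seed)
    best_mask, best_fit = None, -np.inf
    for mask in range(1, 2**k):
        ind = Individual(tuple((mask >> i) & 1 for i in range(k)))
        fit = evaluator.evaluate(ind)
        if fit > best_fit + 1e-12:
            best_mask, best_fit = ind, fit
    return best_mask, float(best_fit)


def config_from_dict(d: dict) -> GAConfig:
    """Build a GAConfig from a plain dict (e.g. parsed YAML)."""
    return GAConfig(**d)


def config_replace(config: GAConfig, **kw) -> GAConfig:
    return replace(config, **kw)
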