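"""Synthetic data generators: Gaussian tables and planted mock pools.

Three generators make the whole pipeline testable with no downloads:

* :func:`gen_imbalanced_gaussian` — two spherical Gaussian classes with a
  controllable mean separation and imbalance ratio, emulating the
  imbalanced binary feature tables of the study datasets.
* :func:`gen_mock_pool` — a pool of "classifiers" given directly as fixed
  per-fold validation predictions with chosen marginal error rates and a
  shared-latent error correlation.  Because the predictions are fixed,
  ensemble fitness is exactly computable and the optimal subset is known
  by exhaustive enumeration — the ground truth the search is tested
  against.
* :func:`gen_toy_abk_instance` — a tiny discrete dataset whose minimum
  (α,β)-feasible feature set is certified by enumeration.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataio import Dataset
from .featsel import ABKConfig, DiscreteDataset, ab_k_select
from .folds_models import FoldSplit, ModelStore
from .ga_search import Individual, exhaustive_best


@dataclass
class MockPool:
    """A fixed-prediction classifier pool with a certified optimal subset."""

    k: int
    member_ids: list[str]
    per_fold_val_predictions: dict[tuple[str, int], np.ndarray]
    labels_per_fold: list[np.ndarray]
    true_best_mask: Individual
    true_best_fitness: float
    tie_seed: int = 0

    def to_store(self) -> tuple[ModelStore, FoldSplit, np.ndarray]:
        """Assemble the ModelStore/FoldSplit/labels triple the GA consumes."""
        n_folds = len(self.labels_per_fold)
        sizes = [v.size for v in self.labels_per_fold]
        offsets = np.concatenate([[0], np.cumsum(sizes)])
        validation = [np.arange(offsets[f], offsets[f + 1])
                      for f in range(n_folds)]
        folds = FoldSplit(n_folds=n_folds, validation_indices=validation, seed=0)
        labels = np.concatenate(self.labels_per_fold)
        store = ModelStore(
            pool_ids=list(self.member_ids),
            n_folds=n_folds,
            val_predictions=dict(self.per_fold_val_predictions),
            labels=labels,
            dataset_hash="mock",
            seed=0,
        )
        return store, folds, labels


def gen_imbalanced_gaussian(n_minority: int, n_majority: int,
                            n_features: int, separation: float,
                            seed: int = 0) -> Dataset:
    """Two spherical unit-variance Gaussians with mean distance ``separation``.

    Label 1 is the minority class.  Rows are shuffled (seeded) so class
    blocks are interleaved as in real tables.
    """
    if n_minority < 1 or n_majority < 1:
        raise ValueError("class counts must be >= 1")
    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = np.random.default_rng(seed)
    shift = separation / np.sqrt(n_features)
    X_maj = rng.standard_normal((n_majority, n_features))
    X_min = rng.standard_normal((n_minority, n_features)) + shift
    X = np.vstack([X_maj, X_min])
    y = np.concatenate([np.zeros(n_majority, dtype=int),
                        np.ones(n_minority, dtype=int)])
    order = rng.permutation(X.shape[0])
    return Dataset(
        features=X[order],
        labels=y[order],
        feature_names=[f"f{j}" for j in range(n_features)],
        name=f"gauss(sep={separation},min={n_minority},maj={n_majority})",
    )


def gen_mock_pool(k: int, n_per_fold: int, n_folds: int,
                  member_error_rates, correlation=0.0,
                  seed: int = 0, tie_seed: int = 0) -> MockPool:
    """Fixed-prediction pool with planted error rates and error correlation.

    Each member i errs on a sample with marginal probability
    ``member_error_rates[i]``.  Correlation is induced by a shared latent
    uniform draw per sample: with probability ``correlation`` (scalar or
    per-member) a member consults the shared draw instead of its own, so
    correlated members tend to err on the same samples while marginal rates
    are preserved.  The true best mask/fitness are found by enumerating all
    2^k - 1 subsets with the same evaluator the GA uses.
    """
    if k > 16:
        raise ValueError("k capped at 16 for exhaustive certification")
    error_rates = np.asarray(member_error_rates, dtype=float)
    if error_rates.shape != (k,):
        raise ValueError("member_error_rates must have length k")
    if ((error_rates < 0) | (error_rates > 1)).any():
        raise ValueError("error rates must lie in [0, 1]")
    corr = np.broadcast_to(np.asarray(correlation, dtype=float), (k,))

    rng = np.random.default_rng(seed)
    member_ids = [f"m{i}" for i in range(k)]
    labels_per_fold, predictions = [], {}
    for f in range(n_folds):
        labels = (np.arange(n_per_fold) % 2).astype(int)
        labels = rng.permutation(labels)
        labels_per_fold.append(labels)
        shared = rng.random(n_per_fold)
        for i in range(k):
            own = rng.random(n_per_fold)
            use_shared = rng.random(n_per_fold) < corr[i]
            draw = np.where(use_shared, shared, own)
            err = draw < error_rates[i]
            predictions[(member_ids[i], f)] = np.where(err, 1 - labels, labels)

    pool = MockPool(
        k=k,
        member_ids=member_ids,
        per_fold_val_predictions=predictions,
        labels_per_fold=labels_per_fold,
        true_best_mask=Individual(tuple([1] + [0] * (k - 1))),  # placeholder
        true_best_fitness=0.0,
        tie_seed=tie_seed,
    )
    store, folds, labels = pool.to_store()
    best, fitness = exhaustive_best(store, folds, labels, tie_seed=tie_seed)
    pool.true_best_mask = best
    pool.true_best_fitness = fitness
    return pool


def gen_planted_mock_pool(k: int, seed: int = 0, planted_size: int = 5,
                          n_per_fold: int = 30, n_folds: int = 10,
                          distractor_error: float = 0.35,
                          distractor_correlation: float = 0.9,
                          tie_seed: int = 0) -> MockPool:
    """Pool with a planted diverse subset that forms the best ensemble.

    The first ``planted_size`` members (odd, >= 3) err on a 2-sample common
    block per fold plus 2 member-specific samples from pairwise disjoint
    blocks, so the majority vote of the planted members errs on exactly the
    common block — a high, flat optimum with a clear fitness gap.  The
    remaining members are high-error and strongly correlated with each
    other, so they cannot combine into anything competitive.  The optimum
    is still certified by full enumeration, never assumed.
    """
    if planted_size % 2 == 0 or planted_size < 3:
        raise ValueError("planted_size must be odd and >= 3")
    if k <= planted_size:
        raise ValueError("k must exceed planted_size")
    if n_per_fold < 2 + 2 * planted_size:
        raise ValueError("n_per_fold too small for disjoint error blocks")
    if k > 16:
        raise ValueError("k capped at 16 for exhaustive certification")
    rng = np.random.default_rng(seed)
    member_ids = [f"m{i}" for i in range(k)]
    labels_per_fold, predictions = [], {}
    for f in range(n_folds):
        labels = rng.permutation((np.arange(n_per_fold) % 2).astype(int))
        labels_per_fold.append(labels)
        samples = rng.permutation(n_per_fold)
        common = samples[:2]
        for i in range(planted_size):
            own = samples[2 + 2 * i: 4 + 2 * i]
            errs = np.concatenate([common, own])
            pred = labels.copy()
            pred[errs] = 1 - pred[errs]
            predictions[(member_ids[i], f)] = pred
        shared = rng.random(n_per_fold)
        for i in range(planted_size, k):
            own_draw = rng.random(n_per_fold)
            use_shared = rng.random(n_per_fold) < distractor_correlation
            draw = np.where(use_shared, shared, own_draw)
            err = draw < distractor_error
            predictions[(member_ids[i], f)] = np.where(err, 1 - labels, labels)

    pool = MockPool(
        k=k,
        member_ids=member_ids,
        per_fold_val_predictions=predictions,
        labels_per_fold=labels_per_fold,
        true_best_mask=Individual(tuple([1] * planted_size
                                        + [0] * (k - planted_size))),
        true_best_fitness=0.0,
        tie_seed=tie_seed,
    )
    store, folds, labels = pool.to_store()
    best, fitness = exhaustive_best(store, folds, labels, tie_seed=tie_seed)
    pool.true_best_mask = best
    pool.true_best_fitness = fitness
    return pool


def gen_redundant_strong_pool(seed: int = 0, n_per_fold: int = 20,
                              n_folds: int = 10, tie_seed: int = 0) -> MockPool:
    """A pool where the best single member is absent from the best ensemble.

    Member 0 ("strong") has the highest individual accuracy (2 errors per
    fold vs 4 for each weak member), but its two errors land inside two
    *different* weak members' error sets, so every committee that includes
    it errs or ties somewhere.  Members 1-3 ("weak") err on pairwise
    disjoint samples, so their three-way majority vote is error-free: the
    unique exhaustive optimum is {weak_a, weak_b, weak_c} with fitness
    exactly 1.0 — diversity beats the strongest individual.
    """
    if n_per_fold < 12:
        raise ValueError("n_per_fold must be >= 12 to place disjoint errors")
    rng = np.random.default_rng(seed)
    member_ids = ["strong", "weak_a", "weak_b", "weak_c"]
    labels_per_fold, predictions = [], {}
    for f in range(n_folds):
        labels = rng.permutation((np.arange(n_per_fold) % 2).astype(int))
        labels_per_fold.append(labels)
        samples = rng.permutation(n_per_fold)
        err_sets = {
            "weak_a": samples[0:4],
            "weak_b": samples[4:8],
            "weak_c": samples[8:12],
            # one error shared with weak_a, one with weak_b
            "strong": samples[[0, 4]],
        }
        for member, errs in err_sets.items():
            pred = labels.copy()
            pred[errs] = 1 - pred[errs]
            predictions[(member, f)] = pred

    pool = MockPool(
        k=4,
        member_ids=member_ids,
        per_fold_val_predictions=predictions,
        labels_per_fold=labels_per_fold,
        true_best_mask=Individual((0, 1, 1, 1)),
        true_best_fitness=1.0,
        tie_seed=tie_seed,
    )
    store, folds, labels = pool.to_store()
    best, fitness = exhaustive_best(store, folds, labels, tie_seed=tie_seed)
    pool.true_best_mask = best
    pool.true_best_fitness = fitness
    return pool


@dataclass
class ToyABKInstance:
    """A small discrete instance with an enumeration-certified minimum set."""

    dataset: DiscreteDataset
    alpha: int
    beta: int
    minimum_set: set[int]
    minimum_cardinality: int


def gen_toy_abk_instance(seed: int = 0, alpha: int = 2, beta: int = 0,
                         n_samples: int = 6, n_features: int = 5,
                         ) -> ToyABKInstance:
    """Random small binary-code instance, regenerated until (α,β)-feasible.

    The certified minimum is recomputed here by the exhaustive solver; test
    suites should re-derive it independently rather than trust the fixture.
    """
    rng = np.random.default_rng(seed)
    labels = (np.arange(n_samples) % 2).astype(int)
    for _ in range(200):
        codes = rng.integers(0, 2, size=(n_samples, n_features))
        dd = DiscreteDataset(
            codes=codes,
            labels=labels,
            cutpoints=[np.array([0.5])] * n_features,
            kept_features=list(range(n_features)),
            feature_names=[f"f{j}" for j in range(n_features)],
        )
        try:
            exact = ab_k_select(dd, ABKConfig(alpha=alpha, beta=beta,
                                              solver="exhaustive"))
        except ValueError:
            continue
        return ToyABKInstance(
            dataset=dd,
            alpha=alpha,
            beta=beta,
            minimum_set=exact,
            minimum_cardinality=len(exact),
        )
    raise RuntimeError("could not generate a feasible instance")
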