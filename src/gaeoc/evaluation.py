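"""Final-ensemble evaluation and the repeated-runs protocol.

After the search picks a bitmask, its members are retrained on the *full*
training set and the majority-vote ensemble is scored once on held-out test
data.  Because the search is stochastic, experiments are repeated across
seeds and summarised by mean/stdev and the number of distinct winning
ensembles.  Off-the-shelf ensemble baselines (bagging, AdaBoost, random
forest) are called from scikit-learn for comparison, never re-derived.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import (AdaBoostClassifier, BaggingClassifier,
                              RandomForestClassifier)

from .dataio import DataError, Dataset
from .ensemble_core import (ConfusionMatrix, EnsembleSpec, MetricsRecord,
                            confusion, ensemble_predict, metrics)
from .folds_models import ClassifierSpec, FoldSplit, ModelStore, \
    _task_seed, build_estimator
from .ga_search import GAConfig, GAResult, Individual, config_replace, \
    decode_individual, run_ga


@dataclass
class RunSummary:
    """Aggregate of repeated search+test runs."""

    per_run: list[dict]
    mean_mcc: float
    stdev_mcc: float
    mean_accuracy: float
    stdev_accuracy: float
    n_distinct_ensembles: int

    def recompute(self) -> "RunSummary":
        """Independent recomputation of the summary statistics from per_run."""
        return summarize_runs(self.per_run)


def summarize_runs(per_run: list[dict]) -> RunSummary:
    mccs = np.array([r["test_metrics"]["mcc"] for r in per_run], dtype=float)
    accs = np.array([r["test_metrics"]["accuracy"] for r in per_run], dtype=float)
    masks = {r["best_mask"] for r in per_run}
    return RunSummary(
        per_run=per_run,
        mean_mcc=float(mccs.mean()),
        stdev_mcc=float(mccs.std(ddof=0)),
        mean_accuracy=float(accs.mean()),
        stdev_accuracy=float(accs.std(ddof=0)),
        n_distinct_ensembles=len(masks),
    )


def finalize_and_test(best: Individual, pool: list[ClassifierSpec],
                      train: Dataset, test: Dataset,
                      tie_seed: int = 0, seed: int = 0,
                      ) -> tuple[MetricsRecord, ConfusionMatrix]:
    """Retrain the selected members on all of ``train`` and score on ``test``."""
    if train.feature_names != test.feature_names:
        raise DataError("train/test feature schemas differ")
    spec = decode_individual(best, pool)
    by_id = {s.id: (i, s) for i, s in enumerate(pool)}
    predictions: dict[str, np.ndarray] = {}
    for member in spec.member_ids:
        ci, cspec = by_id[member]
        est = build_estimator(cspec, _task_seed(seed, ci, -1 % 2**16))
        est.fit(train.features, train.labels)
        predictions[member] = np.asarray(est.predict(test.features), dtype=int)
    tie_rng = np.random.default_rng(np.random.SeedSequence([tie_seed, 2]))
    fused = ensemble_predict(spec, predictions, tie_rng)
    cm = confusion(test.labels, fused)
    return metrics(cm), cm


def repeated_runs(ga_config: GAConfig, pool: list[ClassifierSpec],
                  store: ModelStore, folds: FoldSplit, labels: np.ndarray,
                  train: Dataset, test: Dataset,
                  n_runs: int, base_seed: int = 0) -> RunSummary:
    """Full search + final test with seeds base_seed ... base_seed+n_runs-1.

    The fold split and model store are reused across runs (only the GA seed
    varies); this isolates the search stochasticity, and is the default
    protocol — rebuild the store per run if fold re-randomisation is wanted.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    per_run = []
    for r in range(n_runs):
        seed = base_seed + r
        result: GAResult = run_ga(config_replace(ga_config, seed=seed),
                                  store, folds, labels)
        rec, _cm = finalize_and_test(result.best, pool, train, test,
                                     tie_seed=seed, seed=seed)
        per_run.append({
            "seed": seed,
            "best_mask": str(result.best),
            "fitness": result.best_fitness,
            "generations": result.generations_run,
            "termination_reason": result.termination_reason,
            "test_metrics": rec.as_dict(),
        })
    return summarize_runs(per_run)


_BASELINES = {
    "bagging": lambda seed: BaggingClassifier(random_state=seed),
    "adaboost": lambda seed: AdaBoostClassifier(random_state=seed),
    "random_forest": lambda seed: RandomForestClassifier(random_state=seed),
}


def baseline_comparison(train: Dataset, test: Dataset,
                        baselines: list[str], seed: int = 0,
                        gaeoc_metrics: MetricsRecord | None = None,
                        ) -> pd.DataFrame:
    """Score off-the-shelf ensemble baselines on the same train/test split.

    Baselines run with library-default hyperparameters.  Unknown names are
    skipped with a warning row; duplicates are rejected.  When the search's
    own test metrics are supplied they appear as a ``ga_eoc`` row.
    """
    if len(set(baselines)) != len(baselines):
        raise ValueError("duplicate baseline names")
    rows = []
    for name in baselines:
        if name not in _BASELINES:
            import warnings

            warnings.warn(f"baseline {name!r} unavailable; skipped",
                          stacklevel=2)
            continue
        est = _BASELINES[name](seed)
        est.fit(train.features, train.labels)
        pred = np.asarray(est.predict(test.features), dtype=int)
        rec = metrics(confusion(test.labels, pred))
        rows.append({"classifier": name, **{k: v for k, v in
                                            rec.as_dict().items()
                                            if k != "undefined"}})
    if gaeoc_metrics is not None:
        rows.append({"classifier": "ga_eoc",
                     **{k: v for k, v in gaeoc_metrics.as_dict().items()
                        if k != "undefined"}})
    return pd.DataFrame(rows,
                        columns=["classifier", "accuracy", "precision",
                                 "recall", "f_measure", "mcc"])
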