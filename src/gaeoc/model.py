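"""Model/Results front end for the ensemble-selection pipeline.

:class:`EnsembleSelectionModel` bundles a training dataset, a classifier
pool and the search settings; ``fit()`` builds the stratified folds, trains
and caches the per-(classifier, fold) models, runs the genetic search and
returns an :class:`EnsembleSelectionResults` carrying the selected
ensemble, its per-fold MCCs, the fitness trajectory and a ``summary()``
table.  The pipeline modules remain usable directly for finer control.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dataio import DataError, Dataset
from .evaluation import finalize_and_test
from .folds_models import (ClassifierSpec, default_pool, make_cv_folds,
                           train_fold_models)
from .ga_search import GAConfig, GAResult, decode_individual, run_ga


class EnsembleSelectionModel:
    """Searches for the best majority-vote ensemble for a binary dataset."""

    def __init__(self, train: Dataset, pool: list[ClassifierSpec] | None = None,
                 n_folds: int = 10, ga_config: GAConfig | None = None):
        if not train.is_binary():
            raise DataError("training dataset must be binary with both classes")
        self.train = train
        self.pool = pool if pool is not None else default_pool()
        self.n_folds = n_folds
        self.ga_config = ga_config or GAConfig(pool_size=len(self.pool))
        if self.ga_config.pool_size != len(self.pool):
            raise ValueError("ga_config.pool_size must match the pool")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_column: str,
                       positive_label=None, name: str = "dataframe",
                       **kwargs) -> "EnsembleSelectionModel":
        labels = df[label_column]
        if positive_label is not None:
            y = (labels == positive_label).astype(int).to_numpy()
        else:
            counts = labels.value_counts()
            positive = sorted(v for v in counts.index
                              if counts[v] == counts.min())[-1]
            y = (labels == positive).astype(int).to_numpy()
        feats = df.drop(columns=[label_column])
        dataset = Dataset(
            features=feats.to_numpy(dtype=float),
            labels=y,
            feature_names=[str(c) for c in feats.columns],
            name=name,
        )
        return cls(dataset, **kwargs)

    def fit(self, seed: int = 0, n_jobs: int = 1) -> "EnsembleSelectionResults":
        folds = make_cv_folds(self.train, self.n_folds, seed=seed)
        store = train_fold_models(self.train, folds, self.pool, seed=seed,
                                  n_jobs=n_jobs, keep_models=False)
        config = GAConfig(**{**self.ga_config.__dict__, "seed": seed})
        ga_result = run_ga(config, store, folds, self.train.labels)
        return EnsembleSelectionResults(self, ga_result, folds, seed)


class EnsembleSelectionResults:
    """Fitted search outcome: the chosen ensemble and its diagnostics."""

    def __init__(self, model: EnsembleSelectionModel, ga_result: GAResult,
                 folds, seed: int):
        self.model = model
        self.ga_result = ga_result
        self.folds = folds
        self.seed = seed
        self.ensemble = decode_individual(ga_result.best, model.pool)

    @property
    def best_mask(self) -> str:
        return str(self.ga_result.best)

    @property
    def fitness(self) -> float:
        return self.ga_result.best_fitness

    @property
    def member_ids(self) -> tuple[str, ...]:
        return self.ensemble.member_ids

    @property
    def per_fold_mcc(self) -> list[float]:
        return self.ga_result.per_fold_mcc

    @property
    def fitness_history(self) -> list[float]:
        return self.ga_result.fitness_history

    def evaluate(self, test: Dataset):
        """Retrain the ensemble on the full training set and score ``test``."""
        return finalize_and_test(self.ga_result.best, self.model.pool,
                                 self.model.train, test,
                                 tie_seed=self.seed, seed=self.seed)

    def as_report(self, test_metrics: dict | None = None) -> dict:
        return {
            "best_mask": self.best_mask,
            "member_ids": list(self.member_ids),
            "per_fold_mcc": self.per_fold_mcc,
            "fitness": self.fitness,
            "test_metrics": test_metrics or {},
            "seed": self.seed,
            "generations": self.ga_result.generations_run,
            "n_folds": self.folds.n_folds,
        }

    def summary(self) -> str:
        r = self.ga_result
        lines = [
            "Ensemble selection results",
            "=" * 54,
            f"{'Training dataset:':<26}{self.model.train.name}",
            f"{'Pool size (k):':<26}{len(self.model.pool)}",
            f"{'Population size:':<26}{self.model.ga_config.population_size}",
            f"{'Folds:':<26}{self.folds.n_folds}",
            f"{'Seed:':<26}{self.seed}",
            "-" * 54,
            f"{'Best fitness (mean MCC):':<26}{r.best_fitness:.4f}",
            f"{'Best mask:':<26}{self.best_mask}",
            f"{'Members:':<26}{', '.join(self.member_ids)}",
            f"{'Generations run:':<26}{r.generations_run}",
            f"{'Termination:':<26}{r.termination_reason}",
            f"{'Fitness evaluations:':<26}{r.n_evaluations}",
            "-" * 54,
            "Per-fold MCC: " + " ".join(f"{v:.3f}" for v in r.per_fold_mcc),
            "=" * 54,
        ]
        return "\n".join(lines)
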