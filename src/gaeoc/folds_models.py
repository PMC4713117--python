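"""Cross-validation folds and the cached per-(classifier, fold) model store.

The search phase never retrains anything: every pool classifier is trained
once on each of the n_folds training folds and its predictions on the
held-out fold are cached in a :class:`ModelStore`.  For the default pool of
20 learners and 10 folds that is 200 cached models.  Ensemble fitness is
then a pure lookup-and-vote over these cached vectors.

The default pool mirrors a heterogeneous 20-learner WEKA-style mix (Bayes
variants, linear models, SVM, nearest neighbour, rule/tree learners and a
majority-class baseline) using scikit-learn estimators.  Exact behavioural
parity with any other toolkit is not promised — the search method is
pool-agnostic and the pool is fully pluggable.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from joblib import Parallel, delayed
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression, Perceptron, SGDClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import BernoulliNB, GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .dataio import DataError, Dataset

FAMILIES = ("bayes", "linear", "svm", "knn", "rule", "tree", "baseline")


@dataclass(frozen=True)
class ClassifierSpec:
    """One base learner in the pool; bit i of a GA individual selects pool[i]."""

    id: str
    family: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")


# algorithm name (in hyperparameters["algorithm"]) -> estimator factory
_BUILDERS = {
    "gaussian_nb": lambda p, seed: GaussianNB(**p),
    "bernoulli_nb": lambda p, seed: BernoulliNB(**p),
    "logistic": lambda p, seed: LogisticRegression(max_iter=2000, **p),
    "sgd": lambda p, seed: SGDClassifier(random_state=seed, **p),
    "svc": lambda p, seed: SVC(random_state=seed, **p),
    "perceptron": lambda p, seed: Perceptron(random_state=seed, **p),
    "knn": lambda p, seed: KNeighborsClassifier(**p),
    "tree": lambda p, seed: DecisionTreeClassifier(random_state=seed, **p),
    "random_forest": lambda p, seed: RandomForestClassifier(random_state=seed, **p),
    "gradient_boosting": lambda p, seed: GradientBoostingClassifier(
        random_state=seed, **p),
    "majority": lambda p, seed: DummyClassifier(strategy="most_frequent"),
}


def build_estimator(spec: ClassifierSpec, seed: int):
    """Instantiate the scikit-learn estimator for a pool entry."""
    params = dict(spec.hyperparameters)
    algorithm = params.pop("algorithm", None)
    if algorithm not in _BUILDERS:
        raise ValueError(f"{spec.id}: unknown algorithm {algorithm!r}")
    return _BUILDERS[algorithm](params, seed)


def default_pool() -> list[ClassifierSpec]:
    """The 20-learner heterogeneous pool (k = 20, so 2^20 - 1 ensembles).

    Near-duplicate entries (the two flavours of naive Bayes) are kept as
    distinct bits on purpose to preserve the 20-bit search space.
    """
    t = lambda **kw: {"algorithm": "tree", **kw}
    return [
        ClassifierSpec("bayes_net", "bayes", {"algorithm": "bernoulli_nb"}),
        ClassifierSpec("naive_bayes", "bayes", {"algorithm": "gaussian_nb"}),
        ClassifierSpec("naive_bayes_updateable", "bayes",
                       {"algorithm": "gaussian_nb"}),
        ClassifierSpec("lib_svm", "svm", {"algorithm": "svc", "gamma": "scale"}),
        ClassifierSpec("logistic", "linear", {"algorithm": "logistic", "C": 1.0}),
        ClassifierSpec("sgd", "linear", {"algorithm": "sgd", "loss": "hinge"}),
        ClassifierSpec("simple_logistic", "linear",
                       {"algorithm": "logistic", "C": 0.1}),
        ClassifierSpec("voted_perceptron", "linear", {"algorithm": "perceptron"}),
        ClassifierSpec("ibk", "knn", {"algorithm": "knn", "n_neighbors": 1}),
        ClassifierSpec("decision_table", "rule", t(max_depth=3)),
        ClassifierSpec("jrip", "rule", t(criterion="entropy", min_samples_leaf=5)),
        ClassifierSpec("oner", "rule", t(max_depth=1, criterion="entropy")),
        ClassifierSpec("part", "rule", t(max_depth=6)),
        ClassifierSpec("random_tree", "rule", t(splitter="random")),
        ClassifierSpec("rep_tree", "rule", t(ccp_alpha=0.01)),
        ClassifierSpec("zero_r", "baseline", {"algorithm": "majority"}),
        ClassifierSpec("decision_stump", "tree", t(max_depth=1)),
        ClassifierSpec("j48", "tree", t(ccp_alpha=0.005)),
        ClassifierSpec("random_forest", "tree",
                       {"algorithm": "random_forest", "n_estimators": 30}),
        ClassifierSpec("lmt", "tree",
                       {"algorithm": "gradient_boosting", "n_estimators": 30}),
    ]


@dataclass
class FoldSplit:
    """Stratified n-fold partition of {0, ..., n-1} by validation fold."""

    n_folds: int
    validation_indices: list[np.ndarray]
    seed: int

    def __post_init__(self) -> None:
        self.validation_indices = [np.asarray(v, dtype=int)
                                   for v in self.validation_indices]
        if len(self.validation_indices) != self.n_folds:
            raise DataError("fold count mismatch")
        concat = np.concatenate(self.validation_indices)
        n = concat.size
        if not np.array_equal(np.sort(concat), np.arange(n)):
            raise DataError("validation folds must partition the sample indices")

    @property
    def n_samples(self) -> int:
        return sum(v.size for v in self.validation_indices)

    def train_indices(self, fold: int) -> np.ndarray:
        others = [v for f, v in enumerate(self.validation_indices) if f != fold]
        return np.sort(np.concatenate(others))


def make_cv_folds(dataset: Dataset, n_folds: int = 10, seed: int = 0) -> FoldSplit:
    """Stratified k-fold split; fold sizes and class proportions within ±1."""
    if n_folds < 2:
        raise DataError("n_folds must be >= 2")
    counts = dataset.class_counts()
    small = {c: n for c, n in counts.items() if n < n_folds}
    if small:
        raise DataError(
            f"class counts {small} smaller than n_folds={n_folds}"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    validation = [val for _, val in
                  skf.split(dataset.features, dataset.labels)]
    return FoldSplit(n_folds=n_folds, validation_indices=validation, seed=seed)


@dataclass
class ModelStore:
    """Cached trained models and validation-fold predictions.

    ``val_predictions[(classifier_id, fold)]`` holds the binary prediction
    vector over that fold's validation samples.  Models themselves are kept
    only when ``keep_models`` was requested (the search needs only the
    predictions).  ``failures`` records learners that failed to train on a
    fold and fell back to their training-fold majority class.
    """

    pool_ids: list[str]
    n_folds: int
    val_predictions: dict[tuple[str, int], np.ndarray]
    labels: np.ndarray
    dataset_hash: str
    seed: int
    models: dict[tuple[str, int], object] | None = None
    failures: list[tuple[str, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        expected = len(self.pool_ids) * self.n_folds
        if len(self.val_predictions) != expected:
            raise DataError(
                f"store must have {expected} entries, got {len(self.val_predictions)}"
            )

    @property
    def n_entries(self) -> int:
        return len(self.val_predictions)


def dataset_hash(dataset: Dataset) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(dataset.features).tobytes())
    h.update(np.ascontiguousarray(dataset.labels).tobytes())
    return h.hexdigest()[:16]


def _task_seed(seed: int, clf_index: int, fold: int) -> int:
    ss = np.random.SeedSequence([seed, clf_index, fold])
    return int(ss.generate_state(1)[0] % (2**31))


def _fit_one(spec: ClassifierSpec, clf_index: int, fold: int,
             X_train, y_train, X_val, seed: int):
    """Train one (classifier, fold) pair; never raises.

    A learner that fails to train (or a single-class training fold) falls
    back to predicting the majority class of its training folds.
    """
    majority = int(np.bincount(y_train).argmax())
    task_seed = _task_seed(seed, clf_index, fold)
    try:
        est = build_estimator(spec, task_seed)
        est.fit(X_train, y_train)
        pred = np.asarray(est.predict(X_val), dtype=int)
        return (spec.id, fold), est, pred, None
    except Exception as exc:  # noqa: BLE001 - contract: the store never aborts
        pred = np.full(X_val.shape[0], majority, dtype=int)
        return (spec.id, fold), None, pred, str(exc)


def train_fold_models(dataset: Dataset, folds: FoldSplit,
                      pool: list[ClassifierSpec], seed: int = 0,
                      n_jobs: int = 1, keep_models: bool = True) -> ModelStore:
    """Train every pool classifier on every training fold and cache predictions.

    The (classifier, fold) tasks are independent; with ``n_jobs > 1`` they
    run in parallel and results are merged by key, so parallel and serial
    construction produce identical stores.
    """
    if not pool:
        raise DataError("empty classifier pool")
    if len({s.id for s in pool}) != len(pool):
        raise DataError("duplicate classifier ids in pool")
    if folds.n_samples != dataset.n_samples:
        raise DataError("fold split does not match the dataset size")

    tasks = []
    for fold in range(folds.n_folds):
        train_idx = folds.train_indices(fold)
        val_idx = folds.validation_indices[fold]
        X_train, y_train = dataset.features[train_idx], dataset.labels[train_idx]
        X_val = dataset.features[val_idx]
        for ci, spec in enumerate(pool):
            tasks.append((spec, ci, fold, X_train, y_train, X_val))

    if n_jobs == 1:
        results = [_fit_one(*t, seed=seed) for t in tasks]
    else:
        results = Parallel(n_jobs=n_jobs)(
            delayed(_fit_one)(*t, seed=seed) for t in tasks)

    val_predictions, models, failures = {}, {}, []
    for key, est, pred, err in results:
        val_predictions[key] = pred
        if keep_models:
            models[key] = est
        if err is not None:
            failures.append((key[0], key[1], err))

    return ModelStore(
        pool_ids=[s.id for s in pool],
        n_folds=folds.n_folds,
        val_predictions=val_predictions,
        labels=dataset.labels.copy(),
        dataset_hash=dataset_hash(dataset),
        seed=seed,
        models=models if keep_models else None,
        failures=failures,
    )
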