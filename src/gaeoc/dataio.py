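"""Reading and writing labelled tabular datasets.

The in-memory container is :class:`Dataset`: a dense real-valued feature
matrix, an integer label vector and the feature names.  Binary problems are
always mapped so that the positive (usually minority) class is 1 and the
other class is 0; multiclass tables keep contiguous integer codes and are
meant to be decomposed with :func:`one_vs_all`.

Supported on-disk formats are headed CSV (the native format) and ARFF
(read-only, via :func:`scipy.io.arff.loadarff`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class DataError(ValueError):
    """Raised for malformed input tables or invalid dataset operations."""


@dataclass
class Dataset:
    """A labelled feature table.

    Parameters
    ----------
    features : (n_samples, n_features) float array
    labels : (n_samples,) int array with values in a contiguous label set
    feature_names : unique column names, one per feature
    name : free-form identifier used in reports
    label_mapping : original label value -> integer code, if the table was
        read from disk; ``None`` for programmatically built datasets.
    """

    features: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    name: str = "dataset"
    label_mapping: dict | None = None
    single_class: bool = field(default=False)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.ndim != 2:
            raise DataError("features must be a 2-D matrix")
        if self.features.shape[0] != self.labels.shape[0]:
            raise DataError(
                f"row count mismatch: {self.features.shape[0]} feature rows "
                f"vs {self.labels.shape[0]} labels"
            )
        if len(self.feature_names) != self.features.shape[1]:
            raise DataError("feature_names length must equal the column count")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise DataError("feature names must be unique")
        if not np.isfinite(self.features).all():
            raise DataError(f"{self.name!r}: non-finite or missing feature values")
        self.single_class = len(np.unique(self.labels)) < 2

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def class_counts(self) -> dict[int, int]:
        values, counts = np.unique(self.labels, return_counts=True)
        return {int(v): int(c) for v, c in zip(values, counts)}

    def is_binary(self) -> bool:
        return set(np.unique(self.labels)) <= {0, 1} and not self.single_class

    def subset(self, indices, name: str | None = None) -> "Dataset":
        """Row subset (order given by ``indices``), sharing the schema."""
        indices = np.asarray(indices, dtype=int)
        return Dataset(
            features=self.features[indices],
            labels=self.labels[indices],
            feature_names=list(self.feature_names),
            name=name or self.name,
            label_mapping=self.label_mapping,
        )

    def select_features(self, indices, name: str | None = None) -> "Dataset":
        indices = sorted(int(i) for i in indices)
        return Dataset(
            features=self.features[:, indices],
            labels=self.labels.copy(),
            feature_names=[self.feature_names[i] for i in indices],
            name=name or self.name,
            label_mapping=self.label_mapping,
        )

    def imbalance_ratio(self) -> float:
        """Majority-class count divided by minority-class count."""
        counts = sorted(self.class_counts().values())
        if len(counts) != 2:
            raise DataError("imbalance ratio is defined for binary datasets")
        return counts[1] / counts[0]


def _map_binary_labels(raw: pd.Series, positive_label: str | None):
    """Map two raw label values onto {0, 1}.

    The positive class is ``positive_label`` when supplied, otherwise the
    minority class (ties broken towards the lexicographically larger value so
    the choice is deterministic).
    """
    values = raw.astype(str)
    counts = values.value_counts()
    distinct = sorted(counts.index)
    if positive_label is not None:
        positive_label = str(positive_label)
        if positive_label not in distinct:
            raise DataError(
                f"positive_label {positive_label!r} not found among labels {distinct}"
            )
        positive = positive_label
    else:
        candidates = sorted(v for v in distinct if counts[v] == counts.min())
        positive = candidates[-1]
    mapping = {v: (1 if v == positive else 0) for v in distinct}
    return values.map(mapping).to_numpy(dtype=int), mapping


def read_table(
    path,
    format: str = "delimited",
    label_column: str = "class",
    positive_label: str | None = None,
) -> Dataset:
    """Read a labelled table from CSV or ARFF into a :class:`Dataset`.

    Labels are mapped to contiguous integers: binary tables get positive
    class 1 / other 0 (see :func:`_map_binary_labels`), multiclass tables get
    codes in sorted label order.  The mapping is recorded on the dataset.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"input file not found: {path}")
    if format == "delimited":
        try:
            df = pd.read_csv(path)
        except pd.errors.EmptyDataError:
            raise DataError(f"empty input file: {path}") from None
    elif format == "arff":
        from scipy.io import arff as scipy_arff

        data, _meta = scipy_arff.loadarff(str(path))
        df = pd.DataFrame(data)
        for col in df.columns:
            if df[col].dtype == object:
                df[col] = df[col].str.decode("utf-8")
    else:
        raise DataError(f"unknown format {format!r} (expected 'delimited' or 'arff')")

    if df.shape[0] == 0:
        raise DataError(f"empty input file: {path}")
    if label_column not in df.columns:
        raise DataError(
            f"label column {label_column!r} not present; columns are {list(df.columns)}"
        )

    raw_labels = df[label_column]
    feat_df = df.drop(columns=[label_column])
    for col in feat_df.columns:
        coerced = pd.to_numeric(feat_df[col], errors="coerce")
        bad = coerced.isna() & feat_df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataError(
                f"non-numeric feature value {feat_df[col].iloc[row]!r} "
                f"in column {col!r}, row {row}"
            )
        if coerced.isna().any():
            raise DataError(f"missing value in feature column {col!r}")
        feat_df[col] = coerced

    distinct = raw_labels.astype(str).nunique()
    if distinct <= 2:
        labels, mapping = _map_binary_labels(raw_labels, positive_label)
    else:
        ordered = sorted(raw_labels.astype(str).unique())
        mapping = {v: i for i, v in enumerate(ordered)}
        labels = raw_labels.astype(str).map(mapping).to_numpy(dtype=int)

    return Dataset(
        features=feat_df.to_numpy(dtype=float),
        labels=labels,
        feature_names=[str(c) for c in feat_df.columns],
        name=path.stem,
        label_mapping=mapping,
    )


def write_table(dataset: Dataset, path, label_column: str = "class") -> None:
    """Write a dataset back to headed CSV (inverse of :func:`read_table`)."""
    if label_column in dataset.feature_names:
        raise DataError(f"label column name {label_column!r} clashes with a feature")
    df = pd.DataFrame(dataset.features, columns=dataset.feature_names)
    df[label_column] = dataset.labels
    df.to_csv(path, index=False)


def one_vs_all(dataset: Dataset, target_class) -> Dataset:
    """Binary one-vs-all decomposition: ``target_class`` becomes 1, rest 0.

    ``target_class`` may be an integer code present in the labels or an
    original label value recorded in the dataset's mapping.  Sample order is
    preserved; call once per class to obtain the full decomposition.
    """
    target = None
    if dataset.label_mapping and str(target_class) in dataset.label_mapping:
        target = dataset.label_mapping[str(target_class)]
    else:
        try:
            candidate = int(target_class)
        except (TypeError, ValueError):
            candidate = None
        if candidate is not None and candidate in dataset.classes:
            target = candidate
    if target is None:
        raise DataError(
            f"target class {target_class!r} absent from label set "
            f"{sorted(dataset.classes.tolist())}"
        )
    if len(dataset.classes) < 2:
        raise DataError("one_vs_all requires at least two classes")
    labels = (dataset.labels == target).astype(int)
    return Dataset(
        features=dataset.features.copy(),
        labels=labels,
        feature_names=list(dataset.feature_names),
        name=f"{dataset.name}:ova{target}",
        label_mapping={"rest": 0, str(target_class): 1},
    )


#: keys every run report must carry before it is written to disk
REPORT_KEYS = (
    "best_mask",
    "member_ids",
    "per_fold_mcc",
    "fitness",
    "test_metrics",
    "seed",
    "generations",
    "n_folds",
)


def write_report(result: dict, path) -> None:
    """Write a run-result manifest as canonical JSON.

    The record must contain :data:`REPORT_KEYS`; ``per_fold_mcc`` must have
    exactly ``n_folds`` entries.  Serialisation is canonical (sorted keys, no
    trailing whitespace) so identical records produce byte-identical files.
    """
    missing = [k for k in REPORT_KEYS if k not in result]
    if missing:
        raise DataError(f"result record is missing keys: {missing}")
    if len(result["per_fold_mcc"]) != result["n_folds"]:
        raise DataError(
            f"per_fold_mcc has {len(result['per_fold_mcc'])} entries "
            f"but n_folds is {result['n_folds']}"
        )
    payload = json.dumps(result, sort_keys=True, indent=1)
    Path(path).write_text(payload + "\n")


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())
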