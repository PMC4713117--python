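"""Majority-vote fusion and classification metrics.

The fusion rule gives each ensemble member one unweighted vote per sample;
the positive class wins on a strict majority, and an exact tie is resolved
uniformly at random from an explicit, seeded RNG stream so whole runs stay
reproducible.  The headline metric is the Matthews correlation coefficient
(MCC), computed from all four confusion-matrix cells:

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with the convention MCC = 0 whenever a denominator factor vanishes — which
is exactly the score a constant (majority-class) predictor receives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 contingency table for a binary problem (positive class = 1)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class EnsembleSpec:
    """An ordered selection of classifier ids from a pool."""

    member_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValueError("an ensemble must have at least one member")
        if len(set(self.member_ids)) != len(self.member_ids):
            raise ValueError("duplicate member ids in ensemble")

    @property
    def size(self) -> int:
        return len(self.member_ids)


def majority_vote(votes, tie_rng: np.random.Generator) -> int:
    """Unweighted majority vote over one sample's member predictions.

    Returns 1 when positive votes exceed half the committee, 0 when they
    fall short, and a uniform random draw from ``tie_rng`` on an exact tie
    (only possible for even committees).
    """
    votes = np.asarray(votes)
    if votes.size == 0:
        raise ValueError("empty vote vector")
    if not np.isin(votes, (0, 1)).all():
        raise ValueError("votes must be 0/1")
    pos = int(votes.sum())
    k = votes.size
    if 2 * pos > k:
        return 1
    if 2 * pos < k:
        return 0
    return int(tie_rng.integers(0, 2))


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Count the four outcomes of binary predictions against truth."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: {y_true.shape} truth vs {y_pred.shape} predictions"
        )
    for name, v in (("y_true", y_true), ("y_pred", y_pred)):
        if not np.isin(v, (0, 1)).all():
            raise ValueError(f"{name} must contain only 0/1 values")
    return ConfusionMatrix(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient of a confusion matrix.

    Integer arithmetic for the numerator and denominator product (no
    intermediate overflow), floating square root at the end.  Returns 0.0
    when any denominator factor is zero.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tp, fp, tn, fn = int(cm.tp), int(cm.fp), int(cm.tn), int(cm.fn)
    denom_factors = (tp + fp, tp + fn, tn + fp, tn + fn)
    if any(f == 0 for f in denom_factors):
        return 0.0
    num = tp * tn - fp * fn
    denom = math.sqrt(math.prod(denom_factors))
    return num / denom


@dataclass(frozen=True)
class MetricsRecord:
    """Standard binary-classification metrics from one confusion matrix.

    Ratios with a zero denominator are reported as 0.0 and their names
    collected in ``undefined``.
    """

    accuracy: float
    precision: float
    recall: float
    f_measure: float
    mcc: float
    undefined: tuple[str, ...] = field(default=())

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f_measure": self.f_measure,
            "mcc": self.mcc,
            "undefined": list(self.undefined),
        }


def metrics(cm: ConfusionMatrix) -> MetricsRecord:
    """Accuracy, precision, recall, F-measure and MCC from one matrix."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    accuracy = (cm.tp + cm.tn) / cm.total
    precision = ratio(cm.tp, cm.tp + cm.fp, "precision")
    recall = ratio(cm.tp, cm.tp + cm.fn, "recall")
    if precision + recall == 0:
        undefined.append("f_measure")
        f_measure = 0.0
    else:
        f_measure = 2 * precision * recall / (precision + recall)
    return MetricsRecord(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f_measure=f_measure,
        mcc=mcc(cm),
        undefined=tuple(undefined),
    )


def ensemble_predict(ensemble: EnsembleSpec,
                     per_member_predictions: dict[str, np.ndarray],
                     tie_rng: np.random.Generator) -> np.ndarray:
    """Elementwise majority vote of the members' prediction vectors.

    Tie draws are consumed from ``tie_rng`` in increasing sample order, so
    the output is reproducible for a given generator state.
    """
    missing = [m for m in ensemble.member_ids if m not in per_member_predictions]
    if missing:
        raise ValueError(f"missing member predictions: {missing}")
    vectors = [np.asarray(per_member_predictions[m]) for m in ensemble.member_ids]
    lengths = {v.shape for v in vectors}
    if len(lengths) != 1:
        raise ValueError(f"member prediction lengths differ: {sorted(lengths)}")
    stacked = np.stack(vectors, axis=0)
    if not np.isin(stacked, (0, 1)).all():
        raise ValueError("member predictions must be 0/1")
    k = stacked.shape[0]
    pos = stacked.sum(axis=0)
    out = np.where(2 * pos > k, 1, 0)
    ties = np.flatnonzero(2 * pos == k)
    if ties.size:
        out[ties] = tie_rng.integers(0, 2, size=ties.size)
    return out.astype(int)
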