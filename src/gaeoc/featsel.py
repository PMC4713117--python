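"""Feature selection: entropy/MDL discretisation and (α,β)-k set selection.

Two stages, used separately or chained:

1. :func:`mdl_discretize_filter` — per-feature recursive entropy-minimising
   cut-point search with the minimum-description-length stopping rule of
   Fayyad & Irani.  A feature for which no cut passes the MDL test carries
   no class information at this granularity and is discarded; the survivors
   are returned as small-integer interval codes.

2. :func:`ab_k_select` — the (α,β)-k minimum feature set: a smallest subset
   S of the (discrete) features such that every inter-class sample pair
   differs on at least α features of S and every intra-class pair agrees on
   at least β features of S.  A greedy multicover solver is the default;
   an exhaustive solver certifies minimum cardinality on small instances.

:func:`consolidate_features` provides the union / intersection combination
of per-replicate selections used when balancing produced several datasets.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .dataio import DataError, Dataset


class InfeasibleError(ValueError):
    """Raised when no feature subset can satisfy the (α,β) constraints."""


@dataclass
class DiscreteDataset:
    """A discretised view of a dataset: interval codes per kept feature."""

    codes: np.ndarray                  # (n_samples, n_kept) small ints
    labels: np.ndarray                 # binary vector
    cutpoints: list[np.ndarray]        # per kept feature, sorted thresholds
    kept_features: list[int]           # column index into the source Dataset
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=int)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.codes.shape[0] != self.labels.shape[0]:
            raise DataError("codes / labels row mismatch")
        if self.codes.shape[1] != len(self.kept_features):
            raise DataError("codes column count must match kept_features")
        if len(self.cutpoints) != len(self.kept_features):
            raise DataError("cutpoints must align with kept_features")
        for j, cuts in enumerate(self.cutpoints):
            if len(cuts) and self.codes[:, j].max() > len(cuts):
                raise DataError(f"code out of range for feature column {j}")

    @property
    def n_samples(self) -> int:
        return self.codes.shape[0]

    @property
    def n_features(self) -> int:
        return self.codes.shape[1]


@dataclass
class ABKConfig:
    """Settings for (α,β)-k selection.

    alpha : minimum number of selected features on which every inter-class
        pair must differ (≥ 1).
    beta : minimum number of selected features on which every intra-class
        pair must agree (≥ 0).
    solver : 'greedy' (default) or 'exhaustive'; the exhaustive solver is
        only permitted up to ``exhaustive_cap`` features.
    """

    alpha: int = 1
    beta: int = 0
    solver: str = "greedy"
    exhaustive_cap: int = 20

    def __post_init__(self) -> None:
        if self.alpha < 1:
            raise ValueError("alpha must be >= 1")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.solver not in ("greedy", "exhaustive"):
            raise ValueError(f"unknown solver {self.solver!r}")


# ---------------------------------------------------------------------------
# MDL discretisation
# ---------------------------------------------------------------------------

def _entropy(labels: np.ndarray) -> float:
    """Class-information entropy in bits."""
    if labels.size == 0:
        return 0.0
    _, counts = np.unique(labels, return_counts=True)
    p = counts / labels.size
    return float(-(p * np.log2(p)).sum())


def _mdl_gain_and_threshold(labels, left, right):
    """Information gain of a candidate cut and its MDL acceptance threshold.

    The cut is accepted iff gain > (log2(N-1) + delta) / N, where
    delta = log2(3^c - 2) - [c*Ent(S) - c1*Ent(S1) - c2*Ent(S2)] and c, c1,
    c2 count the classes present in the parent and each side.
    """
    n = labels.size
    ent_s = _entropy(labels)
    ent_l, ent_r = _entropy(left), _entropy(right)
    gain = ent_s - (left.size / n) * ent_l - (right.size / n) * ent_r
    c = np.unique(labels).size
    c1 = np.unique(left).size
    c2 = np.unique(right).size
    delta = np.log2(3.0**c - 2.0) - (c * ent_s - c1 * ent_l - c2 * ent_r)
    threshold = (np.log2(n - 1) + delta) / n
    return gain, threshold


def _find_cuts(values: np.ndarray, labels: np.ndarray) -> list[float]:
    """Recursive binary cut search on one feature (values need not be sorted)."""
    order = np.argsort(values, kind="stable")
    values, labels = values[order], labels[order]

    def recurse(lo: int, hi: int) -> list[float]:
        v, y = values[lo:hi], labels[lo:hi]
        n = v.size
        if n < 2 or np.unique(y).size < 2:
            return []
        # candidate cuts: midpoints between adjacent distinct values
        best = None
        for i in range(1, n):
            if v[i] == v[i - 1]:
                continue
            gain, thr = _mdl_gain_and_threshold(y, y[:i], y[i:])
            if best is None or gain > best[0] + 1e-15:
                best = (gain, thr, i)
        if best is None:
            return []
        gain, thr, i = best
        if gain <= thr:
            return []
        cut = float((v[i - 1] + v[i]) / 2.0)
        return recurse(lo, lo + i) + [cut] + recurse(lo + i, hi)

    return recurse(0, values.size)


def mdl_discretize_filter(dataset: Dataset) -> DiscreteDataset:
    """Discretise every feature and keep only those with an accepted cut.

    Cut points minimise the weighted class entropy of the induced partition
    and are accepted recursively while they pass the MDL criterion; features
    with no accepted cut are dropped.  Invariant to strictly monotone
    transforms of a feature (only the value order matters).
    """
    if dataset.single_class:
        raise DataError("discretisation is undefined for single-class data")
    kept, cutpoints, columns = [], [], []
    for j in range(dataset.n_features):
        cuts = _find_cuts(dataset.features[:, j], dataset.labels)
        if not cuts:
            continue
        cuts_arr = np.asarray(sorted(cuts), dtype=float)
        kept.append(j)
        cutpoints.append(cuts_arr)
        columns.append(np.searchsorted(cuts_arr, dataset.features[:, j]))
    codes = (np.stack(columns, axis=1) if columns
             else np.empty((dataset.n_samples, 0), dtype=int))
    return DiscreteDataset(
        codes=codes,
        labels=dataset.labels.copy(),
        cutpoints=cutpoints,
        kept_features=kept,
        feature_names=[dataset.feature_names[j] for j in kept],
    )


# ---------------------------------------------------------------------------
# (α,β)-k selection
# ---------------------------------------------------------------------------

def _pair_tables(dd: DiscreteDataset):
    """Boolean tables pair × feature: inter-pair differs / intra-pair agrees."""
    idx0 = np.flatnonzero(dd.labels == 0)
    idx1 = np.flatnonzero(dd.labels == 1)
    if idx0.size == 0 or idx1.size == 0:
        raise DataError("(α,β)-k selection requires both classes present")
    inter_pairs = [(int(a), int(b)) for a in idx0 for b in idx1]
    intra_pairs = ([(int(a), int(b)) for a, b in itertools.combinations(idx0, 2)]
                   + [(int(a), int(b)) for a, b in itertools.combinations(idx1, 2)])
    codes = dd.codes
    inter = np.array([codes[a] != codes[b] for a, b in inter_pairs], dtype=bool)
    intra = np.array([codes[a] == codes[b] for a, b in intra_pairs], dtype=bool)
    inter = inter.reshape(len(inter_pairs), dd.n_features)
    intra = intra.reshape(len(intra_pairs), dd.n_features)
    return inter_pairs, inter, intra_pairs, intra


def _check_feasible(config, inter_pairs, inter, intra_pairs, intra):
    if inter.shape[0]:
        diff_counts = inter.sum(axis=1)
        worst = int(np.argmin(diff_counts))
        max_alpha = int(diff_counts[worst])
        if max_alpha < config.alpha:
            a, b = inter_pairs[worst]
            raise InfeasibleError(
                f"alpha={config.alpha} infeasible: inter-class pair "
                f"(sample {a}, sample {b}) differs on only {max_alpha} "
                f"feature(s); maximum feasible alpha at beta={config.beta} "
                f"is {max_alpha}"
            )
    if config.beta > 0 and intra.shape[0]:
        agree_counts = intra.sum(axis=1)
        worst = int(np.argmin(agree_counts))
        max_beta = int(agree_counts[worst])
        if max_beta < config.beta:
            a, b = intra_pairs[worst]
            raise InfeasibleError(
                f"beta={config.beta} infeasible: intra-class pair "
                f"(sample {a}, sample {b}) agrees on only {max_beta} feature(s)"
            )


def _satisfies(selected_cols, config, inter, intra) -> bool:
    cols = sorted(selected_cols)
    if not cols:
        return inter.shape[0] == 0 and (config.beta == 0 or intra.shape[0] == 0)
    ok_inter = (inter[:, cols].sum(axis=1) >= config.alpha).all() if inter.shape[0] else True
    ok_intra = (intra[:, cols].sum(axis=1) >= config.beta).all() if intra.shape[0] else True
    return bool(ok_inter and ok_intra)


def ab_k_select(dd: DiscreteDataset, config: ABKConfig | None = None) -> set[int]:
    """Select an (α,β)-feasible feature set; returns source-dataset indices.

    Greedy solver: repeatedly add the feature that covers the most
    still-unsatisfied pair constraints (an inter pair needs α covering
    features that differ on it, an intra pair needs β that agree), ties
    broken towards the lowest feature index.  Exhaustive solver: smallest
    feasible subset by enumeration (lexicographically first among minima).

    Raises :class:`InfeasibleError`, naming a violating pair and the
    maximum feasible α, when the constraints cannot be met even with every
    feature selected.
    """
    config = config or ABKConfig()
    inter_pairs, inter, intra_pairs, intra = _pair_tables(dd)
    _check_feasible(config, inter_pairs, inter, intra_pairs, intra)

    n = dd.n_features
    if config.solver == "exhaustive":
        if n > config.exhaustive_cap:
            raise ValueError(
                f"exhaustive solver capped at {config.exhaustive_cap} features "
                f"(instance has {n})"
            )
        for size in range(0, n + 1):
            for combo in itertools.combinations(range(n), size):
                if _satisfies(combo, config, inter, intra):
                    return {dd.kept_features[j] for j in combo}
        raise InfeasibleError("no feasible subset found")  # pragma: no cover

    # greedy multicover
    inter_deficit = np.full(inter.shape[0], config.alpha, dtype=int)
    intra_deficit = np.full(intra.shape[0], config.beta, dtype=int)
    selected: list[int] = []
    available = list(range(n))
    while inter_deficit.sum() + intra_deficit.sum() > 0:
        best_j, best_cover = None, -1
        for j in available:
            cover = int(inter[inter_deficit > 0, j].sum()) + \
                int(intra[intra_deficit > 0, j].sum())
            if cover > best_cover:
                best_j, best_cover = j, cover
        if best_cover <= 0:  # pragma: no cover - excluded by feasibility check
            raise InfeasibleError("greedy solver stalled on an uncoverable pair")
        selected.append(best_j)
        available.remove(best_j)
        inter_deficit = np.maximum(inter_deficit - inter[:, best_j].astype(int), 0)
        intra_deficit = np.maximum(intra_deficit - intra[:, best_j].astype(int), 0)
    return {dd.kept_features[j] for j in selected}


def verify_ab_constraints(dd: DiscreteDataset, selected: set[int],
                          alpha: int, beta: int) -> bool:
    """Post-hoc check of the (α,β) constraints by direct pair enumeration."""
    cols = [dd.kept_features.index(f) for f in sorted(selected)]
    _, inter, _, intra = _pair_tables(dd)
    cfg = ABKConfig(alpha=alpha, beta=beta)
    return _satisfies(cols, cfg, inter, intra)


def consolidate_features(feature_sets: list[set[int]], mode: str) -> set[int]:
    """Union or intersection of per-replicate feature selections."""
    if not feature_sets:
        raise ValueError("consolidate_features requires a non-empty list")
    sets = [set(s) for s in feature_sets]
    if mode == "union":
        return set().union(*sets)
    if mode == "intersection":
        return set.intersection(*sets)
    raise ValueError(f"unknown mode {mode!r} (expected 'union' or 'intersection')")


# ---------------------------------------------------------------------------
# Replicate pipelines (UAB / IAB / UEAB)
# ---------------------------------------------------------------------------

def select_features_pipeline(replicates: list[Dataset], mode: str,
                             config: ABKConfig | None = None) -> set[int]:
    """Consolidated feature selection over balanced replicates.

    ``uab``  — discretise + (α,β)-k per replicate, union, then one more
    (α,β)-k pass on the union-reduced first replicate.
    ``iab``  — as UAB but intersect the per-replicate selections and stop.
    ``ueab`` — per-replicate MDL *filter* then (α,β)-k, union of selections.
    ``plain`` — single dataset: discretise then (α,β)-k.
    """
    config = config or ABKConfig()
    if not replicates:
        raise ValueError("no replicates supplied")
    if mode == "plain":
        return ab_k_select(mdl_discretize_filter(replicates[0]), config)

    per_rep = [ab_k_select(mdl_discretize_filter(rep), config)
               for rep in replicates]
    if mode == "iab":
        return consolidate_features(per_rep, "intersection")
    if mode in ("uab", "ueab"):
        union = consolidate_features(per_rep, "union")
        if mode == "ueab":
            return union
        reduced = replicates[0].select_features(sorted(union))
        dd = mdl_discretize_filter(reduced)
        inner = ab_k_select(dd, config)
        kept = sorted(union)
        return {kept[i] for i in inner}
    raise ValueError(f"unknown mode {mode!r}")
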