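"""Entropy/MDL discretisation and (α,β)-k minimum feature set selection."""

import itertools
import math

import numpy as np
import pytest

from gaeoc.dataio import DataError, Dataset
from gaeoc.featsel import (ABKConfig, DiscreteDataset, InfeasibleError,
                           ab_k_select, consolidate_features,
                           mdl_discretize_filter, verify_ab_constraints)
from gaeoc.synthetic import gen_toy_abk_instance


def _dataset(columns, labels, name="toy"):
    X = np.column_stack(columns).astype(float)
    return Dataset(X, np.asarray(labels, int),
                   [f"f{j}" for j in range(X.shape[1])], name=name)


def _entropy(y):
    _, counts = np.unique(y, return_counts=True)
    p = counts / y.size
    return float(-(p * np.log2(p)).sum())


def _best_single_cut(values, labels):
    """Independent single-split oracle: (max gain, its MDL threshold)."""
    order = np.argsort(values, kind="stable")
    v, y = np.asarray(values)[order], np.asarray(labels)[order]
    n = v.size
    base = _entropy(y)
    best = None
    for i in range(1, n):
        if v[i] == v[i - 1]:
            continue
        left, right = y[:i], y[i:]
        gain = base - (i / n) * _entropy(left) - ((n - i) / n) * _entropy(right)
        c, c1, c2 = (np.unique(a).size for a in (y, left, right))
        delta = math.log2(3.0**c - 2.0) - (c * base - c1 * _entropy(left)
                                           - c2 * _entropy(right))
        threshold = (math.log2(n - 1) + delta) / n
        if best is None or gain > best[0]:
            best = (gain, threshold)
    return best


class TestMDLDiscretize:
    def test_perfectly_ordered_feature_kept_with_one_cut(self):
        labels = [0] * 10 + [1] * 10
        values = np.concatenate([-np.arange(1, 11), np.arange(1, 11)])
        dd = mdl_discretize_filter(_dataset([values], labels))
        assert dd.kept_features == [0]
        assert len(dd.cutpoints[0]) == 1
        # the accepted cut separates the classes exactly
        assert (dd.codes[:10, 0] == 0).all() and (dd.codes[10:, 0] == 1).all()

    def test_constant_feature_dropped(self):
        labels = [0, 1] * 10
        dd = mdl_discretize_filter(_dataset([np.ones(20)], labels))
        assert dd.kept_features == []
        assert dd.codes.shape == (20, 0)

    def test_label_independent_feature_dropped(self):
        """Random labels: the best single cut fails MDL, feature is dropped."""
        rng = np.random.default_rng(21)
        values = rng.standard_normal(50)
        labels = rng.integers(0, 2, 50)
        gain, threshold = _best_single_cut(values, labels)
        assert gain <= threshold  # independent oracle agrees it must go
        dd = mdl_discretize_filter(_dataset([values], labels))
        assert dd.kept_features == []

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        values = rng.standard_normal(40)
        labels = (values + 0.3 * rng.standard_normal(40) > 0).astype(int)
        dd_raw = mdl_discretize_filter(_dataset([values], labels))
        dd_exp = mdl_discretize_filter(_dataset([np.exp(values)], labels))
        assert dd_raw.kept_features == dd_exp.kept_features
        np.testing.assert_array_equal(dd_raw.codes, dd_exp.codes)

    def test_single_class_rejected(self):
        with pytest.raises(DataError, match="single-class"):
            mdl_discretize_filter(_dataset([np.arange(4.0)], [1, 1, 1, 1]))


def _discrete(codes, labels):
    codes = np.asarray(codes, int)
    return DiscreteDataset(
        codes=codes,
        labels=np.asarray(labels, int),
        cutpoints=[np.arange(codes[:, j].max()) + 0.5
                   for j in range(codes.shape[1])],
        kept_features=list(range(codes.shape[1])),
    )


def _oracle_min_cardinality(dd, alpha, beta):
    """Independent subset enumeration with direct pair checking."""
    n = dd.n_features
    idx0 = np.flatnonzero(dd.labels == 0)
    idx1 = np.flatnonzero(dd.labels == 1)
    best = None
    for size in range(n + 1):
        for combo in itertools.combinations(range(n), size):
            ok = all(
                sum(dd.codes[a, j] != dd.codes[b, j] for j in combo) >= alpha
                for a in idx0 for b in idx1)
            if ok and beta > 0:
                for group in (idx0, idx1):
                    for a, b in itertools.combinations(group, 2):
                        if sum(dd.codes[a, j] == dd.codes[b, j]
                               for j in combo) < beta:
                            ok = False
            if ok:
                best = combo
                return len(best)
    return None


class TestABKSelect:
    def test_single_perfect_discriminator(self):
        codes = [[0, 1, 0], [0, 0, 1], [1, 1, 1], [1, 0, 0]]
        dd = _discrete(codes, [0, 0, 1, 1])
        assert ab_k_select(dd, ABKConfig(alpha=1, beta=0)) == {0}

    def test_greedy_matches_exhaustive_cardinality(self):
        """Toy 6-sample, 5-feature instance; oracle enumerates all 2^5 sets."""
        rng = np.random.default_rng(9)
        codes = rng.integers(0, 2, size=(6, 5))
        labels = [0, 0, 0, 1, 1, 1]
        dd = _discrete(codes, labels)
        cfg = ABKConfig(alpha=2, beta=0)
        greedy = ab_k_select(dd, cfg)
        oracle = _oracle_min_cardinality(dd, 2, 0)
        exhaustive = ab_k_select(dd, ABKConfig(alpha=2, beta=0,
                                               solver="exhaustive"))
        assert len(exhaustive) == oracle
        assert len(greedy) == len(exhaustive)
        assert verify_ab_constraints(dd, greedy, 2, 0)

    def test_infeasible_alpha_names_pair_and_bound(self):
        codes = [[0, 0], [0, 1], [1, 0], [1, 1]]
        dd = _discrete(codes, [0, 0, 1, 1])
        with pytest.raises(InfeasibleError, match="maximum feasible alpha"):
            ab_k_select(dd, ABKConfig(alpha=3, beta=0))

    def test_greedy_always_satisfies_constraints(self):
        rng = np.random.default_rng(17)
        for trial in range(10):
            codes = rng.integers(0, 3, size=(8, 6))
            labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
            dd = _discrete(codes, labels)
            for alpha, beta in ((1, 0), (2, 0), (1, 1)):
                try:
                    sel = ab_k_select(dd, ABKConfig(alpha=alpha, beta=beta))
                except InfeasibleError:
                    continue
                assert verify_ab_constraints(dd, sel, alpha, beta)

    def test_beta_constraint_enforced(self):
        # feature 0 separates classes; feature 1 is constant within classes
        codes = [[0, 0], [0, 0], [1, 1], [1, 1]]
        dd = _discrete(codes, [0, 0, 1, 1])
        sel = ab_k_select(dd, ABKConfig(alpha=1, beta=2))
        assert verify_ab_constraints(dd, sel, 1, 2)
        assert sel == {0, 1}


class TestConsolidate:
    @pytest.mark.parametrize("mode,expected", [
        ("union", {1, 2, 3}),
        ("intersection", {2}),
    ])
    def test_set_identities(self, mode, expected):
        assert consolidate_features([{1, 2}, {2, 3}], mode) == expected

    @pytest.mark.parametrize("mode", ["union", "intersection"])
    def test_single_set_identity(self, mode):
        assert consolidate_features([{4, 7}], mode) == {4, 7}

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            consolidate_features([], "union")


class TestToyInstances:
    def test_certified_minimum_matches_independent_enumeration(self):
        inst = gen_toy_abk_instance(seed=0)
        oracle = _oracle_min_cardinality(inst.dataset, inst.alpha, inst.beta)
        assert inst.minimum_cardinality == oracle

    def test_single_discriminator_instance(self):
        codes = [[0, 1], [0, 0], [1, 1], [1, 0]]
        dd = _discrete(codes, [0, 0, 1, 1])
        exact = ab_k_select(dd, ABKConfig(alpha=1, solver="exhaustive"))
        assert exact == {0}
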