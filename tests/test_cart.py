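"""Gini arithmetic, tree growth, determinism and an independent CART
cross-check."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from pilotcalls.cart import (PREDICTORS, TreeConfig, classify, classify_table,
                             fit_tree, gini_impurity, global_gini, render_tree,
                             tree_to_dict)


def _table(n, **overrides):
    base = {"dur_s": 0.5, "bw_hz": 1000.0, "peak_hz": 3000.0, "range_ratio": 1.5,
            "trend_ratio": 1.0, "n_inflections": 0, "n_segments": 1, "n_elements": 1}
    rows = []
    for i in range(n):
        row = dict(base)
        for k, v in overrides.items():
            row[k] = v[i] if hasattr(v, "__len__") else v
        rows.append(row)
    return pd.DataFrame(rows)


class TestGiniImpurity:
    def test_balanced_two_class(self):
        assert gini_impurity([10, 10]) == pytest.approx(0.5)

    def test_pure_node(self):
        assert gini_impurity([10, 0]) == 0.0

    def test_three_class_hand_computation(self):
        assert gini_impurity([6, 3, 1]) == pytest.approx(0.54)

    def test_empty_node_rejected(self):
        with pytest.raises(ValueError):
            gini_impurity([0, 0])

    @given(st.lists(st.integers(0, 50), min_size=2, max_size=6).filter(lambda c: sum(c) > 0))
    def test_permutation_invariant_and_bounded(self, counts):
        g = gini_impurity(counts)
        assert g == pytest.approx(gini_impurity(list(reversed(counts))))
        assert 0 <= g <= 1 - 1 / len(counts) + 1e-12


class TestFitTree:
    def test_inflection_separable_types(self):
        X = _table(20, n_inflections=[0] * 10 + [10] * 10)
        y = ["low"] * 10 + ["high"] * 10
        tree = fit_tree(X, y)
        assert tree.split_feature == "Inflec"
        assert tree.left.gini == 0.0 and tree.right.gini == 0.0
        assert classify_table(tree, X) == y

    def test_one_sample_per_class_pure_leaves(self):
        X = _table(3, dur_s=[0.2, 0.5, 0.9])
        tree = fit_tree(X, ["a", "b", "c"], TreeConfig(min_leaf=1))
        leaves = [nd for nd in tree.nodes() if nd.is_leaf]
        assert all(leaf.gini == 0.0 for leaf in leaves)
        assert len(leaves) == 3

    def test_single_class_trivial_leaf_with_warning(self):
        with pytest.warns(UserWarning, match="single class"):
            tree = fit_tree(_table(5), ["a"] * 5)
        assert tree.is_leaf and tree.predicted_type == "a"

    def test_auxiliary_frequency_columns_rejected(self):
        X = _table(4)
        X["f_min_hz"] = 1000.0
        with pytest.raises(ValueError, match="auxiliary"):
            fit_tree(X, ["a", "a", "b", "b"])

    def test_refit_identical(self, rng):
        X = _table(40, dur_s=rng.uniform(0.2, 1.2, 40).round(2),
                   n_elements=rng.integers(1, 5, 40))
        y = rng.choice(["a", "b", "c"], 40)
        t1, t2 = fit_tree(X, y), fit_tree(X, y)
        assert tree_to_dict(t1) == tree_to_dict(t2)

    def test_splits_strictly_decrease_child_impurity(self, rng):
        X = _table(60, dur_s=rng.uniform(0.2, 1.2, 60), bw_hz=rng.uniform(0, 4000, 60))
        y = rng.choice(["a", "b", "c"], 60)
        tree = fit_tree(X, y)
        for nd in tree.nodes():
            if not nd.is_leaf:
                child = (nd.left.n * nd.left.gini + nd.right.n * nd.right.gini) / nd.n
                assert child < nd.gini
                assert nd.left.n + nd.right.n == nd.n

    def test_matches_sklearn_training_accuracy(self, rng):
        """Independent CART cross-check: on cleanly separable data both
        implementations should classify the training set perfectly."""
        from sklearn.tree import DecisionTreeClassifier
        X = _table(30, dur_s=np.r_[rng.uniform(0.1, 0.4, 15), rng.uniform(0.8, 1.2, 15)],
                   n_segments=np.r_[np.ones(15), np.full(15, 3)])
        y = ["a"] * 15 + ["b"] * 15
        ours = fit_tree(X, y)
        skl = DecisionTreeClassifier(criterion="gini", random_state=0).fit(
            X.to_numpy(float), y)
        assert classify_table(ours, X) == list(skl.predict(X.to_numpy(float))) == y


class TestGlobalGini:
    def test_single_pure_leaf_zero(self):
        with pytest.warns(UserWarning):
            tree = fit_tree(_table(4), ["a"] * 4)
        assert global_gini(tree) == 0.0

    def test_three_node_tree_is_one_sixth(self):
        X = _table(20, n_inflections=[0] * 10 + [10] * 10)
        tree = fit_tree(X, ["low"] * 10 + ["high"] * 10)
        assert global_gini(tree, "all") == pytest.approx(1 / 6, abs=1e-12)
        assert global_gini(tree, "internal") == pytest.approx(0.5)
        assert global_gini(tree, "leaves") == 0.0

    def test_weighted_variant(self):
        X = _table(20, n_inflections=[0] * 10 + [10] * 10)
        tree = fit_tree(X, ["low"] * 10 + ["high"] * 10)
        # root n=20 gini .5, two leaves n=10 gini 0 -> weighted = 10/40
        assert global_gini(tree, "all", weighted=True) == pytest.approx(0.25)


class TestClassify:
    @pytest.fixture
    def toy_tree(self):
        X = _table(20, n_inflections=[0] * 10 + [10] * 10)
        return fit_tree(X, ["low"] * 10 + ["high"] * 10)

    def test_training_sample_goes_to_its_leaf(self, toy_tree):
        row = _table(1, n_inflections=0).iloc[0]
        label, path = classify(toy_tree, row)
        assert label == "low"
        assert path == ["Inflec < 5"]

    def test_high_inflection_routed_high(self, toy_tree):
        label, _ = classify(toy_tree, _table(1, n_inflections=10).iloc[0])
        assert label == "high"

    def test_missing_predictor_named(self, toy_tree):
        with pytest.raises(KeyError, match="Inflec"):
            classify(toy_tree, {"Dur": 0.5})

    def test_batch_prediction_count(self, toy_tree):
        X = _table(7, n_inflections=[0, 10, 0, 10, 0, 10, 0])
        assert len(classify_table(toy_tree, X)) == 7

    def test_render_mentions_split(self, toy_tree):
        text = render_tree(toy_tree)
        assert "Inflec < 5" in text and "leaf" in text
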