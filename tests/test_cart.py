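import numpy as np
import pytest

from dilitree.cart import (
    TreeModel,
    TreeParams,
    best_split,
    gini_impurity,
    grow_tree,
    predict,
    rule_classifier,
    select_depth_by_cv,
)

from _reference_cart import ref_best_split, ref_grow, same_tree

UNCONSTRAINED = TreeParams(max_depth=None, min_split=2, min_leaf=1, min_rel_decrease=0.0)


class TestGini:
    def test_pure_node(self):
        assert gini_impurity((10, 0)) == 0.0

    def test_maximal(self):
        assert gini_impurity((5, 5)) == 0.5

    def test_cohort_proportion(self):
        assert gini_impurity((432, 220)) == pytest.approx(0.4471, abs=1e-4)

    def test_empty_node_error(self):
        with pytest.raises(ValueError):
            gini_impurity((0, 0))


class TestBestSplit:
    def test_textbook_example(self):
        found = best_split(np.array([1, 2, 3, 10, 11, 12.0]), [0, 0, 0, 1, 1, 1])
        assert found == (0, 6.5, 3.0)

    def test_constant_feature(self):
        assert best_split(np.ones(10), [0, 1] * 5) is None

    def test_pure_labels(self):
        assert best_split(np.arange(10.0), [1] * 10) is None

    def test_separating_feature_chosen(self, rng):
        noise = rng.normal(size=40)
        sep = np.r_[np.zeros(20), np.ones(20)]
        y = sep.astype(int)
        X = np.column_stack([noise, sep])
        found = best_split(X, y)
        ref = ref_best_split(X.tolist(), list(y))
        assert found[0] == 1 == ref[0]
        assert found[1] == ref[1]

    def test_matches_bruteforce_on_random_instance(self, rng):
        X = rng.normal(size=(200, 6))
        y = rng.integers(0, 2, size=200)
        found = best_split(X, y)
        ref = ref_best_split(X.tolist(), list(map(int, y)))
        assert found[0] == ref[0]
        assert found[1] == ref[1]
        assert found[2] == pytest.approx(ref[2], rel=1e-9)

    def test_min_leaf_respected(self, rng):
        X = rng.normal(size=(30, 2))
        y = rng.integers(0, 2, size=30)
        found = best_split(X, y, min_leaf=10)
        if found is not None:
            col = X[:, found[0]]
            assert (col < found[1]).sum() >= 10
            assert (col >= found[1]).sum() >= 10

    def test_nan_rejected(self):
        X = np.array([[1.0], [np.nan]])
        with pytest.raises(ValueError, match="NaN"):
            best_split(X, [0, 1])


class TestGrowPredict:
    def test_separable_depth_one(self):
        X = np.r_[np.zeros(50), np.ones(50)][:, None]
        y = np.r_[np.zeros(50, int), np.ones(50, int)]
        model = grow_tree(X, y, UNCONSTRAINED)
        assert model.depth() == 1
        assert (predict(model, X) == y).all()

    def test_pure_labels_single_leaf(self):
        model = grow_tree(np.arange(30.0)[:, None], np.ones(30, int), UNCONSTRAINED)
        assert model.root.is_leaf
        assert all(v == 0.0 for v in model.importance.values())

    def test_memorization_when_unconstrained(self, rng):
        X = rng.normal(size=(80, 4))
        y = rng.integers(0, 2, size=80)
        model = grow_tree(X, y, UNCONSTRAINED)
        assert (predict(model, X) == y).all()

    def test_boundary_value_goes_right(self):
        X = np.array([[1.0], [2.0], [3.0], [10.0], [11.0], [12.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        model = grow_tree(X, y, UNCONSTRAINED)
        thr = model.root.threshold
        assert predict(model, np.array([[thr]]))[0] == 1

    def test_root_only_majority_positive(self):
        model = grow_tree(np.zeros((10, 1)), np.r_[np.ones(6, int), np.zeros(4, int)],
                          UNCONSTRAINED)
        assert (predict(model, np.zeros((5, 1))) == 1).all()

    def test_leaf_tie_breaks_positive(self):
        model = grow_tree(np.zeros((4, 1)), np.array([1, 1, 0, 0]), UNCONSTRAINED)
        assert model.root.predicted_class == 1

    def test_missing_feature_column_named(self, rng):
        import pandas as pd

        X = pd.DataFrame({"a": rng.normal(size=20), "b": rng.normal(size=20)})
        y = rng.integers(0, 2, size=20)
        model = grow_tree(X, y, UNCONSTRAINED)
        with pytest.raises(KeyError, match="b"):
            predict(model, pd.DataFrame({"a": [1.0]}))

    def test_matches_reference_tree(self, rng):
        X = rng.normal(size=(200, 5))
        y = rng.integers(0, 2, size=200)
        params = TreeParams(max_depth=3, min_split=2, min_leaf=1, min_rel_decrease=0.0)
        model = grow_tree(X, y, params)
        ref = ref_grow(X.tolist(), list(map(int, y)), max_depth=3)
        assert same_tree(ref, model.root)

    def test_empty_input_error(self):
        with pytest.raises(ValueError):
            grow_tree(np.empty((0, 1)), [], UNCONSTRAINED)


class TestTreeInvariants:
    def fit_random(self, seed, **kw):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(150, 4))
        y = (X[:, 0] + 0.5 * rng.normal(size=150) > 0).astype(int)
        return X, y, grow_tree(X, y, TreeParams(**{"max_depth": 4, "min_split": 2,
                                                   "min_leaf": 1,
                                                   "min_rel_decrease": 0.0, **kw}))

    def test_children_counts_sum_to_parent(self):
        _, _, model = self.fit_random(1)

        def check(node):
            if node.is_leaf:
                return
            assert node.class_counts[0] == node.left.class_counts[0] + node.right.class_counts[0]
            assert node.class_counts[1] == node.left.class_counts[1] + node.right.class_counts[1]
            check(node.left)
            check(node.right)

        check(model.root)

    def test_gini_consistent_with_counts(self):
        _, _, model = self.fit_random(2)

        def check(node):
            assert node.gini == pytest.approx(gini_impurity(node.class_counts), abs=1e-12)
            if not node.is_leaf:
                check(node.left)
                check(node.right)

        check(model.root)

    def test_importance_nonnegative_and_unused_zero(self):
        _, _, model = self.fit_random(3)
        used = set()

        def walk(node):
            if not node.is_leaf:
                used.add(node.split_feature)
                walk(node.left)
                walk(node.right)

        walk(model.root)
        for name, value in model.importance.items():
            assert value >= 0.0
            if name not in used:
                assert value == 0.0

    def test_importance_conservation(self):
        X, y, model = self.fit_random(4)
        n = len(y)

        def total_decrease(node):
            if node.is_leaf:
                return 0.0
            dec = (
                sum(node.class_counts) * node.gini
                - sum(node.left.class_counts) * node.left.gini
                - sum(node.right.class_counts) * node.right.gini
            )
            return dec + total_decrease(node.left) + total_decrease(node.right)

        assert sum(model.importance.values()) == pytest.approx(
            total_decrease(model.root) / n, rel=1e-9
        )

    def test_monotone_capacity(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(200, 4))
        y = rng.integers(0, 2, size=200)
        accs = []
        for depth in (1, 2, 3, 5, 8):
            model = grow_tree(X, y, TreeParams(depth, 2, 1, 0.0))
            accs.append((predict(model, X) == y).mean())
        assert accs == sorted(accs)

    def test_permutation_determinism(self, rng):
        X = rng.normal(size=(120, 4))
        y = rng.integers(0, 2, size=120)
        perm = rng.permutation(120)
        a = grow_tree(X, y, TreeParams(3, 2, 1, 0.0))
        b = grow_tree(X[perm], y[perm], TreeParams(3, 2, 1, 0.0))
        assert a.to_json() == b.to_json()

    def test_json_roundtrip_lossless(self):
        _, _, model = self.fit_random(6)
        restored = TreeModel.from_json(model.to_json())
        assert restored.to_json() == model.to_json()
        assert restored.root.threshold == model.root.threshold


class TestDepthSelection:
    def test_depth_one_rule_recovered(self):
        rng = np.random.default_rng(0)
        x = np.r_[rng.normal(-4, 0.5, 250), rng.normal(4, 0.5, 250)]
        y = np.r_[np.zeros(250, int), np.ones(250, int)]
        X = np.column_stack([x, rng.normal(size=500)])
        depth, table = select_depth_by_cv(
            X, y, depth_grid=(1, 2, 3, 4, 5), seed=7,
            params=TreeParams(None, 2, 1, 0.0),
        )
        assert depth == 1

    def test_single_depth_grid(self, rng):
        X = rng.normal(size=(60, 2))
        y = rng.integers(0, 2, size=60)
        depth, _ = select_depth_by_cv(X, y, depth_grid=(3,), seed=0,
                                      params=TreeParams(None, 2, 1, 0.0))
        assert depth == 3

    def test_same_seed_same_table(self, rng):
        X = rng.normal(size=(80, 2))
        y = rng.integers(0, 2, size=80)
        _, t1 = select_depth_by_cv(X, y, (1, 2), seed=3)
        _, t2 = select_depth_by_cv(X, y, (1, 2), seed=3)
        assert t1.equals(t2)

    def test_too_many_folds_error(self):
        y = np.r_[np.ones(3, int), np.zeros(50, int)]
        X = np.random.default_rng(0).normal(size=(53, 2))
        with pytest.raises(ValueError, match="fewer"):
            select_depth_by_cv(X, y, (1, 2), k=5, seed=0)


class TestRuleClassifier:
    def test_boundary_positive(self):
        assert rule_classifier(7.4) == "positive"

    def test_second_node_negative(self):
        assert rule_classifier(7.0, -1.0) == "negative"

    def test_indeterminate(self):
        assert rule_classifier(7.0, 0.5) == "indeterminate"
        assert rule_classifier(7.0, None) == "indeterminate"

    def test_strict_mode_maps_to_negative(self):
        assert rule_classifier(7.0, 0.5, strict_two_class=True) == "negative"

    def test_nonfinite_error(self):
        with pytest.raises(ValueError):
            rule_classifier(float("nan"))
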