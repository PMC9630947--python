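import numpy as np
import pandas as pd
import pytest

from matchexplain.cart_engine import (
    FittedTree,
    Split,
    TreeControl,
    TreeNode,
    best_split,
    cost_complexity_sequence,
    cross_validated_error,
    export_dot,
    gini_impurity,
    grow_tree,
    predict,
    predict_probability,
    prune,
    tree_from_json,
    tree_to_json,
)
from _oracles import enumerate_pruned_subtrees, exhaustive_best_split

LOOSE = TreeControl(minsplit=2, minbucket=1, cp_grow=1e-9, n_folds=2)


def make_stump(n_in_left=2, n_out_right=2):
    """Hand-built 4-subject stump: root (2,2), pure children."""
    root = TreeNode(n_in=2, n_out=2, depth=0,
                    split=Split("x", "continuous", threshold=0.5))
    root.left = TreeNode(n_in=2, n_out=0, depth=1)
    root.right = TreeNode(n_in=0, n_out=2, depth=1)
    return FittedTree(root=root, feature_names=("x",),
                      feature_kinds={"x": "continuous"}, n_total=4)


class TestGini:
    @pytest.mark.parametrize(
        "counts,expected", [((5, 0), 0.0), ((5, 5), 0.5), ((3, 1), 0.375)]
    )
    def test_reference_values(self, counts, expected):
        assert gini_impurity(counts) == pytest.approx(expected, abs=1e-12)

    def test_empty_node_rejected(self):
        with pytest.raises(ValueError):
            gini_impurity((0, 0))


class TestBestSplit:
    def test_separable_midpoint(self):
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        y = ["out", "out", "in", "in"]
        s = best_split(X, y, LOOSE)
        assert s.feature == "x" and s.threshold == pytest.approx(2.5)

    def test_constant_labels_give_none(self):
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        assert best_split(X, ["in"] * 3, LOOSE) is None

    def test_constant_covariate_gives_none(self):
        X = pd.DataFrame({"x": [2.0, 2.0, 2.0, 2.0]})
        assert best_split(X, ["in", "out", "in", "out"], LOOSE) is None

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(7)
        for trial in range(100):
            n = int(rng.integers(6, 51))
            X = pd.DataFrame(
                {
                    "u": rng.normal(size=n).round(2),
                    "v": rng.integers(0, 5, size=n).astype(float),
                    "cat": rng.choice(["a", "b", "c", "d"], size=n),
                }
            )
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                continue
            got = best_split(X, y, LOOSE)
            cols = [
                ("u", "continuous", X["u"].tolist()),
                ("v", "continuous", X["v"].tolist()),
                ("cat", "categorical", X["cat"].tolist()),
            ]
            want = exhaustive_best_split(cols, y.tolist(), minbucket=1)
            if want is None or want[0] <= 1e-12:
                continue
            assert got is not None, trial
            # recompute the achieved decrease of the returned split
            if got.kind == "continuous":
                mask = X[got.feature] < got.threshold
            else:
                mask = X[got.feature].isin(got.left_levels)
            p = y.mean()
            g0 = 1 - p * p - (1 - p) * (1 - p)

            def gini(v):
                if len(v) == 0:
                    return 0.0
                q = np.mean(v)
                return 1 - q * q - (1 - q) * (1 - q)

            dec = g0 - (
                mask.sum() * gini(y[mask]) + (~mask).sum() * gini(y[~mask])
            ) / n
            assert dec == pytest.approx(want[0], abs=1e-10), trial


class TestGrowTree:
    def test_two_stratum_cohort_exact(self):
        # ages < 50 all out, >= 50 all in
        X = pd.DataFrame({"age": [30.0, 35, 40, 45, 55, 60, 65, 70]})
        y = ["out"] * 4 + ["in"] * 4
        t = grow_tree(X, y, LOOSE)
        assert t.n_leaves == 2
        assert t.root.split.feature == "age"
        assert t.root.split.threshold == pytest.approx(50.0)
        assert t.root.left.probability == 0.0
        assert t.root.right.probability == 1.0

    def test_maxdepth_zero_gives_root_only(self):
        X = pd.DataFrame({"x": np.arange(10.0)})
        y = ["in"] * 4 + ["out"] * 6
        t = grow_tree(X, y, TreeControl(minsplit=2, minbucket=1, maxdepth=0))
        assert t.root.is_leaf
        assert t.root.probability == pytest.approx(0.4)

    def test_no_admissible_split_gives_root_only(self):
        X = pd.DataFrame({"x": [1.0] * 10})
        y = ["in"] * 5 + ["out"] * 5
        t = grow_tree(X, y, LOOSE)
        assert t.root.is_leaf

    def test_leaf_counts_partition_parent(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(
            {"a": rng.normal(size=300), "c": rng.choice(list("pqr"), 300)}
        )
        y = (rng.random(300) < 0.3 + 0.4 * (X["a"] > 0)).astype(int)
        t = grow_tree(X, y, TreeControl(minsplit=10, minbucket=5, cp_grow=0.001))
        for node in t.nodes():
            if not node.is_leaf:
                assert node.n_in == node.left.n_in + node.right.n_in
                assert node.n_out == node.left.n_out + node.right.n_out
                assert node.left.n >= 5 and node.right.n >= 5

    def test_training_set_prediction_reproduces_leaf_counts(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"a": rng.normal(size=200)})
        y = (rng.random(200) < 0.2 + 0.6 * (X["a"] > 0.3)).astype(int)
        t = grow_tree(X, y, TreeControl(minsplit=10, minbucket=5))
        probs, labels, flags = predict(t, X)
        assert not flags.any()
        for leaf in t.leaves():
            members = np.flatnonzero(np.isclose(probs, leaf.probability))
            # members of other identical-probability leaves may join; check
            # totals instead
        totals = {}
        for p in probs:
            totals[round(p, 12)] = totals.get(round(p, 12), 0) + 1
        leaf_totals = {}
        for leaf in t.leaves():
            key = round(leaf.probability, 12)
            leaf_totals[key] = leaf_totals.get(key, 0) + leaf.n
        assert totals == leaf_totals


class TestPruning:
    def test_stump_alpha_ladder(self):
        seq = cost_complexity_sequence(make_stump())
        assert seq.alphas == [0.0, 0.5]
        assert seq.subtrees[0].n_leaves == 2
        assert seq.subtrees[1].root.is_leaf

    def test_prune_at_reference_cps(self):
        stump = make_stump()
        assert prune(stump, 0.0).n_leaves == 2
        assert prune(stump, 0.4).n_leaves == 2
        assert prune(stump, 0.6).root.is_leaf
        assert prune(stump, 1.0).root.is_leaf

    def test_root_only_sequence(self):
        X = pd.DataFrame({"x": [1.0] * 6})
        t = grow_tree(X, ["in", "out"] * 3, LOOSE)
        seq = cost_complexity_sequence(t)
        assert seq.alphas == [0.0]

    def _random_tree(self, rng, n_internal_max=10):
        n = int(rng.integers(20, 80))
        n_in = int(rng.integers(1, n))
        budget = [int(rng.integers(0, n_internal_max + 1))]

        def build(n_in, n_out, depth):
            node = TreeNode(n_in=n_in, n_out=n_out, depth=depth)
            if budget[0] > 0 and n_in + n_out >= 2 and rng.random() < 0.8:
                budget[0] -= 1
                li = int(rng.integers(0, n_in + 1))
                lo = int(rng.integers(0, n_out + 1))
                if (li + lo == 0) or (li == n_in and lo == n_out):
                    return node
                node.split = Split("x", "continuous", threshold=0.0)
                node.left = build(li, lo, depth + 1)
                node.right = build(n_in - li, n_out - lo, depth + 1)
            return node

        root = build(n_in, n - n_in, 0)
        return FittedTree(root=root, feature_names=("x",),
                          feature_kinds={"x": "continuous"}, n_total=n)

    def test_prune_minimizes_cost_over_all_subtrees(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            tree = self._random_tree(rng)
            options = enumerate_pruned_subtrees(tree.root)
            seq = cost_complexity_sequence(tree)
            assert all(
                b > a + 1e-15 for a, b in zip(seq.alphas, seq.alphas[1:])
            )
            self._assert_nested(seq)
            for cp in rng.uniform(0, 0.6, size=10):
                chosen = seq.subtree_for(cp)
                cost = chosen.risk() + cp * chosen.n_leaves
                best = min(r / tree.n_total + cp * l for r, l in options)
                assert cost == pytest.approx(best, abs=1e-10)

    @staticmethod
    def _assert_nested(seq):
        def is_subtree(small, big):
            if small.is_leaf:
                return True
            if big.is_leaf:
                return False
            return is_subtree(small.left, big.left) and is_subtree(
                small.right, big.right
            )

        for a, b in zip(seq.subtrees[1:], seq.subtrees[:-1]):
            assert is_subtree(a.root, b.root)


class TestCrossValidation:
    def test_separable_data_near_zero_error(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=200)
        X = pd.DataFrame({"x": x})
        y = (x > 0).astype(int)
        ctl = TreeControl(minsplit=10, minbucket=5, n_folds=5, seed=1)
        curve = cross_validated_error(X, y, ctl)
        assert curve.errors.min() < 0.05
        tree = prune(grow_tree(X, y, ctl), curve.cp_at_min())
        assert not tree.root.is_leaf

    def test_pure_noise_error_near_base_rate(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame({"x": rng.normal(size=400)})
        y = (rng.random(400) < 0.3).astype(int)
        ctl = TreeControl(seed=2)
        curve = cross_validated_error(X, y, ctl)
        base = min(y.mean(), 1 - y.mean())
        i = int(np.argmin(curve.errors))
        assert curve.errors[i] <= base + 3 * curve.std_errors[i]

    def test_same_seed_same_curve(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame({"x": rng.normal(size=150)})
        y = (rng.random(150) < 0.4 + 0.3 * (X["x"] > 0)).astype(int)
        ctl = TreeControl(minsplit=10, minbucket=5, seed=9)
        a = cross_validated_error(X, y, ctl)
        b = cross_validated_error(X, y, ctl)
        assert np.array_equal(a.errors, b.errors)
        assert np.array_equal(a.cps, b.cps)

    def test_tiny_minority_class_raises(self):
        X = pd.DataFrame({"x": np.arange(10.0)})
        y = [1] + [0] * 9
        with pytest.raises(ValueError, match="class"):
            cross_validated_error(
                X, y, TreeControl(minsplit=2, minbucket=1, n_folds=5)
            )


class TestPredictAndExport:
    def test_leaf_probability_and_label(self):
        stump = make_stump()
        p, label = predict_probability(stump, {"x": 0.2})
        assert p == 1.0 and label == "in"
        p, label = predict_probability(stump, {"x": 0.9})
        assert p == 0.0 and label == "out"

    def test_root_only_constant_prediction(self):
        X = pd.DataFrame({"x": [1.0] * 8})
        t = grow_tree(X, ["in"] * 6 + ["out"] * 2, LOOSE)
        probs, labels, _ = predict(t, pd.DataFrame({"x": [0.0, 5.0, -3.0]}))
        assert np.allclose(probs, 0.75)
        assert all(labels == "in")

    def test_unseen_level_routed_to_majority_child_and_flagged(self):
        X = pd.DataFrame({"c": ["a"] * 6 + ["b"] * 3})
        y = ["in"] * 6 + ["out"] * 3
        t = grow_tree(X, y, LOOSE)
        assert not t.root.is_leaf
        probs, labels, flags = predict(t, pd.DataFrame({"c": ["zzz"]}))
        assert flags[0]
        bigger = (t.root.left if t.root.left.n >= t.root.right.n
                  else t.root.right)
        assert probs[0] == pytest.approx(bigger.probability)

    def test_dot_node_count_and_annotations(self):
        import re

        stump = make_stump()
        dot = export_dot(stump)
        node_lines = re.findall(r"^\s*n\d+ \[label=", dot, flags=re.M)
        assert len(node_lines) == 3
        assert "1.00" in dot and "0.00" in dot and "50%" in dot and "100%" in dot

    def test_json_round_trip(self):
        X = pd.DataFrame({"a": np.arange(20.0),
                          "c": ["u", "v"] * 10})
        y = ["out"] * 10 + ["in"] * 10
        t = grow_tree(X, y, LOOSE)
        back = tree_from_json(tree_to_json(t))
        probs_a, labels_a, _ = predict(t, X)
        probs_b, labels_b, _ = predict(back, X)
        assert np.array_equal(probs_a, probs_b)
        assert np.array_equal(labels_a, labels_b)
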