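import numpy as np
import pandas as pd
import pytest

from wearhar.forest import (
    Forest,
    TrainConfig,
    Tree,
    count_split_nodes,
    forest_from_dict,
    forest_to_dict,
    importance,
    load_forest,
    predict_proba,
    save_forest,
    select_reduced_features,
    train,
    tree_shape,
)


def _blobs(n=100, seed=0, separation=6.0):
    """Two well-separated Gaussian blobs in 2 features."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, (n // 2, 2))
    b = rng.normal(separation, 1.0, (n // 2, 2))
    X = pd.DataFrame(np.vstack([a, b]), columns=["f0", "f1"])
    y = np.array(["a"] * (n // 2) + ["b"] * (n // 2), dtype=object)
    return X, y


def _noisy_multiclass(n_per_class=120, n_classes=3, n_features=4, seed=5,
                      separation=0.6):
    """Heavily overlapping classes: trees always grow to the split cap."""
    rng = np.random.default_rng(seed)
    frames, labels = [], []
    for c in range(n_classes):
        frames.append(rng.normal(c * separation, 1.0, (n_per_class, n_features)))
        labels += [f"c{c}"] * n_per_class
    X = pd.DataFrame(np.vstack(frames),
                     columns=[f"f{i}" for i in range(n_features)])
    return X, np.array(labels, dtype=object)


class TestTrain:
    def test_split_cap_bounds_tree_size(self):
        X, y = _noisy_multiclass()
        f = train(X, y, TrainConfig(max_splits=5, seed=1))
        for t in f.trees:
            assert t.split_count <= 5
            assert t.node_count <= 11
            assert t.leaf_count <= 6
            assert t.node_count == 2 * t.split_count + 1

    def test_separable_blobs_reach_perfect_training_accuracy(self):
        X, y = _blobs(n=100, seed=3)
        # brute-force oracle: a single threshold on f0 separates the blobs
        assert X[y == "a"]["f0"].max() < X[y == "b"]["f0"].min()
        f = train(X, y, TrainConfig(seed=2))
        assert (f.predict(X) == y).mean() == 1.0

    def test_single_class_degenerate_forest(self):
        X = pd.DataFrame({"f0": [1.0, 2.0, 3.0, 4.0]})
        y = np.array(["only"] * 4, dtype=object)
        f = train(X, y, TrainConfig(seed=0))
        assert f.degenerate
        proba = f.predict_proba(X)
        assert np.all(proba == 1.0)
        assert list(f.predict(X)) == ["only"] * 4

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            train(pd.DataFrame({"f0": []}), np.array([], dtype=object),
                  TrainConfig())

    def test_seeded_determinism(self):
        X, y = _noisy_multiclass(seed=9)
        a = train(X, y, TrainConfig(seed=77))
        b = train(X, y, TrainConfig(seed=77))
        assert forest_to_dict(a) == forest_to_dict(b)
        c = train(X, y, TrainConfig(seed=78))
        assert forest_to_dict(a) != forest_to_dict(c)

    def test_leaf_probabilities_sum_to_one(self):
        X, y = _noisy_multiclass()
        f = train(X, y, TrainConfig(seed=4))
        for t in f.trees:
            for nd in t.nodes:
                if nd["feature"] is None:
                    assert sum(nd["probs"]) == pytest.approx(1.0)


def _brute_force_proba(forest: Forest, row: dict) -> np.ndarray:
    """Independent oracle: recursive per-tree traversal, then averaging."""

    def walk(tree: Tree, i: int):
        nd = tree.nodes[i]
        if nd["feature"] is None:
            return np.asarray(nd["probs"], dtype=float)
        child = nd["left"] if row[nd["feature"]] <= nd["threshold"] else nd["right"]
        return walk(tree, child)

    per_tree = [walk(t, 0) for t in forest.trees]
    mean = np.mean(per_tree, axis=0)
    return mean / mean.sum()


class TestPredictProba:
    def test_matches_per_tree_brute_force(self):
        X, y = _noisy_multiclass(seed=2)
        f = train(X, y, TrainConfig(seed=13))
        for i in range(20):
            row = X.iloc[i].to_dict()
            assert np.allclose(predict_proba(f, row), _brute_force_proba(f, row))

    def test_probabilities_normalized(self):
        X, y = _noisy_multiclass(seed=8)
        f = train(X, y, TrainConfig(seed=3))
        proba = f.predict_proba(X)
        assert np.all(proba >= 0)
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_single_tree_forest_equals_its_leaf_distribution(self):
        X, y = _noisy_multiclass(seed=4)
        f = train(X, y, TrainConfig(n_trees=1, seed=6))
        row = X.iloc[0].to_dict()
        only_tree = Forest([f.trees[0]], f.feature_names, f.classes, f.config)
        assert np.allclose(predict_proba(f, row),
                           predict_proba(only_tree, row))

    def test_missing_feature_rejected(self):
        X, y = _blobs()
        f = train(X, y, TrainConfig(seed=1))
        with pytest.raises(KeyError):
            predict_proba(f, {"f0": 1.0})


def _single_feature_forest():
    """Hand-built forest whose only split is on feature 'f'."""
    nodes = [
        {"feature": "f", "threshold": 0.5, "left": 1, "right": 2,
         "n": 100.0, "impurity": 0.5, "probs": None},
        {"feature": None, "threshold": None, "left": None, "right": None,
         "n": 50.0, "impurity": 0.0, "probs": [1.0, 0.0]},
        {"feature": None, "threshold": None, "left": None, "right": None,
         "n": 50.0, "impurity": 0.0, "probs": [0.0, 1.0]},
    ]
    return Forest([Tree(nodes)], ["f", "g"], ["a", "b"], TrainConfig())


class TestImportance:
    def test_single_feature_carries_all_mass(self):
        ranking = dict(importance(_single_feature_forest()))
        assert ranking["f"] == pytest.approx(1.0)
        assert ranking["g"] == 0.0

    def test_scores_sum_to_one_and_sorted(self):
        X, y = _noisy_multiclass(seed=3)
        f = train(X, y, TrainConfig(seed=21))
        ranked = importance(f)
        scores = [s for _, s in ranked]
        assert sum(scores) == pytest.approx(1.0)
        assert scores == sorted(scores, reverse=True)

    def test_matches_sklearn_on_single_tree(self):
        """Cross-check impurity-decrease accounting against sklearn."""
        from sklearn.tree import DecisionTreeClassifier

        X, y = _noisy_multiclass(seed=12)
        clf = DecisionTreeClassifier(max_leaf_nodes=6, random_state=0)
        clf.fit(X.to_numpy(), y)
        from wearhar.forest import _sklearn_to_tree

        tree = _sklearn_to_tree(clf, list(X.columns), list(clf.classes_),
                                sorted(set(y)))
        mine = dict(importance(Forest([tree], list(X.columns),
                                      sorted(set(y)), TrainConfig())))
        theirs = dict(zip(X.columns, clf.feature_importances_))
        for name in X.columns:
            assert mine[name] == pytest.approx(theirs[name], abs=1e-9)

    def test_untrained_forest_rejected(self):
        with pytest.raises(ValueError):
            importance(Forest([], ["f"], ["a"], TrainConfig()))


class TestSelectReducedFeatures:
    def test_single_sufficient_feature_gives_size_one(self):
        rng = np.random.default_rng(0)
        n = 200
        informative = np.r_[rng.normal(0, 1, n // 2), rng.normal(8, 1, n // 2)]
        X = pd.DataFrame({
            "signal": informative,
            "noise1": rng.normal(0, 1, n),
            "noise2": rng.normal(0, 1, n),
        })
        y = np.array(["a"] * (n // 2) + ["b"] * (n // 2), dtype=object)
        subset = select_reduced_features(X, y, TrainConfig(seed=5),
                                         n_splits=20)
        assert subset == ["signal"]

    def test_cap_binds(self):
        X, y = _noisy_multiclass(seed=6, n_features=6, separation=0.3)
        subset = select_reduced_features(X, y, TrainConfig(seed=7),
                                         cap=3, tolerance=0.0, n_splits=10)
        assert len(subset) <= 3

    def test_never_more_than_eight(self):
        X, y = _noisy_multiclass(seed=7, n_features=12, separation=0.2)
        subset = select_reduced_features(X, y, TrainConfig(seed=8),
                                         tolerance=0.0, n_splits=10)
        assert 1 <= len(subset) <= 8


class TestStructuralAccounting:
    def test_fully_grown_forests_total_250_split_nodes(self):
        """5 forests x 10 trees x 5 splits when every tree saturates the cap."""
        forests = [
            train(*_noisy_multiclass(seed=s),
                  TrainConfig(max_splits=5, n_trees=10, seed=s))
            for s in range(5)
        ]
        for f in forests:
            for t in f.trees:
                assert t.split_count == 5  # cap saturated on overlapping data
        assert count_split_nodes(forests) == 250

    def test_single_leaf_tree_has_zero_splits(self):
        leaf = Tree([{"feature": None, "threshold": None, "left": None,
                      "right": None, "n": 10.0, "impurity": 0.0,
                      "probs": [1.0]}])
        f = Forest([leaf], ["f"], ["a"], TrainConfig())
        assert count_split_nodes([f]) == 0

    def test_count_equals_nodes_minus_leaves(self):
        X, y = _noisy_multiclass(seed=11)
        f = train(X, y, TrainConfig(seed=14))
        independent = sum(t.node_count - t.leaf_count for t in f.trees)
        assert count_split_nodes([f]) == independent

    def test_tree_shape_arithmetic(self):
        assert tree_shape(5) == (11, 10, 6)
        assert tree_shape(10) == (21, 20, 11)


class TestSerialization:
    def test_round_trip_bit_exact(self, tmp_path):
        X, y = _noisy_multiclass(seed=15)
        f = train(X, y, TrainConfig(seed=16))
        path = tmp_path / "forest.json"
        save_forest(f, path)
        g = load_forest(path)
        assert forest_to_dict(g) == forest_to_dict(f)
        assert np.array_equal(f.predict_proba(X), g.predict_proba(X))

    def test_dict_round_trip(self):
        X, y = _blobs(seed=17)
        f = train(X, y, TrainConfig(seed=18))
        g = forest_from_dict(forest_to_dict(f))
        assert g.feature_names == f.feature_names
        assert g.classes == f.classes
        assert g.config == f.config


def test_accuracy_saturates_with_more_trees():
    """Held-out accuracy does not degrade when growing 1 -> 10 trees."""
    X, y = _noisy_multiclass(seed=19, n_per_class=200, separation=1.0)
    rng = np.random.default_rng(20)
    idx = rng.permutation(len(X))
    tr, te = idx[: len(idx) // 2], idx[len(idx) // 2:]

    def acc(n_trees):
        f = train(X.iloc[tr], y[tr], TrainConfig(n_trees=n_trees, seed=21))
        return (f.predict(X.iloc[te]) == y[te]).mean()

    assert acc(10) >= acc(1) - 0.02
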