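"""Random forests under embedded-deployment constraints.

Trees are grown best-first by impurity decrease with a hard cap on the
number of internal (split) nodes, so a cap of 5 splits yields at most
11 nodes, 10 edges and 6 leaves — the accounting a microcontroller
implementation budgets flash for.  Individual depth-capped CARTs are fitted
with scikit-learn (``max_leaf_nodes = max_splits + 1`` reproduces exactly
this best-first, split-capped growth); bootstrap aggregation, the portable
tree representation, JSON serialization, feature importance and the
reduced-feature selection rule live here.

A trained forest is a pure data object: prediction is the arithmetic mean of
the trees' leaf class distributions, traversed on the package's own flat
node arrays, so that a serialized model reloads and predicts bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureVector


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of one embedded forest.

    Defaults follow the reduced on-board models: 10 trees, at most 5 splits
    per tree, Gini impurity, bootstrap sampling with replacement and a
    minimum split sample size of 10.  ``min_leaf_samples`` is
    classifier-specific on the device (71 / 143 / 47 / 74 for Stage 1,
    Sedentary, Moderate and Rigorous at the full training-set size).
    """

    n_trees: int = 10
    max_splits: int = 5
    min_split_samples: int = 10
    min_leaf_samples: int = 1
    criterion: str = "gini"
    seed: int = 0


#: device min-leaf sizes per classifier, in the printed order
REDUCED_MIN_LEAF = {"stage1": 71, "sedentary": 143, "moderate": 47, "rigorous": 74}


class Tree:
    """One decision tree as a flat node list.

    ``nodes[i]`` is a dict with keys ``feature`` (name, or None for a leaf),
    ``threshold``, ``left``, ``right`` (child indices), ``n`` (training
    samples reaching the node), ``impurity``, and for leaves ``probs`` (class
    distribution over the forest's class list, summing to 1).  Traversal
    sends ``x[feature] <= threshold`` to the left child.
    """

    def __init__(self, nodes: list[dict]):
        self.nodes = nodes
        self._compiled = None

    @property
    def split_count(self) -> int:
        return sum(1 for nd in self.nodes if nd["feature"] is not None)

    @property
    def leaf_count(self) -> int:
        return len(self.nodes) - self.split_count

    @property
    def node_count(self) -> int:
        return len(self.nodes)

    def _compile(self, feature_names: list[str], n_classes: int):
        if self._compiled is None:
            name_to_idx = {f: i for i, f in enumerate(feature_names)}
            n = len(self.nodes)
            feat = np.full(n, -1, dtype=int)
            thr = np.zeros(n)
            left = np.zeros(n, dtype=int)
            right = np.zeros(n, dtype=int)
            probs = np.zeros((n, n_classes))
            for i, nd in enumerate(self.nodes):
                if nd["feature"] is not None:
                    feat[i] = name_to_idx[nd["feature"]]
                    thr[i] = nd["threshold"]
                    left[i] = nd["left"]
                    right[i] = nd["right"]
                else:
                    probs[i] = nd["probs"]
            self._compiled = (feat, thr, left, right, probs)
        return self._compiled

    def leaf_probs(self, X: np.ndarray, feature_names: list[str],
                   n_classes: int) -> np.ndarray:
        """Class distribution of the leaf reached by each row of ``X``."""
        feat, thr, left, right, probs = self._compile(feature_names, n_classes)
        idx = np.zeros(len(X), dtype=int)
        while True:
            internal = feat[idx] >= 0
            if not internal.any():
                break
            rows = np.nonzero(internal)[0]
            f = feat[idx[rows]]
            go_left = X[rows, f] <= thr[idx[rows]]
            idx[rows] = np.where(go_left, left[idx[rows]], right[idx[rows]])
        return probs[idx]


@dataclass
class Forest:
    """A trained ensemble plus the metadata needed to run and audit it."""

    trees: list[Tree]
    feature_names: list[str]
    classes: list[str]
    config: TrainConfig
    degenerate: bool = False  # single-class training set

    def _as_matrix(self, X) -> np.ndarray:
        if isinstance(X, FeatureVector):
            X = X.values
        if isinstance(X, dict):
            return np.array([[float(X[f]) for f in self.feature_names]])
        if isinstance(X, pd.DataFrame):
            return X[self.feature_names].to_numpy(float)
        return np.asarray(X, dtype=float)

    def predict_proba(self, X) -> np.ndarray:
        """Mean of the trees' leaf distributions; rows sum to 1."""
        M = self._as_matrix(X)
        acc = np.zeros((len(M), len(self.classes)))
        for t in self.trees:
            acc += t.leaf_probs(M, self.feature_names, len(self.classes))
        acc /= len(self.trees)
        return acc / acc.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return np.array([self.classes[i] for i in proba.argmax(axis=1)], dtype=object)


def _sklearn_to_tree(clf: DecisionTreeClassifier, feature_names: list[str],
                     local_classes, global_classes: list[str]) -> Tree:
    t = clf.tree_
    class_pos = {c: global_classes.index(c) for c in local_classes}
    nodes = []
    for i in range(t.node_count):
        n = float(t.weighted_n_node_samples[i])
        imp = float(t.impurity[i])
        if t.children_left[i] == -1:  # leaf
            local = np.asarray(t.value[i][0], dtype=float)
            local = local / local.sum()
            probs = np.zeros(len(global_classes))
            for c, p in zip(local_classes, local):
                probs[class_pos[c]] = p
            nodes.append({"feature": None, "threshold": None, "left": None,
                          "right": None, "n": n, "impurity": imp,
                          "probs": probs.tolist()})
        else:
            nodes.append({"feature": feature_names[t.feature[i]],
                          "threshold": float(t.threshold[i]),
                          "left": int(t.children_left[i]),
                          "right": int(t.children_right[i]),
                          "n": n, "impurity": imp, "probs": None})
    return Tree(nodes)


def train(X: pd.DataFrame, y, config: TrainConfig) -> Forest:
    """Fit an embedded forest: bootstrap with replacement, capped trees.

    Same ``(X, y, config)`` always yields an identical forest.  A
    single-class training set produces a degenerate (single-leaf-tree)
    forest, flagged but usable; an empty training set is an error.
    """
    y = np.asarray(y, dtype=object)
    if len(X) == 0:
        raise ValueError("empty training set")
    if len(X) != len(y):
        raise ValueError("X and y length mismatch")
    feature_names = list(X.columns)
    classes = sorted(set(y.tolist()))
    M = X.to_numpy(float)

    rng = np.random.default_rng(config.seed)
    trees = []
    for _ in range(config.n_trees):
        idx = rng.integers(0, len(M), len(M))
        tree_seed = int(rng.integers(0, 2**31 - 1))
        clf = DecisionTreeClassifier(
            criterion=config.criterion,
            max_leaf_nodes=config.max_splits + 1,
            min_samples_split=config.min_split_samples,
            min_samples_leaf=config.min_leaf_samples,
            random_state=tree_seed,
        )
        clf.fit(M[idx], y[idx])
        trees.append(_sklearn_to_tree(clf, feature_names,
                                      list(clf.classes_), classes))
    return Forest(trees, feature_names, classes, config,
                  degenerate=(len(classes) == 1))


def predict_proba(forest: Forest, x) -> np.ndarray:
    """Class-probability vector for one feature vector (dict-like)."""
    return forest.predict_proba(x)[0]


def importance(forest: Forest) -> list[tuple[str, float]]:
    """Features ranked by normalized total impurity decrease.

    The score of a feature is the sum, over every split on it in every tree,
    of ``n * impurity - n_left * impurity_left - n_right * impurity_right``,
    normalized so scores sum to 1.  Ties are broken by feature-name order.
    """
    if not forest.trees:
        raise ValueError("untrained forest")
    scores = {f: 0.0 for f in forest.feature_names}
    for tree in forest.trees:
        for nd in tree.nodes:
            if nd["feature"] is None:
                continue
            left, right = tree.nodes[nd["left"]], tree.nodes[nd["right"]]
            decrease = (nd["n"] * nd["impurity"]
                        - left["n"] * left["impurity"]
                        - right["n"] * right["impurity"])
            scores[nd["feature"]] += decrease
    total = sum(scores.values())
    if total > 0:
        scores = {f: s / total for f, s in scores.items()}
    return sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))


def _balanced_splits(y: np.ndarray, n_splits: int, rng: np.random.Generator):
    """Repeated random 50/50 class-balanced train/test index splits."""
    by_class = {c: np.nonzero(y == c)[0] for c in sorted(set(y.tolist()))}
    splits = []
    for _ in range(n_splits):
        train_idx, test_idx = [], []
        for idx in by_class.values():
            perm = rng.permutation(idx)
            half = len(perm) // 2
            train_idx.append(perm[:half])
            test_idx.append(perm[half:])
        splits.append((np.concatenate(train_idx), np.concatenate(test_idx)))
    return splits


def _mean_split_accuracy(X: pd.DataFrame, y: np.ndarray, cols: list[str],
                         config: TrainConfig, splits, seeds) -> float:
    accs = []
    for (tr, te), s in zip(splits, seeds):
        cfg = TrainConfig(**{**asdict(config), "seed": int(s)})
        f = train(X.iloc[tr][cols], y[tr], cfg)
        accs.append(float(np.mean(f.predict(X.iloc[te][cols]) == y[te])))
    return float(np.mean(accs))


def select_reduced_features(X: pd.DataFrame, y, config: TrainConfig,
                            cap: int = 8, tolerance: float = 0.02,
                            n_splits: int = 100,
                            seed: int | None = None) -> list[str]:
    """Importance-ranked prefix selection with an accuracy-loss budget.

    Features are ranked by forest importance on the full set; the smallest
    prefix whose mean held-out accuracy (repeated random 50/50 class-balanced
    splits) is within ``tolerance`` (default 2 percentage points) of the
    full-set accuracy is returned, capped at ``cap`` (default 8) features.
    """
    y = np.asarray(y, dtype=object)
    if X.shape[1] < 1:
        raise ValueError("need at least one feature")
    ranking = [f for f, _ in importance(train(X, y, config))]

    rng = np.random.default_rng(config.seed if seed is None else seed)
    splits = _balanced_splits(y, n_splits, rng)
    seeds = rng.integers(0, 2**31 - 1, n_splits)

    cap = min(cap, X.shape[1])
    baseline = _mean_split_accuracy(X, y, list(X.columns), config, splits, seeds)
    for n in range(1, cap + 1):
        prefix = ranking[:n]
        acc = _mean_split_accuracy(X, y, prefix, config, splits, seeds)
        if acc >= baseline - tolerance:
            return prefix
    return ranking[:cap]


def count_split_nodes(forests) -> int:
    """Total internal (if-statement) nodes across all trees of all forests."""
    return sum(t.split_count for f in forests for t in f.trees)


def tree_shape(max_splits: int) -> tuple[int, int, int]:
    """(nodes, edges, leaves) of a tree fully grown to its split cap."""
    return 2 * max_splits + 1, 2 * max_splits, max_splits + 1


# --- JSON serialization (bit-exact round trip) ------------------------------

def forest_to_dict(forest: Forest) -> dict:
    return {
        "config": asdict(forest.config),
        "feature_names": forest.feature_names,
        "classes": forest.classes,
        "degenerate": forest.degenerate,
        "trees": [t.nodes for t in forest.trees],
    }


def forest_from_dict(doc: dict) -> Forest:
    return Forest(
        trees=[Tree(nodes) for nodes in doc["trees"]],
        feature_names=list(doc["feature_names"]),
        classes=list(doc["classes"]),
        config=TrainConfig(**doc["config"]),
        degenerate=bool(doc.get("degenerate", False)),
    )


def save_forest(forest: Forest, path) -> None:
    with open(path, "w") as fh:
        json.dump(forest_to_dict(forest), fh, indent=1)


def load_forest(path) -> Forest:
    with open(path) as fh:
        return forest_from_dict(json.load(fh))


__all__ = [
    "TrainConfig",
    "REDUCED_MIN_LEAF",
    "Tree",
    "Forest",
    "train",
    "predict_proba",
    "importance",
    "select_reduced_features",
    "count_split_nodes",
    "tree_shape",
    "forest_to_dict",
    "forest_from_dict",
    "save_forest",
    "load_forest",
]
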