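"""Random-forest CPP/non-CPP classifier, implemented from first principles.

The ensemble follows the classic bagging recipe: each tree sees a
bootstrap resample of the training set and a random subset of the 27
descriptors, grows by CART with Gini impurity, and votes a hard class at
its leaves.  The consensus probability P(CPP) is the average of the tree
votes — with 500 trees the probabilities are granular at 0.002, which is
what makes values like 0.112 expressible.

Two feature-subset rules are provided:

* ``random_size`` (default) — each tree draws a subset whose size is
  itself uniform on 1..27, i.e. some trees are near-stumps over a couple
  of descriptors and some see everything;
* ``fixed_m`` — the conventional fixed-size subset (default m = 6,
  ceil(sqrt(27))).

The estimator is scikit-learn compatible (``fit``/``predict``/
``predict_proba``/``get_params``) and operates on descriptor matrices;
pair it with :class:`~moonpep.descriptors.PeptideFeaturizer` in a
Pipeline to classify raw sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Union

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.utils.validation import check_is_fitted

from .descriptors import FEATURE_NAMES, N_FEATURES, PeptideFeaturizer, featurize
from .records import LabeledDataset, PeptideRecord


@dataclass
class TreeNode:
    """One node of a CART tree: either a split or a leaf vote."""

    feature: int = -1
    threshold: float = 0.0
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None
    vote: int = 0
    n0: int = 0
    n1: int = 0

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def predict_one(self, x: np.ndarray) -> int:
        node = self
        while not node.is_leaf:
            node = node.left if x[node.feature] <= node.threshold else node.right
        return node.vote

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"vote": int(self.vote), "n0": self.n0, "n1": self.n1}
        return {"feature": int(self.feature), "threshold": float(self.threshold),
                "left": self.left.to_dict(), "right": self.right.to_dict(),
                "n0": self.n0, "n1": self.n1}

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        if "feature" not in d:
            return cls(vote=d["vote"], n0=d["n0"], n1=d["n1"])
        return cls(feature=d["feature"], threshold=d["threshold"],
                   left=cls.from_dict(d["left"]), right=cls.from_dict(d["right"]),
                   n0=d["n0"], n1=d["n1"])


@dataclass
class DecisionTree:
    """A grown tree plus its bootstrap and feature-subset bookkeeping."""

    root: TreeNode
    feature_subset: List[int]
    bootstrap_indices: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.array([self.root.predict_one(x) for x in X], dtype=int)


def _gini(n0: int, n1: int) -> float:
    n = n0 + n1
    if n == 0:
        return 0.0
    p1 = n1 / n
    return 2.0 * p1 * (1.0 - p1)


def best_split(X: np.ndarray, y: np.ndarray, features: Sequence[int],
               min_leaf: int = 1):
    """Exhaustive best (feature, threshold) split by Gini impurity decrease.

    Thresholds are midpoints between consecutive distinct sorted values.
    Ties in impurity decrease break to the lowest feature index, then the
    lowest threshold (features are scanned in ascending order and only a
    strictly better gain replaces the incumbent).  Returns
    ``(gain, feature, threshold)`` or ``None`` if no split improves.
    """
    n = len(y)
    parent = _gini(int(n - y.sum()), int(y.sum()))
    total1 = int(y.sum())
    best = None
    for f in sorted(features):
        v = X[:, f]
        order = np.argsort(v, kind="mergesort")
        vs, ys = v[order], y[order]
        cum1 = np.cumsum(ys)
        boundaries = np.nonzero(vs[1:] > vs[:-1])[0]
        for i in boundaries:
            nl = int(i) + 1
            nr = n - nl
            if nl < min_leaf or nr < min_leaf:
                continue
            l1 = int(cum1[i])
            r1 = total1 - l1
            child = (nl * _gini(nl - l1, l1) + nr * _gini(nr - r1, r1)) / n
            gain = parent - child
            thr = float((vs[i] + vs[i + 1]) / 2.0)
            if thr >= vs[i + 1]:
                # adjacent floats: midpoint rounded onto the right value
                thr = float(vs[i])
            if gain > 0.0 and (best is None or gain > best[0]):
                best = (gain, int(f), thr)
    return best


def _grow(X: np.ndarray, y: np.ndarray, features: Sequence[int],
          min_leaf: int, max_depth: Optional[int], depth: int = 0) -> TreeNode:
    n0 = int(len(y) - y.sum())
    n1 = int(y.sum())
    # majority vote; tie breaks to non-CPP (class 0)
    vote = 1 if n1 > n0 else 0
    if n0 == 0 or n1 == 0:
        return TreeNode(vote=vote, n0=n0, n1=n1)
    if max_depth is not None and depth >= max_depth:
        return TreeNode(vote=vote, n0=n0, n1=n1)
    split = best_split(X, y, features, min_leaf=min_leaf)
    if split is None:
        return TreeNode(vote=vote, n0=n0, n1=n1)
    _, f, thr = split
    mask = X[:, f] <= thr
    left = _grow(X[mask], y[mask], features, min_leaf, max_depth, depth + 1)
    right = _grow(X[~mask], y[~mask], features, min_leaf, max_depth, depth + 1)
    return TreeNode(feature=f, threshold=thr, left=left, right=right,
                    n0=n0, n1=n1)


def grow_tree(X: np.ndarray, y: np.ndarray, feature_subset: Sequence[int],
              rng: np.random.Generator, min_leaf: int = 1,
              max_depth: Optional[int] = None,
              bootstrap: bool = True) -> DecisionTree:
    """Grow one CART tree on a bootstrap resample restricted to a subset."""
    n = len(y)
    if bootstrap:
        idx = rng.integers(0, n, size=n)
    else:
        idx = np.arange(n)
    root = _grow(X[idx], y[idx], feature_subset, min_leaf, max_depth)
    return DecisionTree(root=root, feature_subset=sorted(int(f) for f in feature_subset),
                        bootstrap_indices=idx)


class CPPForest(ClassifierMixin, BaseEstimator):
    """Random forest of hard-voting CART trees for CPP classification.

    Parameters
    ----------
    n_trees : int
        Ensemble size (default 500).
    feature_rule : {"random_size", "fixed_m"}
        How each tree's descriptor subset is drawn: a uniformly random
        subset size on 1..n_features, or a constant ``m``.
    m : int
        Subset size under ``fixed_m`` (default 6 = ceil(sqrt(27))).
    min_leaf : int
        Minimum samples per leaf (default 1: grow to purity).
    max_depth : int or None
        Optional depth cap.
    vote : {"hard", "soft"}
        Consensus rule: mean of leaf majority votes (default; gives
        granular probabilities k/n_trees) or mean of leaf class-1
        fractions.
    random_state : int or None
        Seed; the same (data, params, seed) gives a bit-identical model.

    Attributes
    ----------
    trees_ : list of DecisionTree
    oob_error_ : float or None
        Out-of-bag misclassification rate.
    feature_order_ : list of str
        Descriptor names when fitted on 27-column input.
    """

    def __init__(self, n_trees: int = 500, feature_rule: str = "random_size",
                 m: int = 6, min_leaf: int = 1, max_depth: Optional[int] = None,
                 vote: str = "hard", random_state: Optional[int] = None):
        self.n_trees = n_trees
        self.feature_rule = feature_rule
        self.m = m
        self.min_leaf = min_leaf
        self.max_depth = max_depth
        self.vote = vote
        self.random_state = random_state

    def fit(self, X, y) -> "CPPForest":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("labels must be binary 0/1")
        if len(np.unique(y)) < 2:
            raise ValueError("training requires both classes")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        n, p = X.shape
        if self.feature_rule == "fixed_m" and not 1 <= self.m <= p:
            raise ValueError(f"m must be in 1..{p}")
        rng = np.random.default_rng(self.random_state)
        self.trees_ = []
        oob_votes = np.zeros((n, 2), dtype=int)  # columns: votes for 0, for 1
        for _ in range(self.n_trees):
            if self.feature_rule == "random_size":
                size = int(rng.integers(1, p + 1))
            elif self.feature_rule == "fixed_m":
                size = self.m
            else:
                raise ValueError(f"unknown feature_rule {self.feature_rule!r}")
            subset = np.sort(rng.choice(p, size=size, replace=False))
            tree = grow_tree(X, y, subset, rng, min_leaf=self.min_leaf,
                             max_depth=self.max_depth)
            self.trees_.append(tree)
            oob = np.setdiff1d(np.arange(n), tree.bootstrap_indices,
                               assume_unique=False)
            if oob.size:
                preds = tree.predict(X[oob])
                for i, pred in zip(oob, preds):
                    oob_votes[i, pred] += 1
        voted = oob_votes.sum(axis=1) > 0
        if voted.any():
            # per-sample OOB majority; tie -> class 0
            oob_pred = (oob_votes[voted, 1] > oob_votes[voted, 0]).astype(int)
            self.oob_error_ = float(np.mean(oob_pred != y[voted]))
        else:
            self.oob_error_ = None
        self.n_features_in_ = p
        self.classes_ = np.array([0, 1])
        self.feature_order_ = list(FEATURE_NAMES) if p == N_FEATURES else \
            [f"f{i}" for i in range(p)]
        return self

    def _tree_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}")
        if self.vote == "hard":
            return np.stack([t.predict(X) for t in self.trees_]).astype(float)
        scores = np.empty((len(self.trees_), len(X)))
        for ti, t in enumerate(self.trees_):
            for xi, x in enumerate(X):
                node = t.root
                while not node.is_leaf:
                    node = (node.left if x[node.feature] <= node.threshold
                            else node.right)
                tot = node.n0 + node.n1
                scores[ti, xi] = node.n1 / tot if tot else 0.0
        return scores

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "trees_")
        p1 = self._tree_scores(X).mean(axis=0)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def make_pipeline(featurizer: Optional[PeptideFeaturizer] = None,
                  **forest_params) -> Pipeline:
    """Sequence-in pipeline: PeptideFeaturizer -> CPPForest."""
    return Pipeline([
        ("featurize", featurizer or PeptideFeaturizer()),
        ("forest", CPPForest(**forest_params)),
    ])


def train_forest(dataset: LabeledDataset,
                 featurizer: Optional[PeptideFeaturizer] = None,
                 **forest_params) -> Pipeline:
    """Featurize a labeled dataset and fit the forest; returns the Pipeline."""
    counts = dataset.class_counts()
    if counts[0] == 0 or counts[1] == 0:
        raise ValueError("training requires both classes")
    pipe = make_pipeline(featurizer, **forest_params)
    pipe.fit(dataset.sequences, np.asarray(dataset.labels))
    return pipe


def predict_pcpp(model, seq_or_vector: Union[str, PeptideRecord, np.ndarray]) -> float:
    """Consensus P(CPP) for a raw sequence or a precomputed 27-vector.

    Accepts a fitted sequence Pipeline or a bare :class:`CPPForest`
    (the latter requires either a vector input or a 27-feature model).
    """
    if isinstance(seq_or_vector, (str, PeptideRecord)):
        if isinstance(model, Pipeline):
            return float(model.predict_proba([seq_or_vector])[0, 1])
        vec = featurize(seq_or_vector)
        return float(model.predict_proba(vec[None, :])[0, 1])
    vec = np.asarray(seq_or_vector, dtype=float)
    if vec.ndim == 1:
        vec = vec[None, :]
    if isinstance(model, Pipeline):
        return float(model.named_steps["forest"].predict_proba(vec)[0, 1])
    return float(model.predict_proba(vec)[0, 1])


def cross_validate(dataset: LabeledDataset, k_folds: int = 5,
                   featurizer: Optional[PeptideFeaturizer] = None,
                   seed: Optional[int] = None, **forest_params) -> dict:
    """Stratified k-fold cross-validation of the featurize+forest pipeline.

    Returns per-fold and mean accuracy, sensitivity (recall on CPPs) and
    specificity (recall on non-CPPs).
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    y = np.asarray(dataset.labels)
    counts = dataset.class_counts()
    if min(counts.values()) < k_folds:
        raise ValueError("each class needs at least k_folds members")
    X = (featurizer or PeptideFeaturizer()).fit(dataset.sequences).transform(
        dataset.sequences)
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    folds = []
    for fold_i, (tr, te) in enumerate(skf.split(X, y)):
        params = dict(forest_params)
        base_seed = params.pop("random_state", seed)
        tree_seed = None if base_seed is None else (base_seed + fold_i) % (2 ** 31)
        clf = CPPForest(random_state=tree_seed, **params).fit(X[tr], y[tr])
        pred = clf.predict(X[te])
        yt = y[te]
        tp = int(((pred == 1) & (yt == 1)).sum())
        tn = int(((pred == 0) & (yt == 0)).sum())
        fp = int(((pred == 1) & (yt == 0)).sum())
        fn = int(((pred == 0) & (yt == 1)).sum())
        folds.append({
            "fold": fold_i,
            "accuracy": (tp + tn) / len(yt),
            "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
            "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        })
    mean = {k: float(np.mean([f[k] for f in folds]))
            for k in ("accuracy", "sensitivity", "specificity")}
    return {"folds": folds, "mean": mean}
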