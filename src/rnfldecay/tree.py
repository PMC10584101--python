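"""Binary decision trees for glaucoma classification from loss indices.

Trees are grown by greedy binary CART splits on the decay-derived
features (global loss Lambda, local loss lambda*, petal count nu, ...),
maximizing the Gini impurity decrease.  Each candidate split must earn
its place: its Gini decrease is compared against the permutation null
(labels shuffled, maximum achievable decrease over all features and
thresholds recomputed), and the split is accepted only when that
maximal-selection p-value falls below ``alpha_split``.  This keeps the
reported p-values honest under threshold selection while retaining the
familiar CART report surface (per-node Gini, class counts,
specificity with normal eyes as the negative class).

``ClusteredTreeClassifier`` refines classification by first
partitioning eyes according to their circular cluster (the von Mises
mixture component of mu*), fitting one tree per stratum, and pooling
the confusion counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_random_state

logger = logging.getLogger(__name__)

NEGATIVE_LABEL = "normal"
POSITIVE_LABEL = "glaucoma"


def gini_impurity(class_counts: Sequence[float]) -> float:
    """Gini impurity 1 - sum (n_c / n)^2 of a node's class counts."""
    counts = np.asarray(class_counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("class counts must be non-negative")
    n = counts.sum()
    if n == 0:
        raise ValueError("cannot compute impurity of an empty node")
    p = counts / n
    return float(1.0 - np.sum(p * p))


@dataclass
class TreeNode:
    """One node of a fitted tree (leaf when ``feature`` is None)."""

    class_counts: tuple[int, int]  # (n_negative, n_positive), raw counts
    gini: float
    feature: str | None = None
    threshold: float | None = None
    p_value: float | None = None
    left: "TreeNode | None" = None  # feature <= threshold
    right: "TreeNode | None" = None
    depth: int = 0
    weighted_counts: tuple[float, float] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def n(self) -> int:
        return int(sum(self.class_counts))

    @property
    def prediction(self) -> int:
        """0 = negative (normal), 1 = positive; ties predict negative.

        Majority vote on (class-weighted, if weighting is on) counts.
        """
        counts = self.weighted_counts or self.class_counts
        return int(counts[1] > counts[0])


def _best_split_curves(
    x_sorted_y: np.ndarray, valid: np.ndarray, x_sorted_w: np.ndarray | None = None
) -> np.ndarray:
    """Gini decrease at every candidate cut, given y (0/1) in x-sorted order.

    ``valid[i]`` marks cuts between positions i and i+1 where the
    feature value actually changes; invalid cuts get -inf.  Supports a
    2-D ``x_sorted_y`` of shape (B, n) for permutation batches.  With
    sample weights the impurity uses weighted class proportions.
    """
    y = np.atleast_2d(x_sorted_y).astype(float)
    w = np.ones_like(y) if x_sorted_w is None else np.atleast_2d(x_sorted_w)
    wy = w * y
    pos_left = np.cumsum(wy, axis=1)[:, :-1]
    w_left = np.cumsum(w, axis=1)[:, :-1]
    pos_total = wy.sum(axis=1, keepdims=True)
    w_total = w.sum(axis=1, keepdims=True)
    pos_right = pos_total - pos_left
    w_right = w_total - w_left
    g_parent = 1.0 - (pos_total / w_total) ** 2 - (1.0 - pos_total / w_total) ** 2
    g_left = 1.0 - (pos_left / w_left) ** 2 - (1.0 - pos_left / w_left) ** 2
    g_right = 1.0 - (pos_right / w_right) ** 2 - (1.0 - pos_right / w_right) ** 2
    decrease = (
        g_parent - (w_left / w_total) * g_left - (w_right / w_total) * g_right
    )
    decrease[:, ~valid] = -np.inf
    return decrease if x_sorted_y.ndim == 2 else decrease[0]


class DecayTreeClassifier(BaseEstimator, ClassifierMixin):
    """CART-style tree with permutation-tested splits.

    Parameters
    ----------
    alpha_split : float
        Significance level a split's permutation p-value must beat.
    max_depth : int
        Maximum tree depth (root = depth 0); small trees keep the
        report readable.
    min_node : int
        Minimum samples required in a node to attempt a split.
    n_permutations : int
        Label permutations for the maximal-selection null.
    class_weight : None or "balanced"
        With "balanced", samples are weighted inversely to class
        frequency for split search and leaf voting — the standard CART
        remedy when normal eyes heavily outnumber glaucomatous ones
        and an unweighted tree would collapse to the all-normal vote.
        Reported node Gini and class counts stay on the raw counts.
    random_state : int or None
        Seed for the permutation draws.

    Attributes
    ----------
    root_ : TreeNode
        Fitted tree; a stump (single leaf) when no split is accepted
        or only one class is present.
    feature_names_ : list of str
    classes_ : array([0, 1]) with 0 = normal (negative), 1 = glaucoma.
    """

    def __init__(
        self,
        alpha_split: float = 0.05,
        max_depth: int = 3,
        min_node: int = 7,
        n_permutations: int = 1000,
        class_weight: str | None = None,
        random_state=None,
    ) -> None:
        self.alpha_split = alpha_split
        self.max_depth = max_depth
        self.min_node = min_node
        self.n_permutations = n_permutations
        self.class_weight = class_weight
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(self, X, y) -> "DecayTreeClassifier":
        X, self.feature_names_ = self._as_matrix(X)
        y01 = self._as_binary(y)
        if np.any(~np.isfinite(X)):
            raise ValueError("features must be finite (drop NA rows first)")
        if self.class_weight not in (None, "balanced"):
            raise ValueError("class_weight must be None or 'balanced'")
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        if self.class_weight == "balanced":
            n = y01.size
            wc = {c: n / (2.0 * max(np.sum(y01 == c), 1)) for c in (0, 1)}
            w = np.where(y01 == 1, wc[1], wc[0])
        else:
            w = np.ones(y01.size)
        rng = check_random_state(self.random_state)
        self.root_ = self._grow(X, y01, w, depth=0, rng=rng)
        return self

    def _grow(self, X: np.ndarray, y: np.ndarray, w: np.ndarray, depth: int, rng) -> TreeNode:
        counts = (int(np.sum(y == 0)), int(np.sum(y == 1)))
        node = TreeNode(
            class_counts=counts,
            gini=gini_impurity(counts),
            depth=depth,
            weighted_counts=(float(w[y == 0].sum()), float(w[y == 1].sum())),
        )
        n = y.size
        if depth >= self.max_depth or n < max(2, self.min_node) or min(counts) == 0:
            return node

        best = self._search_split(X, y, w)
        if best is None:
            return node
        feat_idx, threshold, decrease = best
        p_value = self._permutation_p(X, y, w, decrease, rng)
        if p_value >= self.alpha_split:
            return node

        mask_left = X[:, feat_idx] <= threshold
        node.feature = self.feature_names_[feat_idx]
        node.threshold = float(threshold)
        node.p_value = float(p_value)
        node.left = self._grow(X[mask_left], y[mask_left], w[mask_left], depth + 1, rng)
        node.right = self._grow(X[~mask_left], y[~mask_left], w[~mask_left], depth + 1, rng)
        return node

    def _search_split(self, X: np.ndarray, y: np.ndarray, w: np.ndarray):
        """Best (feature, threshold) by Gini decrease; None if no valid cut."""
        best = None
        for f in range(X.shape[1]):
            order = np.argsort(X[:, f], kind="mergesort")
            xs = X[order, f]
            valid = np.diff(xs) > 0
            if not valid.any():
                continue
            dec = _best_split_curves(y[order], valid, w[order])
            i = int(np.argmax(dec))
            if dec[i] <= 0:
                continue
            # threshold at the midpoint between adjacent feature values
            thr = 0.5 * (xs[i] + xs[i + 1])
            if best is None or dec[i] > best[2]:
                best = (f, thr, float(dec[i]))
        return best

    def _permutation_p(
        self, X: np.ndarray, y: np.ndarray, w: np.ndarray, observed: float, rng
    ) -> float:
        """Maximal-selection permutation p-value of the best split.

        Labels (with their class weights) are permuted against the
        features; the null statistic is the best Gini decrease over
        all features and thresholds.
        """
        B = self.n_permutations
        perm_idx = np.empty((B, y.size), dtype=int)
        for b in range(B):
            perm_idx[b] = rng.permutation(y.size)
        null_max = np.full(B, -np.inf)
        for f in range(X.shape[1]):
            order = np.argsort(X[:, f], kind="mergesort")
            valid = np.diff(X[order, f]) > 0
            if not valid.any():
                continue
            y_perm = y[perm_idx][:, order]
            w_perm = w[perm_idx][:, order]
            dec = _best_split_curves(y_perm, valid, w_perm)
            null_max = np.maximum(null_max, dec.max(axis=1))
        return float((1 + np.sum(null_max >= observed - 1e-12)) / (B + 1))

    # ------------------------------------------------------------------
    def predict(self, X) -> np.ndarray:
        X, _ = self._as_matrix(X, expect=self.feature_names_)
        out = np.empty(X.shape[0], dtype=int)
        for i in range(X.shape[0]):
            node = self.root_
            while not node.is_leaf:
                f = self.feature_names_.index(node.feature)
                node = node.left if X[i, f] <= node.threshold else node.right
            out[i] = node.prediction
        return out

    def leaves(self) -> list[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root_]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend([node.right, node.left])
        return out

    def to_text(self) -> str:
        """Indented text rendering of the fitted tree."""
        lines: list[str] = []

        def rec(node: TreeNode, indent: str) -> None:
            tag = (
                f"leaf n={node.n} counts={node.class_counts} gini={node.gini:.3f} "
                f"-> {'glaucoma' if node.prediction else 'normal'}"
                if node.is_leaf
                else f"{node.feature} <= {node.threshold:.4f} "
                f"(p={node.p_value:.4g}, gini={node.gini:.3f}, n={node.n})"
            )
            lines.append(indent + tag)
            if not node.is_leaf:
                rec(node.left, indent + "  ")
                rec(node.right, indent + "  ")

        rec(self.root_, "")
        return "\n".join(lines)

    def to_dot(self) -> str:
        """Graphviz DOT rendering."""
        lines = ["digraph tree {", "  node [shape=box];"]
        counter = {"i": 0}

        def rec(node: TreeNode) -> int:
            idx = counter["i"]
            counter["i"] += 1
            if node.is_leaf:
                label = (
                    f"counts={node.class_counts}\\ngini={node.gini:.3f}\\n"
                    f"{'glaucoma' if node.prediction else 'normal'}"
                )
                lines.append(f'  n{idx} [label="{label}"];')
            else:
                label = (
                    f"{node.feature} <= {node.threshold:.4f}\\n"
                    f"p={node.p_value:.3g}, gini={node.gini:.3f}"
                )
                lines.append(f'  n{idx} [label="{label}"];')
                left = rec(node.left)
                right = rec(node.right)
                lines.append(f"  n{idx} -> n{left} [label=\"yes\"];")
                lines.append(f"  n{idx} -> n{right} [label=\"no\"];")
            return idx

        rec(self.root_)
        lines.append("}")
        return "\n".join(lines)

    # ------------------------------------------------------------------
    @staticmethod
    def _as_matrix(X, expect: list[str] | None = None):
        if isinstance(X, pd.DataFrame):
            names = [str(c) for c in X.columns]
            if expect is not None:
                X = X[expect]
                names = list(expect)
            return X.to_numpy(dtype=float), names
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = expect if expect is not None else [f"x{j}" for j in range(X.shape[1])]
        return X, list(names)

    @staticmethod
    def _as_binary(y) -> np.ndarray:
        y = np.asarray(y)
        if y.dtype.kind in "UOS":
            known = {NEGATIVE_LABEL: 0, POSITIVE_LABEL: 1}
            try:
                return np.array([known[str(v)] for v in y])
            except KeyError as exc:
                raise ValueError(f"unknown class label {exc}") from None
        y = y.astype(int)
        if not set(np.unique(y)) <= {0, 1}:
            raise ValueError("labels must be 'normal'/'glaucoma' or 0/1")
        return y


@dataclass
class ClassifierReport:
    """Confusion counts and summary metrics, normal = negative class."""

    tn: int
    fp: int
    fn: int
    tp: int
    max_leaf_gini: float
    leaf_shares: list[float] = field(default_factory=list)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else np.nan

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else np.nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "tn": self.tn, "fp": self.fp, "fn": self.fn, "tp": self.tp,
                    "specificity": self.specificity,
                    "sensitivity": self.sensitivity,
                    "max_leaf_gini": self.max_leaf_gini,
                }
            ]
        )


def evaluate(model, X, y) -> ClassifierReport:
    """Confusion counts, specificity/sensitivity and leaf impurities."""
    y01 = DecayTreeClassifier._as_binary(y)
    pred = model.predict(X)
    tn = int(np.sum((pred == 0) & (y01 == 0)))
    fp = int(np.sum((pred == 1) & (y01 == 0)))
    fn = int(np.sum((pred == 0) & (y01 == 1)))
    tp = int(np.sum((pred == 1) & (y01 == 1)))
    leaves = model.leaves() if hasattr(model, "leaves") else []
    n_total = sum(leaf.n for leaf in leaves) or 1
    return ClassifierReport(
        tn=tn, fp=fp, fn=fn, tp=tp,
        max_leaf_gini=max((leaf.gini for leaf in leaves), default=np.nan),
        leaf_shares=[leaf.n / n_total for leaf in leaves],
    )


class ClusteredTreeClassifier(BaseEstimator, ClassifierMixin):
    """Per-circular-cluster trees with pooled evaluation.

    Eyes are first grouped by their circular cluster label (the von
    Mises mixture component of their decay direction mu*; eyes without
    a defined mu* form their own stratum), then one permutation-split
    tree is fitted per stratum.  Prediction dispatches each eye to its
    stratum's tree; strata with a single class get a majority stump.
    """

    def __init__(
        self,
        alpha_split: float = 0.05,
        max_depth: int = 3,
        min_node: int = 7,
        n_permutations: int = 1000,
        class_weight: str | None = None,
        random_state=None,
    ) -> None:
        self.alpha_split = alpha_split
        self.max_depth = max_depth
        self.min_node = min_node
        self.n_permutations = n_permutations
        self.class_weight = class_weight
        self.random_state = random_state

    def fit(self, X, y, clusters) -> "ClusteredTreeClassifier":
        clusters = np.asarray(clusters)
        X_mat, names = DecayTreeClassifier._as_matrix(X)
        y01 = DecayTreeClassifier._as_binary(y)
        if clusters.shape[0] != y01.size:
            raise ValueError("clusters must align with the samples")
        self.feature_names_ = names
        self.classes_ = np.array([0, 1])
        self.trees_: dict = {}
        rng = check_random_state(self.random_state)
        for label in pd.unique(clusters):
            mask = clusters == label
            if not mask.any():
                logger.warning("cluster %r is empty; skipped", label)
                continue
            sub_X = X_mat[mask]
            sub_y = y01[mask]
            tree = DecayTreeClassifier(
                alpha_split=self.alpha_split, max_depth=self.max_depth,
                min_node=self.min_node, n_permutations=self.n_permutations,
                class_weight=self.class_weight,
                random_state=rng.randint(2**31 - 1),
            )
            if np.unique(sub_y).size < 2:
                tree.feature_names_ = names
                tree.classes_ = np.array([0, 1])
                counts = (int(np.sum(sub_y == 0)), int(np.sum(sub_y == 1)))
                tree.root_ = TreeNode(class_counts=counts, gini=gini_impurity(counts))
            else:
                tree.fit(pd.DataFrame(sub_X, columns=names), sub_y)
            self.trees_[label] = tree
        return self

    def predict(self, X, clusters) -> np.ndarray:
        clusters = np.asarray(clusters)
        X_mat, _ = DecayTreeClassifier._as_matrix(X, expect=self.feature_names_)
        out = np.zeros(X_mat.shape[0], dtype=int)
        for label, tree in self.trees_.items():
            mask = clusters == label
            if mask.any():
                out[mask] = tree.predict(
                    pd.DataFrame(X_mat[mask], columns=self.feature_names_)
                )
        return out

    def leaves(self) -> list[TreeNode]:
        return [leaf for tree in self.trees_.values() for leaf in tree.leaves()]

    def evaluate(self, X, y, clusters) -> ClassifierReport:
        """Pooled confusion counts over all strata."""
        y01 = DecayTreeClassifier._as_binary(y)
        pred = self.predict(X, clusters)
        tn = int(np.sum((pred == 0) & (y01 == 0)))
        fp = int(np.sum((pred == 1) & (y01 == 0)))
        fn = int(np.sum((pred == 0) & (y01 == 1)))
        tp = int(np.sum((pred == 1) & (y01 == 1)))
        leaves = self.leaves()
        n_total = sum(leaf.n for leaf in leaves) or 1
        return ClassifierReport(
            tn=tn, fp=fp, fn=fn, tp=tp,
            max_leaf_gini=max((leaf.gini for leaf in leaves), default=np.nan),
            leaf_shares=[leaf.n / n_total for leaf in leaves],
        )


def fit_tree(
    features, labels, alpha_split: float = 0.05, min_node: int = 7,
    max_depth: int = 3, n_permutations: int = 1000,
    class_weight: str | None = None, seed=None,
) -> DecayTreeClassifier:
    """Fit a permutation-split tree (functional wrapper)."""
    return DecayTreeClassifier(
        alpha_split=alpha_split, max_depth=max_depth, min_node=min_node,
        n_permutations=n_permutations, class_weight=class_weight,
        random_state=seed,
    ).fit(features, labels)


def fit_tree_by_cluster(
    features, labels, cluster_labels, alpha_split: float = 0.05,
    min_node: int = 7, max_depth: int = 3, n_permutations: int = 1000,
    class_weight: str | None = None, seed=None,
) -> ClusteredTreeClassifier:
    """Fit one tree per circular cluster (functional wrapper)."""
    return ClusteredTreeClassifier(
        alpha_split=alpha_split, max_depth=max_depth, min_node=min_node,
        n_permutations=n_permutations, class_weight=class_weight,
        random_state=seed,
    ).fit(features, labels, cluster_labels)
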