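"""Permutation-split CART trees and the classification report."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import confusion_matrix
from sklearn.tree import DecisionTreeClassifier

import rnfldecay as rd
from rnfldecay.tree import ClassifierReport


class TestGini:
    @pytest.mark.parametrize(
        "counts, expected",
        [((50, 50), 0.5), ((100, 0), 0.0), ((70, 30), 0.42)],
    )
    def test_values(self, counts, expected):
        assert rd.gini_impurity(counts) == pytest.approx(expected)

    def test_empty_node_rejected(self):
        with pytest.raises(ValueError):
            rd.gini_impurity((0, 0))


class TestFitTree:
    def test_perfectly_separable_depth_one(self, rng):
        x = np.concatenate([rng.uniform(0, 1, 50), rng.uniform(2, 3, 50)])
        y = np.array([0] * 50 + [1] * 50)
        tree = rd.fit_tree(x[:, None], y, seed=0)
        assert not tree.root_.is_leaf
        assert tree.root_.left.is_leaf and tree.root_.right.is_leaf
        assert tree.root_.left.gini == 0.0 and tree.root_.right.gini == 0.0
        assert np.array_equal(tree.predict(x[:, None]), y)

    def test_null_labels_rarely_split(self):
        rejected = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            X = rng.uniform(0, 1, size=(100, 2))
            y = rng.integers(0, 2, size=100)
            tree = rd.fit_tree(
                pd.DataFrame(X, columns=["Lambda", "lambda_star"]), y,
                n_permutations=400, seed=seed,
            )
            rejected += tree.root_.is_leaf
        assert rejected >= 0.9 * n_seeds

    def test_shifted_lambda_splits_on_lambda(self, rng):
        n = 150
        lam = np.concatenate([rng.normal(0.2, 0.05, n), rng.normal(0.5, 0.05, n)])
        noise = rng.uniform(0, 1, 2 * n)
        y = np.array([0] * n + [1] * n)
        X = pd.DataFrame({"Lambda": lam, "noise": noise})
        tree = rd.fit_tree(X, y, seed=1)
        assert tree.root_.feature == "Lambda"
        assert tree.root_.p_value < 0.05

    def test_single_class_yields_stump(self):
        X = np.arange(20, dtype=float)[:, None]
        tree = rd.fit_tree(X, np.zeros(20, dtype=int), seed=0)
        assert tree.root_.is_leaf

    def test_root_split_matches_sklearn_oracle(self, rng):
        # same greedy Gini criterion -> same root cut on clean data
        x = np.sort(rng.uniform(0, 1, 80))
        y = (x > x[55]).astype(int)
        ours = rd.fit_tree(x[:, None], y, max_depth=1, seed=0)
        sk = DecisionTreeClassifier(max_depth=1, random_state=0).fit(x[:, None], y)
        assert ours.root_.threshold == pytest.approx(sk.tree_.threshold[0], abs=1e-6)

    def test_string_labels_accepted(self, rng):
        x = np.concatenate([rng.uniform(0, 1, 30), rng.uniform(2, 3, 30)])
        y = ["normal"] * 30 + ["glaucoma"] * 30
        tree = rd.fit_tree(x[:, None], y, seed=0)
        assert np.array_equal(tree.predict(x[:, None]), [0] * 30 + [1] * 30)

    def test_overfit_tree_is_consistent_on_training_data(self, rng):
        X = rng.uniform(0, 1, size=(60, 2))
        y = rng.integers(0, 2, size=60)
        tree = rd.DecayTreeClassifier(
            alpha_split=1.1, max_depth=30, min_node=2, n_permutations=10,
            random_state=0,
        ).fit(X, y)
        assert np.array_equal(tree.predict(X), y)


class TestEvaluate:
    def test_confusion_counts_match_sklearn_oracle(self, rng):
        x = rng.uniform(0, 1, size=(200, 1))
        y = (x[:, 0] + rng.normal(0, 0.2, 200) > 0.5).astype(int)
        tree = rd.fit_tree(x, y, seed=0)
        report = rd.evaluate(tree, x, y)
        tn, fp, fn, tp = confusion_matrix(y, tree.predict(x)).ravel()
        assert (report.tn, report.fp, report.fn, report.tp) == (tn, fp, fn, tp)
        assert report.specificity == pytest.approx(tn / (tn + fp))
        assert report.sensitivity == pytest.approx(tp / (tp + fn))

    def test_perfect_and_degenerate_metrics(self):
        perfect = ClassifierReport(tn=50, fp=0, fn=0, tp=50, max_leaf_gini=0.0)
        assert perfect.specificity == 1.0 and perfect.sensitivity == 1.0
        all_glaucoma = ClassifierReport(tn=0, fp=50, fn=0, tp=50, max_leaf_gini=0.5)
        assert all_glaucoma.specificity == 0.0
        assert ClassifierReport(
            tn=40, fp=10, fn=0, tp=0, max_leaf_gini=0.0
        ).specificity == pytest.approx(0.8)


class TestClusteredTrees:
    def test_single_cluster_equals_plain_tree(self, rng):
        x = np.concatenate([rng.uniform(0, 1, 40), rng.uniform(2, 3, 40)])[:, None]
        y = np.array([0] * 40 + [1] * 40)
        plain = rd.fit_tree(x, y, seed=7)
        clustered = rd.fit_tree_by_cluster(x, y, np.zeros(80, dtype=int), seed=7)
        assert np.array_equal(
            clustered.predict(x, np.zeros(80, dtype=int)), plain.predict(x)
        )

    def test_single_class_cluster_gets_stump(self, rng):
        x = rng.uniform(0, 1, size=(40, 1))
        y = np.array([0] * 20 + [1] * 20)
        clusters = np.array([0] * 20 + [1] * 20)  # each cluster single-class
        model = rd.fit_tree_by_cluster(x, y, clusters, seed=0)
        assert model.trees_[0].root_.is_leaf
        assert model.trees_[1].root_.is_leaf
        pred = model.predict(x, clusters)
        assert np.array_equal(pred, y)  # stump majority = the only class

    def test_opposite_thresholds_beat_pooled_tree(self, rng):
        # glaucoma sits between the two clusters' normal ranges: a single
        # threshold cannot isolate it, per-cluster thresholds can
        n = 60
        lam0 = np.concatenate([rng.normal(0.2, 0.03, n), rng.normal(0.45, 0.03, n)])
        lam1 = np.concatenate([rng.normal(0.7, 0.03, n), rng.normal(0.45, 0.03, n)])
        X = np.concatenate([lam0, lam1])[:, None]
        y = np.array(([0] * n + [1] * n) * 2)
        clusters = np.array([0] * 2 * n + [1] * 2 * n)
        pooled = rd.fit_tree(X, y, max_depth=1, seed=2)
        split = rd.fit_tree_by_cluster(X, y, clusters, max_depth=1, seed=2)
        rep_pooled = rd.evaluate(pooled, X, y)
        rep_split = split.evaluate(X, y, clusters)
        assert rep_split.specificity > rep_pooled.specificity

    def test_balanced_weighting_recovers_minority_class(self, rng):
        # 10:1 prevalence; unweighted majority vote never predicts glaucoma
        lam = np.concatenate([rng.normal(0.3, 0.12, 500), rng.normal(0.45, 0.12, 50)])
        y = np.array([0] * 500 + [1] * 50)
        unweighted = rd.fit_tree(lam[:, None], y, seed=3)
        balanced = rd.fit_tree(lam[:, None], y, class_weight="balanced", seed=3)
        sens_u = rd.evaluate(unweighted, lam[:, None], y).sensitivity
        sens_b = rd.evaluate(balanced, lam[:, None], y).sensitivity
        assert sens_b > sens_u
        assert sens_b > 0.5

    def test_text_and_dot_renderings(self, rng):
        x = np.concatenate([rng.uniform(0, 1, 30), rng.uniform(2, 3, 30)])[:, None]
        y = np.array([0] * 30 + [1] * 30)
        tree = rd.fit_tree(pd.DataFrame(x, columns=["Lambda"]), y, seed=0)
        assert "Lambda <=" in tree.to_text()
        assert tree.to_dot().startswith("digraph")
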