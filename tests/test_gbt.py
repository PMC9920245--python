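import itertools
import json

import numpy as np
import pytest

from treeaemc.gbt import (GBTModel, Hyperparameters, TreeNode, fit_gbt,
                          fit_tree, grad_hess, optimal_leaf_weight,
                          split_gain, structure_score)


class TestClosedForms:
    def test_grad_hess_of_squared_error(self):
        g, h = grad_hess(np.array([3.0, 1.0]), np.array([3.0, 4.0]))
        np.testing.assert_array_equal(g, [0.0, 3.0])
        np.testing.assert_array_equal(h, [1.0, 1.0])

    def test_grad_hess_vectorized_matches_scalar(self):
        y = np.array([0.5, -1.0, 2.0, 3.5, 0.0])
        yhat = np.array([1.0, 0.0, 2.0, -1.0, 4.0])
        g, h = grad_hess(y, yhat)
        for i in range(5):
            gi, hi = grad_hess(y[i : i + 1], yhat[i : i + 1])
            assert g[i] == gi[0] and h[i] == hi[0]

    def test_optimal_leaf_weight_examples(self):
        assert optimal_leaf_weight(-4.0, 2.0, 0.0) == 2.0
        # shrinkage limit: |weight| decreases monotonically in eta
        ws = [abs(optimal_leaf_weight(-4.0, 2.0, e)) for e in (0, 1, 10, 100)]
        assert all(b < a for a, b in zip(ws, ws[1:]))
        with pytest.raises(ValueError):
            optimal_leaf_weight(1.0, -2.0, 1.0)

    def test_single_leaf_predicts_the_mean(self):
        # targets {1, 3} from base 0: G = -4, H = 2 -> weight = mean = 2
        y = np.array([1.0, 3.0])
        g, h = grad_hess(y, np.zeros(2))
        assert optimal_leaf_weight(g.sum(), h.sum(), 0.0) == 2.0

    def test_structure_score_examples(self):
        assert structure_score([(0.0, 2.0)], eta=0.0, gamma=5.0) == 5.0
        assert structure_score([(-4.0, 2.0), (4.0, 2.0)], 0.0, 0.0) == -8.0
        # an empty extra leaf adds exactly gamma
        with_empty = structure_score([(-4.0, 2.0), (4.0, 2.0), (0.0, 0.0)],
                                     eta=1.0, gamma=0.7)
        without = structure_score([(-4.0, 2.0), (4.0, 2.0)], eta=1.0, gamma=0.7)
        assert with_empty - without == pytest.approx(0.7)

    def test_split_gain_examples(self):
        assert split_gain(-4.0, 2.0, -4.0, 2.0, 0.0, 1.5) == -1.5  # symmetric
        assert split_gain(-4.0, 2.0, 4.0, 2.0, 0.0, 0.0) == 8.0
        assert split_gain(-4.0, 2.0, 4.0, 2.0, 0.0, 9.0) == -1.0   # rejected


class TestFitTree:
    def test_pure_node_is_single_zero_leaf(self):
        X = np.array([[1.0], [2.0], [3.0]])
        g = np.zeros(3)
        h = np.ones(3)
        t = fit_tree(X, g, h, max_depth=3, eta=0.0, gamma=0.0,
                     min_child_hessian=0.0)
        assert t.is_leaf and t.weight == 0.0

    def test_depth_one_step_function(self):
        # hand enumeration of the 3 candidate splits puts the best at 2.5
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = np.array([0.0, 0.0, 1.0, 1.0])
        g, h = grad_hess(y, np.zeros(4))
        t = fit_tree(X, g, h, max_depth=1, eta=0.0, gamma=0.0,
                     min_child_hessian=0.0)
        assert t.threshold == 2.5
        assert t.left.weight == 0.0
        assert t.right.weight == 1.0

    def test_constant_feature_gives_single_leaf(self):
        X = np.ones((6, 2))
        y = np.arange(6.0)
        g, h = grad_hess(y, np.zeros(6))
        t = fit_tree(X, g, h, max_depth=3, eta=0.0, gamma=0.0,
                     min_child_hessian=0.0)
        assert t.is_leaf
        assert t.weight == pytest.approx(y.mean())

    def test_depth_two_matches_exhaustive_enumeration(self):
        # brute force over all (root, left, right) split combinations; the
        # greedy tree's structure score must match the greedy path of the
        # exhaustive search on every small fixture
        rng = np.random.default_rng(42)
        for trial in range(5):
            n = rng.integers(6, 13)
            X = np.round(rng.normal(size=(n, 2)), 1)
            y = rng.normal(size=n)
            g, h = grad_hess(y, np.zeros(n))
            t = fit_tree(X, g, h, max_depth=2, eta=0.0, gamma=0.0,
                         min_child_hessian=0.0)
            assert _tree_score(t, X, g, h, 0.0, 0.0) == pytest.approx(
                _greedy_score_by_enumeration(X, g, h), abs=1e-10)

    def test_tilted_xor_needs_both_features(self):
        # a perfectly symmetric XOR has zero first-split gain everywhere, so
        # the gain > 0 rule leaves it unsplit; a slight tilt breaks the
        # symmetry and depth 2 then recovers the full interaction exactly
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        X = np.repeat(X, 3, axis=0)
        y = np.array([0.0, 1.0, 1.1, 0.1]).repeat(3)
        g, h = grad_hess(y, np.full(12, y.mean()))
        t = fit_tree(X, g, h, max_depth=2, eta=0.0, gamma=0.0,
                     min_child_hessian=0.0)
        assert not t.is_leaf and not (t.left.is_leaf or t.right.is_leaf)
        assert {t.left.feature, t.right.feature} != {t.feature}
        pred = y.mean() + t.predict(X)
        np.testing.assert_allclose(pred, y, atol=1e-12)


def _leaf_sums(t, X, g, h):
    idx = np.arange(X.shape[0])
    out = []

    def walk(node, idx):
        if node.is_leaf:
            out.append((g[idx].sum(), h[idx].sum()))
            return
        go_left = X[idx, node.feature] < node.threshold
        walk(node.left, idx[go_left])
        walk(node.right, idx[~go_left])

    walk(t, idx)
    return out


def _tree_score(t, X, g, h, eta, gamma):
    return structure_score(_leaf_sums(t, X, g, h), eta, gamma)


def _greedy_score_by_enumeration(X, g, h):
    """Greedy depth-2 construction where each step enumerates all splits."""

    def best_partition(idx):
        best = None
        for j in range(X.shape[1]):
            for thr in np.unique(X[idx, j]):
                left = idx[X[idx, j] < thr]
                right = idx[X[idx, j] >= thr]
                if len(left) == 0 or len(right) == 0:
                    continue
                gain = split_gain(g[left].sum(), h[left].sum(),
                                  g[right].sum(), h[right].sum(), 0.0, 0.0)
                if best is None or gain > best[0] + 1e-15:
                    best = (gain, left, right)
        return best

    idx = np.arange(X.shape[0])
    root = best_partition(idx)
    if root is None or root[0] <= 0:
        return structure_score([(g.sum(), h.sum())], 0.0, 0.0)
    leaves = []
    for side in root[1:]:
        sub = best_partition(side)
        if sub is None or sub[0] <= 0:
            leaves.append((g[side].sum(), h[side].sum()))
        else:
            leaves.append((g[sub[1]].sum(), h[sub[1]].sum()))
            leaves.append((g[sub[2]].sum(), h[sub[2]].sum()))
    return structure_score(leaves, 0.0, 0.0)


class TestFitGbt:
    def test_zero_rounds_predicts_target_mean(self):
        X = np.arange(10.0).reshape(-1, 1)
        y = np.linspace(0, 5, 10)
        model = fit_gbt(X, y, Hyperparameters(n_trees=0), seed=0)
        np.testing.assert_allclose(model.predict(X), y.mean())

    def test_one_round_unit_shrinkage_equals_single_tree(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 3))
        y = X[:, 0] + 0.2 * rng.normal(size=30)
        hp = Hyperparameters(n_trees=1, learning_rate=1.0, eta=0.0,
                             gamma=0.0, max_depth=6, subsample=1.0,
                             min_child_hessian=1.0)
        model = fit_gbt(X, y, hp, seed=0)
        g, h = grad_hess(y, np.full(30, y.mean()))
        tree = fit_tree(X, g, h, max_depth=6, eta=0.0, gamma=0.0,
                        min_child_hessian=1.0)
        np.testing.assert_allclose(model.predict(X),
                                   y.mean() + tree.predict(X), atol=1e-12)

    def test_training_rmse_non_increasing_in_rounds(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 4))
        y = np.sin(X[:, 0]) + 0.5 * X[:, 1]
        rmses = []
        for k in (0, 5, 20, 60):
            hp = Hyperparameters(n_trees=k, learning_rate=0.3, subsample=1.0)
            m = fit_gbt(X, y, hp, seed=0)
            rmses.append(float(np.sqrt(np.mean((m.predict(X) - y) ** 2))))
        assert all(b <= a + 1e-12 for a, b in zip(rmses, rmses[1:]))

    def test_deterministic_under_seed_with_subsampling(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 3))
        y = X[:, 0]
        hp = Hyperparameters(n_trees=20, subsample=0.7)
        m1 = fit_gbt(X, y, hp, seed=11)
        m2 = fit_gbt(X, y, hp, seed=11)
        np.testing.assert_array_equal(m1.predict(X), m2.predict(X))

    def test_leaf_weights_are_locally_optimal(self):
        # perturbing any leaf weight by +-1e-3 must not lower the penalized
        # second-order objective of that boosting round
        rng = np.random.default_rng(4)
        X = rng.normal(size=(25, 2))
        y = X[:, 0] ** 2
        base = np.full(25, y.mean())
        g, h = grad_hess(y, base)
        eta = 0.5
        tree = fit_tree(X, g, h, max_depth=2, eta=eta, gamma=0.0,
                        min_child_hessian=1.0)

        def objective(weights):
            pred = np.zeros(25)
            leaves = []

            def walk(node, idx):
                if node.is_leaf:
                    leaves.append((node, idx))
                    return
                go_left = X[idx, node.feature] < node.threshold
                walk(node.left, idx[go_left])
                walk(node.right, idx[~go_left])

            walk(tree, np.arange(25))
            obj = 0.0
            for (node, idx), w in zip(leaves, weights):
                obj += g[idx].sum() * w + 0.5 * (h[idx].sum() + eta) * w**2
            return obj

        leaves = _leaf_sums(tree, X, g, h)
        w_opt = np.array([optimal_leaf_weight(G, H, eta) for G, H in leaves])
        base_obj = objective(w_opt)
        for i in range(len(w_opt)):
            for delta in (1e-3, -1e-3):
                w = w_opt.copy()
                w[i] += delta
                assert objective(w) > base_obj

    def test_structure_score_never_increases_with_accepted_splits(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 3))
        y = X[:, 0] * 3
        g, h = grad_hess(y, np.zeros(30))
        scores = []
        for depth in (0, 1, 2, 3):
            t = fit_tree(X, g, h, max_depth=depth, eta=0.0, gamma=0.0,
                         min_child_hessian=1.0)
            scores.append(_tree_score(t, X, g, h, 0.0, 0.0))
        assert all(b <= a + 1e-12 for a, b in zip(scores, scores[1:]))


class TestPredictAndSerialization:
    def test_single_leaf_tree_with_shrinkage(self):
        model = GBTModel(trees=[TreeNode(weight=4.0)], learning_rate=0.5,
                         base_score=1.0, eta=0.0, gamma=0.0, n_features=2)
        np.testing.assert_allclose(model.predict(np.zeros((3, 2))), 3.0)

    def test_dimension_mismatch_rejected(self):
        model = GBTModel(trees=[], learning_rate=0.3, base_score=0.0,
                         eta=0.0, gamma=0.0, n_features=4)
        with pytest.raises(ValueError):
            model.predict(np.zeros((2, 3)))

    def test_json_roundtrip(self, tmp_path):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(40, 3))
        y = X[:, 0] - X[:, 2]
        model = fit_gbt(X, y, Hyperparameters(n_trees=10), seed=0)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = GBTModel.from_json(path)
        np.testing.assert_array_equal(model.predict(X), back.predict(X))

    def test_reference_implementation_agreement(self):
        """Train-set RMSE within 10% of xgboost under matched settings."""
        xgb = pytest.importorskip("xgboost")
        rng = np.random.default_rng(7)
        X = rng.normal(size=(50, 5))
        y = X[:, 0] * 2 + np.sin(X[:, 1]) + 0.1 * rng.normal(size=50)
        hp = Hyperparameters(n_trees=40, max_depth=3, learning_rate=0.3,
                             eta=1.0, gamma=0.0, subsample=1.0,
                             min_child_hessian=1.0)
        ours = fit_gbt(X, y, hp, seed=0)
        rmse_ours = float(np.sqrt(np.mean((ours.predict(X) - y) ** 2)))
        ref = xgb.XGBRegressor(
            n_estimators=40, max_depth=3, learning_rate=0.3, reg_lambda=1.0,
            gamma=0.0, subsample=1.0, min_child_weight=1.0,
            base_score=float(y.mean()), tree_method="exact",
        ).fit(X, y)
        rmse_ref = float(np.sqrt(np.mean((ref.predict(X) - y) ** 2)))
        assert rmse_ours == pytest.approx(rmse_ref, rel=0.10)
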