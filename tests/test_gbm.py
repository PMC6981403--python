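"""The boosted-tree engine: split search, Newton steps, gain importance."""

import numpy as np
import pytest

from prednet.gbm import (
    GBMConfig,
    GBMModel,
    TreeNode,
    best_split,
    fit_gbm,
    gain_importance,
    predict_proba,
    predict_raw,
)
from prednet.evaluation import auc

from conftest import random_binary_problem


# --- independent oracles -------------------------------------------------

def _sse(v):
    return float(((v - v.mean()) ** 2).sum()) if v.size else 0.0


def best_split_oracle(X, r, min_leaf):
    """Exhaustive SSE_parent - SSE_children scan; strict improvement keeps
    the lowest column index on ties."""
    best = None
    parent = _sse(r)
    for j in range(X.shape[1]):
        m = X[:, j] > 0.5
        if m.sum() < min_leaf or (~m).sum() < min_leaf:
            continue
        g = parent - _sse(r[m]) - _sse(r[~m])
        if g > 1e-12 and (best is None or g > best[1] * (1 + 1e-12)):
            best = (j, g)
    return best


def walk_importance(node, acc):
    if node.feature is not None:
        acc[node.feature] += node.gain
        walk_importance(node.left, acc)
        walk_importance(node.right, acc)


def max_depth_of(node):
    if node.is_leaf:
        return 0
    return 1 + max(max_depth_of(node.left), max_depth_of(node.right))


def min_leaf_of(node):
    if node.is_leaf:
        return node.n
    return min(min_leaf_of(node.left), min_leaf_of(node.right))


# --- best_split ----------------------------------------------------------

def test_best_split_hand_example():
    # residuals (1,1,-1,-1) split cleanly by f0: gain = (2*2/4)*(1-(-1))^2 = 4
    X = np.array([[1, 1], [1, 0], [0, 1], [0, 0]], dtype=float)
    r = np.array([1.0, 1.0, -1.0, -1.0])
    feat, gain = best_split(X, np.arange(4), r, min_leaf=1)
    assert feat == 0
    assert gain == pytest.approx(4.0)
    # identity check: gain equals SSE_parent - SSE_children
    assert gain == pytest.approx(_sse(r) - _sse(r[:2]) - _sse(r[2:]))


def test_best_split_zero_variance_returns_none():
    X = np.array([[1, 0], [0, 1], [1, 1], [0, 0]], dtype=float)
    r = np.full(4, 0.25)
    assert best_split(X, np.arange(4), r, min_leaf=1) is None


def test_best_split_tie_goes_to_lower_index():
    X = np.array([[1, 1], [1, 1], [0, 0], [0, 0]], dtype=float)  # identical
    r = np.array([1.0, 2.0, -1.0, -2.0])
    feat, _ = best_split(X, np.arange(4), r, min_leaf=1)
    assert feat == 0


def test_best_split_respects_min_leaf():
    X = np.array([[1], [0], [0], [0]], dtype=float)
    r = np.array([3.0, -1.0, -1.0, -1.0])
    assert best_split(X, np.arange(4), r, min_leaf=2) is None


@pytest.mark.parametrize("seed", range(8))
def test_best_split_matches_exhaustive_oracle(seed):
    rng = np.random.default_rng(seed)
    n, p = rng.integers(20, 200), 10
    X = (rng.random((n, p)) < rng.uniform(0.2, 0.8)).astype(float)
    r = rng.normal(size=n)
    for min_leaf in (1, 5):
        ours = best_split(X, np.arange(n), r, min_leaf)
        oracle = best_split_oracle(X, r, min_leaf)
        if oracle is None:
            assert ours is None
        else:
            assert ours[0] == oracle[0]
            assert ours[1] == pytest.approx(oracle[1], rel=1e-9)


# --- fitting -------------------------------------------------------------

def test_degenerate_target_raises():
    X = np.eye(4)
    with pytest.raises(ValueError, match="degenerate target"):
        fit_gbm(X, np.ones(4))


def test_perfect_predictor_takes_all_gain():
    rng = np.random.default_rng(0)
    X = (rng.random((40, 5)) < 0.5).astype(float)
    y = X[:, 2].copy()
    model = fit_gbm(X, y, GBMConfig(n_trees=1, max_depth=1, min_leaf=1))
    imp = gain_importance(model, normalize=True)
    assert imp[2] == pytest.approx(1.0)
    assert auc(predict_proba(model, X), y) == 1.0


def test_depth2_tree_matches_recursive_oracle(rng):
    """Root and child splits agree with a brute-force SSE enumeration."""
    for seed in range(5):
        local = np.random.default_rng(seed)
        X, y = random_binary_problem(local, 150, 10)
        model = fit_gbm(X, y, GBMConfig(n_trees=1, max_depth=2, min_leaf=5))
        # first-tree residuals are y - mean(y) for every sample
        r = y - y.mean()
        root = model.trees[0]
        oracle_root = best_split_oracle(X, r, 5)
        assert root.feature == oracle_root[0]
        m = X[:, root.feature] > 0.5
        for child, rows in ((root.left, ~m), (root.right, m)):
            oracle_child = best_split_oracle(X[rows], r[rows], 5)
            if oracle_child is None:
                assert child.is_leaf
            else:
                assert child.feature == oracle_child[0]
                assert child.gain == pytest.approx(oracle_child[1], rel=1e-9)


def test_training_loss_nonincreasing(rng):
    X, y = random_binary_problem(rng, 200, 8)
    model = fit_gbm(X, y, GBMConfig(n_trees=30, max_depth=3, min_leaf=5))
    F = np.full(y.size, model.base_score)
    increments = np.zeros_like(F)
    idx = np.arange(y.size)

    def deviance(F):
        p = 1 / (1 + np.exp(-F))
        return -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))

    prev = deviance(F)
    from prednet.gbm import _accumulate

    for tree in model.trees:
        out = np.zeros_like(F)
        _accumulate(tree, X, idx, out)
        F = F + model.config.learn_rate * out
        cur = deviance(F)
        assert cur <= prev + 1e-9
        prev = cur


def test_depth_and_min_leaf_limits(rng):
    X, y = random_binary_problem(rng, 300, 12)
    cfg = GBMConfig(n_trees=20, max_depth=4, min_leaf=10)
    model = fit_gbm(X, y, cfg)
    for tree in model.trees:
        assert max_depth_of(tree) <= cfg.max_depth
        assert min_leaf_of(tree) >= cfg.min_leaf


def test_importance_matches_tree_walk_oracle(rng):
    X, y = random_binary_problem(rng, 250, 10)
    model = fit_gbm(X, y, GBMConfig(n_trees=3, max_depth=3, min_leaf=5))
    acc = np.zeros(X.shape[1])
    for tree in model.trees:
        walk_importance(tree, acc)
    np.testing.assert_allclose(model.importance, acc, rtol=1e-12)
    norm = gain_importance(model, normalize=True)
    assert norm.sum() == pytest.approx(1.0)
    # unused features carry exactly zero importance
    used = set()
    for tree in model.trees:
        stack = [tree]
        while stack:
            node = stack.pop()
            if node.feature is not None:
                used.add(node.feature)
                stack += [node.left, node.right]
    for j in range(X.shape[1]):
        if j not in used:
            assert model.importance[j] == 0.0


def test_importance_invariant_to_row_permutation(rng):
    X, y = random_binary_problem(rng, 180, 8)
    perm = rng.permutation(y.size)
    cfg = GBMConfig(n_trees=10, max_depth=3, min_leaf=5)
    a = fit_gbm(X, y, cfg)
    b = fit_gbm(X[perm], y[perm], cfg)
    np.testing.assert_allclose(a.importance, b.importance, rtol=1e-9)


def test_fit_is_deterministic(rng):
    X, y = random_binary_problem(rng, 120, 6)
    cfg = GBMConfig(n_trees=15, max_depth=4, min_leaf=5)
    assert fit_gbm(X, y, cfg).to_json() == fit_gbm(X, y, cfg).to_json()


def test_zero_gain_data_gives_zero_importance():
    X = np.zeros((30, 4))  # constant features: nothing to split on
    y = np.array([0, 1] * 15, dtype=float)
    model = fit_gbm(X, y, GBMConfig(n_trees=5, max_depth=2, min_leaf=1))
    assert np.all(gain_importance(model) == 0)
    assert np.all(gain_importance(model, normalize=True) == 0)


# --- prediction ----------------------------------------------------------

@pytest.mark.parametrize("base_rate", [0.5, 0.8])
def test_zero_tree_model_predicts_base_rate(base_rate):
    model = GBMModel(
        base_score=float(np.log(base_rate / (1 - base_rate))),
        trees=[], feature_names=["a", "b"], importance=np.zeros(2),
    )
    p = predict_proba(model, np.array([[0.0, 1.0], [1.0, 0.0]]))
    np.testing.assert_allclose(p, base_rate)


def test_predict_column_mismatch_raises(rng):
    X, y = random_binary_problem(rng, 60, 5)
    model = fit_gbm(X, y, GBMConfig(n_trees=2, max_depth=2, min_leaf=5))
    with pytest.raises(ValueError, match="column mismatch"):
        predict_proba(model, X[:, :3])


def test_boosting_separates_perfectly_separable_data(rng):
    X, y = random_binary_problem(rng, 100, 6)
    y = X[:, 0].copy()
    model = fit_gbm(X, y, GBMConfig(n_trees=20, max_depth=2, min_leaf=1))
    assert auc(predict_raw(model, X), y) == 1.0
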