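"""Gradient-boosted shallow regression trees for binary classification.

A deliberately small, deterministic reconstruction of the classic
classification GBM: Bernoulli deviance, depth-limited regression trees fit
to residuals ``r_i = y_i - p_i``, Newton leaf steps
``sum(r) / sum(p(1-p))``, and a shrinkage (learning-rate) factor on every
tree's contribution.  All predictors are binary indicator columns, so the
split search is an exhaustive scan over features: for a feature f
partitioning a node's n samples into sides of size n0/n1 with residual
means m0/m1, the squared-error reduction is

    gain(f) = (n0 * n1 / n) * (m1 - m0)^2

which equals SSE_parent - SSE_left - SSE_right.  Feature importance is the
sum of these gains over every split on the feature across the ensemble
("gain" importance).

There is no row or column subsampling and ties in the split search go to
the lowest column index, so a fit is a pure function of (X, y, config).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

# gains below this are indistinguishable from round-off on unit-scale
# residuals and are treated as zero (no admissible split)
_GAIN_EPS = 1e-12


@dataclass(frozen=True)
class GBMConfig:
    """Boosting hyperparameters.

    ``n_trees=100`` and ``max_depth=4`` follow the published analysis;
    ``learn_rate=0.1`` and ``min_leaf=10`` are the defaults of the GBM
    implementation that analysis used.  ``seed`` is accepted for interface
    symmetry but the fit is exhaustive and deterministic, so it is unused.
    """

    n_trees: int = 100
    max_depth: int = 4
    learn_rate: float = 0.1
    min_leaf: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if not 0 < self.learn_rate <= 1:
            raise ValueError("learn_rate must be in (0, 1]")
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")


class TreeNode:
    """One node of a regression tree.

    A leaf holds a log-odds increment in ``value``; an internal node holds
    the split ``feature`` (column index), its squared-error-reduction
    ``gain`` and two children (``left`` = feature 0, ``right`` = feature 1).
    """

    __slots__ = ("feature", "value", "gain", "n", "left", "right")

    def __init__(self, *, feature=None, value=0.0, gain=0.0, n=0,
                 left=None, right=None):
        self.feature = feature
        self.value = value
        self.gain = gain
        self.n = n
        self.left = left
        self.right = right

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def to_dict(self, feature_names) -> dict:
        if self.is_leaf:
            return {"leaf": self.value, "n": self.n}
        return {
            "split": feature_names[self.feature],
            "gain": self.gain,
            "n": self.n,
            "left": self.left.to_dict(feature_names),
            "right": self.right.to_dict(feature_names),
        }


@dataclass
class GBMModel:
    """A fitted boosted ensemble for one binary target."""

    base_score: float
    trees: list[TreeNode]
    feature_names: list[str]
    importance: np.ndarray = field(repr=False)
    config: GBMConfig = field(default_factory=GBMConfig)

    def to_json(self) -> str:
        """Deterministic JSON dump (base score, trees, importance)."""
        payload = {
            "base_score": self.base_score,
            "n_trees": len(self.trees),
            "feature_names": list(self.feature_names),
            "importance": {
                f: imp
                for f, imp in zip(self.feature_names, self.importance)
                if imp > 0
            },
            "trees": [t.to_dict(self.feature_names) for t in self.trees],
        }
        return json.dumps(payload, sort_keys=True)


def best_split(
    X: np.ndarray,
    rows: np.ndarray,
    residuals: np.ndarray,
    min_leaf: int,
    feature_mask: np.ndarray | None = None,
) -> tuple[int, float] | None:
    """Exhaustive scan for the binary-feature split maximising gain.

    Returns ``(feature_index, gain)`` over features leaving at least
    ``min_leaf`` samples on each side, or ``None`` if no admissible split
    has positive gain.  Exact ties resolve to the lowest column index.
    """
    n = rows.size
    if n < 2 * min_leaf:
        return None
    r = residuals[rows]
    Xs = X[rows]
    s = r.sum()
    n1 = Xs.sum(axis=0)
    s1 = r @ Xs
    n0 = n - n1
    s0 = s - s1
    valid = (n1 >= min_leaf) & (n0 >= min_leaf)
    if feature_mask is not None:
        valid &= feature_mask
    if not valid.any():
        return None
    gains = np.zeros(X.shape[1])
    v1, v0 = n1[valid], n0[valid]
    diff = s1[valid] / v1 - s0[valid] / v0
    gains[valid] = (v0 * v1 / n) * diff * diff
    best = int(np.argmax(gains))
    g = float(gains[best])
    if g <= _GAIN_EPS:
        return None
    return best, g


def _build_tree(
    X: np.ndarray,
    residuals: np.ndarray,
    hessian: np.ndarray,
    rows: np.ndarray,
    depth_left: int,
    min_leaf: int,
    importance: np.ndarray,
    increments: np.ndarray,
) -> TreeNode:
    split = best_split(X, rows, residuals, min_leaf) if depth_left > 0 else None
    if split is None:
        num = residuals[rows].sum()
        den = hessian[rows].sum()
        value = num / den if den > 1e-12 else 0.0
        increments[rows] = value
        return TreeNode(value=value, n=rows.size)
    feat, gain = split
    importance[feat] += gain
    go_right = X[rows, feat] > 0.5
    left = _build_tree(X, residuals, hessian, rows[~go_right],
                       depth_left - 1, min_leaf, importance, increments)
    right = _build_tree(X, residuals, hessian, rows[go_right],
                        depth_left - 1, min_leaf, importance, increments)
    return TreeNode(feature=feat, gain=gain, n=rows.size, left=left, right=right)


def fit_gbm(
    X: np.ndarray,
    y: np.ndarray,
    config: GBMConfig | None = None,
    feature_names: list[str] | None = None,
) -> GBMModel:
    """Boost ``config.n_trees`` depth-limited trees on binary data.

    Raises ``ValueError("degenerate target")`` when ``y`` holds a single
    class.  Boosting stops early once a tree can make no further progress
    (all residuals fitted or no admissible split with nonzero step).
    """
    cfg = config or GBMConfig()
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X rows must match len(y)")
    p_bar = y.mean()
    if p_bar <= 0.0 or p_bar >= 1.0:
        raise ValueError("degenerate target: y contains a single class")
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]
    if len(feature_names) != X.shape[1]:
        raise ValueError("feature_names length must match X columns")

    base = math.log(p_bar / (1.0 - p_bar))
    F = np.full(y.size, base)
    importance = np.zeros(X.shape[1])
    trees: list[TreeNode] = []
    all_rows = np.arange(y.size)
    increments = np.empty(y.size)
    for _ in range(cfg.n_trees):
        p = 1.0 / (1.0 + np.exp(-F))
        residuals = y - p
        if np.max(np.abs(residuals)) < 1e-10:
            break  # target fitted exactly; further trees are no-ops
        hessian = p * (1.0 - p)
        root = _build_tree(X, residuals, hessian, all_rows, cfg.max_depth,
                           cfg.min_leaf, importance, increments)
        if root.is_leaf and abs(root.value) < 1e-12:
            break  # no admissible split and a zero Newton step
        F += cfg.learn_rate * increments
        trees.append(root)
    return GBMModel(
        base_score=base,
        trees=trees,
        feature_names=list(feature_names),
        importance=importance,
        config=cfg,
    )


def _accumulate(node: TreeNode, X: np.ndarray, idx: np.ndarray,
                out: np.ndarray) -> None:
    if node.is_leaf:
        out[idx] += node.value
        return
    go_right = X[idx, node.feature] > 0.5
    _accumulate(node.left, X, idx[~go_right], out)
    _accumulate(node.right, X, idx[go_right], out)


def predict_raw(model: GBMModel, X: np.ndarray) -> np.ndarray:
    """Log-odds scores: base + learn_rate * sum of tree outputs."""
    X = np.asarray(X, dtype=np.float64)
    if X.shape[1] != len(model.feature_names):
        raise ValueError(
            f"column mismatch: model expects {len(model.feature_names)} "
            f"features, got {X.shape[1]}"
        )
    total = np.zeros(X.shape[0])
    idx = np.arange(X.shape[0])
    for tree in model.trees:
        _accumulate(tree, X, idx, total)
    return model.base_score + model.config.learn_rate * total


def predict_proba(model: GBMModel, X: np.ndarray) -> np.ndarray:
    """Class-1 probabilities, strictly inside (0, 1)."""
    return 1.0 / (1.0 + np.exp(-predict_raw(model, X)))


def gain_importance(model: GBMModel, normalize: bool = False) -> np.ndarray:
    """Per-feature summed split gains; optionally rescaled to sum to 1.

    The zero ensemble (no splits anywhere) normalizes to the zero vector.
    """
    raw = model.importance.copy()
    if not normalize:
        return raw
    total = raw.sum()
    return raw / total if total > 0 else raw
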