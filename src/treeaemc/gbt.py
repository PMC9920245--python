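"""Second-order gradient-boosted regression trees, from scratch.

The ensemble prediction is ``yhat = base + nu * sum_k f_k(x)`` where each
``f_k`` is a regression tree fitted to the second-order Taylor expansion of
the squared-error loss around the current prediction.  With per-instance
gradient g_i and Hessian h_i, a fixed tree partition {I_j} has closed-form
optimal leaf weights and objective value (the *structure score*):

    xi_j* = - G_j / (H_j + eta),        G_j = sum g_i,  H_j = sum h_i
    J     = -1/2 sum_j G_j^2 / (H_j + eta) + gamma * T

where eta is the L2 penalty on leaf weights and gamma the per-leaf penalty
(the symbols follow the convention where eta plays the role usually called
lambda).  Trees are grown by exact greedy search: every (feature, midpoint
between consecutive sorted values) split is scored by the decrease in J and
the best positive-gain split is taken.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "Hyperparameters", "TreeNode", "GBTModel", "grad_hess",
    "optimal_leaf_weight", "structure_score", "split_gain",
    "fit_tree", "fit_gbt", "DEFAULT_SEARCH_SPACE",
]


def grad_hess(y: np.ndarray, yhat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First/second derivatives of the squared-error loss L = 1/2 (y - yhat)^2."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have equal length")
    return yhat - y, np.ones_like(y)


def optimal_leaf_weight(G: float, H: float, eta: float) -> float:
    """Closed-form leaf weight -G / (H + eta); requires H + eta > 0."""
    if H + eta <= 0:
        raise ValueError(f"H + eta must be positive, got {H + eta}")
    return -G / (H + eta)


def structure_score(
    leaf_sums: Sequence[tuple[float, float]], eta: float, gamma: float
) -> float:
    """Objective value of a fixed partition: -1/2 sum G^2/(H+eta) + gamma*T."""
    total = 0.0
    for G, H in leaf_sums:
        if H + eta <= 0:
            raise ValueError("every leaf must have H + eta > 0")
        total += G * G / (H + eta)
    return -0.5 * total + gamma * len(leaf_sums)


def split_gain(G_L: float, H_L: float, G_R: float, H_R: float,
               eta: float, gamma: float) -> float:
    """Structure-score decrease of splitting one leaf into (L, R), minus gamma."""
    return 0.5 * (
        G_L**2 / (H_L + eta) + G_R**2 / (H_R + eta)
        - (G_L + G_R) ** 2 / (H_L + H_R + eta)
    ) - gamma


@dataclass
class TreeNode:
    """A split node (feature, threshold, children) or a leaf (weight)."""

    feature: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    weight: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty(X.shape[0])
        self._predict_into(X, np.arange(X.shape[0]), out)
        return out

    def _predict_into(self, X, idx, out) -> None:
        if self.is_leaf:
            out[idx] = self.weight
            return
        go_left = X[idx, self.feature] < self.threshold
        self.left._predict_into(X, idx[go_left], out)
        self.right._predict_into(X, idx[~go_left], out)

    def n_leaves(self) -> int:
        if self.is_leaf:
            return 1
        return self.left.n_leaves() + self.right.n_leaves()

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"weight": self.weight}
        return {"feature": self.feature, "threshold": self.threshold,
                "left": self.left.to_dict(), "right": self.right.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        if "weight" in d:
            return cls(weight=d["weight"])
        return cls(feature=d["feature"], threshold=d["threshold"],
                   left=cls.from_dict(d["left"]), right=cls.from_dict(d["right"]))


@dataclass
class Hyperparameters:
    """Tunable knobs of the booster.

    ``eta`` is the L2 penalty on leaf weights and ``gamma`` the per-leaf
    penalty; ``learning_rate`` (shrinkage nu) scales each tree's
    contribution; ``subsample`` is the row fraction drawn per round;
    ``min_child_hessian`` blocks splits producing a child with Hessian mass
    below it.
    """

    n_trees: int = 100
    max_depth: int = 4
    learning_rate: float = 0.3
    eta: float = 1.0
    gamma: float = 0.0
    subsample: float = 1.0
    min_child_hessian: float = 1.0


#: Default tuner search space: name -> (low, high, integer?)
DEFAULT_SEARCH_SPACE: dict[str, tuple[float, float, bool]] = {
    "n_trees": (10, 300, True),
    "max_depth": (2, 8, True),
    "learning_rate": (0.01, 0.5, False),
    "eta": (0.0, 10.0, False),
    "gamma": (0.0, 5.0, False),
    "subsample": (0.5, 1.0, False),
}


def _best_split(X, g, h, idx, eta, gamma, min_child_hessian):
    """Exact greedy split search over all features and sorted midpoints.

    Fully vectorized over (position, feature).  Ties in gain are broken
    toward the lower feature index then the lower threshold: ``argmax``
    returns the first maximum, positions are threshold-ascending within a
    feature and features are scanned ascending.
    """
    sub = X[idx]                                     # (m, d)
    if sub.shape[0] < 2:
        return -np.inf, None, None
    gs_tot = float(g[idx].sum())
    hs_tot = float(h[idx].sum())
    order = np.argsort(sub, axis=0, kind="stable")
    xs = np.take_along_axis(sub, order, axis=0)
    gl = np.cumsum(g[idx][order], axis=0)[:-1]       # (m-1, d)
    hl = np.cumsum(h[idx][order], axis=0)[:-1]
    gr = gs_tot - gl
    hr = hs_tot - hl
    ok = ((xs[:-1] < xs[1:])                         # distinct neighbours only
          & (hl >= min_child_hessian) & (hr >= min_child_hessian))
    if not ok.any():
        return -np.inf, None, None
    with np.errstate(divide="ignore", invalid="ignore"):
        gain = 0.5 * (gl**2 / (hl + eta) + gr**2 / (hr + eta)
                      - gs_tot**2 / (hs_tot + eta)) - gamma
    gain[~ok] = -np.inf
    p_best = np.argmax(gain, axis=0)                 # per-feature best position
    per_feature = gain[p_best, np.arange(gain.shape[1])]
    j = int(np.argmax(per_feature))
    p = int(p_best[j])
    if not np.isfinite(per_feature[j]):
        return -np.inf, None, None
    return (float(per_feature[j]), j,
            float(0.5 * (xs[p, j] + xs[p + 1, j])))


def fit_tree(
    X: np.ndarray,
    g: np.ndarray,
    h: np.ndarray,
    max_depth: int = 4,
    eta: float = 1.0,
    gamma: float = 0.0,
    min_child_hessian: float = 1.0,
) -> TreeNode:
    """Grow one regression tree by exact greedy structure-score minimization.

    Recursion stops at ``max_depth``, when no split has positive gain, or
    when a candidate child would carry less Hessian mass than
    ``min_child_hessian``; leaves receive the closed-form optimal weight.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    g = np.asarray(g, dtype=float)
    h = np.asarray(h, dtype=float)
    if X.shape[0] != g.size or g.size != h.size or X.shape[0] < 1:
        raise ValueError("X rows, g and h must agree and be non-empty")

    def build(idx: np.ndarray, depth: int) -> TreeNode:
        G = float(g[idx].sum())
        H = float(h[idx].sum())
        if depth < max_depth and idx.size >= 2:
            gain, feat, thr = _best_split(X, g, h, idx, eta, gamma,
                                          min_child_hessian)
            if feat is not None and gain > 0:
                go_left = X[idx, feat] < thr
                return TreeNode(
                    feature=feat, threshold=thr,
                    left=build(idx[go_left], depth + 1),
                    right=build(idx[~go_left], depth + 1),
                )
        return TreeNode(weight=optimal_leaf_weight(G, H, eta))

    return build(np.arange(X.shape[0]), 0)


@dataclass
class GBTModel:
    """Additive ensemble: ``predict(x) = base + nu * sum_k tree_k(x)``."""

    trees: list[TreeNode]
    learning_rate: float
    base_score: float
    eta: float
    gamma: float
    n_features: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"model was trained on {self.n_features} features, got {X.shape[1]}"
            )
        out = np.full(X.shape[0], self.base_score)
        for tree in self.trees:
            out += self.learning_rate * tree.predict(X)
        return out

    # -- serialization ----------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({
            "learning_rate": self.learning_rate,
            "base_score": self.base_score,
            "eta": self.eta,
            "gamma": self.gamma,
            "n_features": self.n_features,
            "trees": [t.to_dict() for t in self.trees],
        })
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, src: str | Path) -> "GBTModel":
        text = Path(src).read_text() if Path(str(src)).exists() else str(src)
        d = json.loads(text)
        return cls(trees=[TreeNode.from_dict(t) for t in d["trees"]],
                   learning_rate=d["learning_rate"], base_score=d["base_score"],
                   eta=d["eta"], gamma=d["gamma"], n_features=d["n_features"])


def fit_gbt(
    X: np.ndarray,
    y: np.ndarray,
    hp: Hyperparameters | None = None,
    seed: int | None = None,
) -> GBTModel:
    """Fit the boosted ensemble.

    The base score is the target mean; each round computes (g, h) at the
    current prediction, optionally subsamples rows with the seeded
    generator, fits one tree, and adds it with shrinkage.  Deterministic
    under ``seed``.
    """
    hp = hp if hp is not None else Hyperparameters()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 training rows")
    rng = np.random.default_rng(seed)
    base = float(y.mean())
    yhat = np.full(n, base)
    trees: list[TreeNode] = []
    for _ in range(hp.n_trees):
        g, h = grad_hess(y, yhat)
        if hp.subsample < 1.0:
            m = max(int(np.ceil(hp.subsample * n)), 2)
            rows = rng.choice(n, size=m, replace=False)
            tree = fit_tree(X[rows], g[rows], h[rows],
                            max_depth=hp.max_depth, eta=hp.eta,
                            gamma=hp.gamma,
                            min_child_hessian=hp.min_child_hessian)
        else:
            tree = fit_tree(X, g, h, max_depth=hp.max_depth, eta=hp.eta,
                            gamma=hp.gamma,
                            min_child_hessian=hp.min_child_hessian)
        yhat = yhat + hp.learning_rate * tree.predict(X)
        trees.append(tree)
    return GBTModel(trees=trees, learning_rate=hp.learning_rate,
                    base_score=base, eta=hp.eta, gamma=hp.gamma,
                    n_features=X.shape[1])
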