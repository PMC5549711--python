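"""Gradient boosting with regression trees, built from first principles.

The model is a stage-wise additive ensemble

    f_M(x) = f_0 + nu * sum_{m=1}^{M} T_m(x)

where each regression tree T_m partitions the input space into J disjoint
axis-aligned regions with a constant value per region. Binary classification
uses labels y in {-1, +1} and the two-class deviance

    L(y, f) = log(1 + exp(-2 y f)),

so the initial score is f_0 = 1/2 * log((1 + ybar)/(1 - ybar)) and the
pseudo-residuals (negative gradient at the current model) are

    R_i = 2 y_i / (1 + exp(2 y_i f_i)).

Each round greedily fits a CART regression tree to the residuals by
least squares, then re-optimizes every leaf value with a single
Newton-Raphson step on the deviance,

    c_j = sum_{i in leaf} R_i / sum_{i in leaf} |R_i| (2 - |R_i|),

a standard approximation to the exact per-leaf line search, which has no
closed form under this loss. The predicted interaction probability is
p(x) = 1 / (1 + exp(-2 f_M(x))).

Everything is deterministic: split thresholds are midpoints of consecutive
distinct sorted feature values, and among equal-gain splits the lowest
feature index, then the lowest threshold, wins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

_FORMAT_VERSION = 1


class GBDTError(ValueError):
    """Raised for invalid training data or model misuse."""


@dataclass(frozen=True)
class GBDTConfig:
    """Hyperparameters of the boosted ensemble.

    ``n_trees`` (M) boosting rounds; trees grown to ``max_depth`` with at
    least ``min_samples_leaf`` training rows per leaf; ``shrinkage`` (nu) in
    (0, 1] scales each tree's contribution (nu = 1 recovers the unshrunk
    stage-wise update). ``loss`` is fixed to two-class deviance.
    """

    n_trees: int = 500
    max_depth: int = 3
    min_samples_leaf: int = 5
    shrinkage: float = 0.1
    seed: int = 0
    loss: str = "deviance"

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise GBDTError("n_trees must be >= 1")
        if self.max_depth < 1:
            raise GBDTError("max_depth must be >= 1")
        if self.min_samples_leaf < 1:
            raise GBDTError("min_samples_leaf must be >= 1")
        if not (0.0 < self.shrinkage <= 1.0):
            raise GBDTError("shrinkage must be in (0, 1]")
        if self.loss != "deviance":
            raise GBDTError(f"unsupported loss {self.loss!r}")


@dataclass
class _Node:
    """A tree node: either an internal split or a leaf with a value."""

    feature: int = -1
    threshold: float = 0.0
    left: "_Node | None" = None
    right: "_Node | None" = None
    value: float = 0.0
    is_leaf: bool = True


@dataclass
class RegressionTree:
    """Axis-aligned binary regression tree; leaves partition the input space."""

    root: _Node

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Leaf value for every row of X."""
        X = np.atleast_2d(X)
        out = np.empty(X.shape[0])
        self._apply(self.root, X, np.arange(X.shape[0]), out)
        return out

    def _apply(self, node: _Node, X: np.ndarray, rows: np.ndarray, out: np.ndarray) -> None:
        if node.is_leaf:
            out[rows] = node.value
            return
        go_left = X[rows, node.feature] <= node.threshold
        self._apply(node.left, X, rows[go_left], out)
        self._apply(node.right, X, rows[~go_left], out)

    def leaves(self) -> list[_Node]:
        """All leaf nodes in deterministic (left-to-right) order."""
        out: list[_Node] = []

        def walk(n: _Node) -> None:
            if n.is_leaf:
                out.append(n)
            else:
                walk(n.left)
                walk(n.right)

        walk(self.root)
        return out

    def apply_leaves(self, X: np.ndarray) -> np.ndarray:
        """Index (into :meth:`leaves` order) of the leaf each row reaches."""
        X = np.atleast_2d(X)
        out = np.empty(X.shape[0], dtype=np.intp)
        counter = [0]

        def walk(n: _Node, rows: np.ndarray) -> None:
            if n.is_leaf:
                out[rows] = counter[0]
                counter[0] += 1
                return
            go_left = X[rows, n.feature] <= n.threshold
            walk(n.left, rows[go_left])
            walk(n.right, rows[~go_left])

        walk(self.root, np.arange(X.shape[0]))
        return out

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())


def negative_gradient(y: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Pseudo-residuals of the two-class deviance at the current scores.

    y must be in {-1, +1}; R_i = 2 y_i / (1 + exp(2 y_i f_i)).
    """
    y = np.asarray(y, dtype=float)
    f = np.asarray(f, dtype=float)
    return 2.0 * y / (1.0 + np.exp(2.0 * y * f))


def _best_split(
    X: np.ndarray, r: np.ndarray, min_samples_leaf: int
) -> tuple[int, float, float] | None:
    """Best least-squares split of (X, r), or None if no valid split exists.

    Returns (feature, threshold, gain) where gain is the decrease in the sum
    of squared deviations relative to the unsplit node. Vectorized over all
    features at once via prefix sums on per-feature sort orders; ties resolve
    to the lowest feature index, then the lowest threshold.
    """
    n, n_features = X.shape
    if n < 2 * min_samples_leaf:
        return None
    order = np.argsort(X, axis=0, kind="stable")
    Xs = np.take_along_axis(X, order, axis=0)
    rs = r[order]
    csum = np.cumsum(rs, axis=0)
    total = csum[-1, 0]  # identical across columns: sum of r
    k = np.arange(1, n)  # rows in the left child per candidate
    left = csum[:-1, :]
    # Maximizing sum_left^2/n_left + sum_right^2/n_right minimizes child SSE.
    score = left**2 / k[:, None] + (total - left) ** 2 / (n - k)[:, None]
    valid = Xs[1:, :] > Xs[:-1, :]
    valid &= ((k >= min_samples_leaf) & (n - k >= min_samples_leaf))[:, None]
    if not valid.any():
        return None
    score = np.where(valid, score, -np.inf)
    # Column-major argmax: lowest feature first, then lowest threshold
    # (candidates are in ascending threshold order within a feature).
    flat = np.argmax(score.ravel(order="F"))
    row, feat = flat % (n - 1), flat // (n - 1)
    best = score[row, feat]
    if not np.isfinite(best):
        return None
    gain = best - total**2 / n
    if gain <= 1e-12:
        return None
    threshold = 0.5 * (Xs[row, feat] + Xs[row + 1, feat])
    return int(feat), float(threshold), float(gain)


def fit_regression_tree(
    X: np.ndarray,
    r: np.ndarray,
    max_depth: int = 3,
    min_samples_leaf: int = 1,
) -> RegressionTree:
    """Greedy CART least-squares fit of targets r; leaf value = mean residual.

    Splitting stops at max_depth, when a child would fall below
    min_samples_leaf, or when no split reduces the squared error (pure node).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    r = np.asarray(r, dtype=float)
    if X.shape[0] == 0:
        raise GBDTError("fit_regression_tree: empty input")
    if X.shape[0] != r.shape[0]:
        raise GBDTError("fit_regression_tree: X and r row counts differ")

    def build(rows: np.ndarray, depth: int) -> _Node:
        node = _Node(value=float(r[rows].mean()), is_leaf=True)
        if depth >= max_depth:
            return node
        split = _best_split(X[rows], r[rows], min_samples_leaf)
        if split is None:
            return node
        feat, thr, _ = split
        go_left = X[rows, feat] <= thr
        node.is_leaf = False
        node.feature = feat
        node.threshold = thr
        node.left = build(rows[go_left], depth + 1)
        node.right = build(rows[~go_left], depth + 1)
        return node

    return RegressionTree(root=build(np.arange(X.shape[0]), 0))


@dataclass
class GBDTModel:
    """A fitted ensemble: initial score f0 plus shrunk regression trees."""

    f0: float
    trees: list[RegressionTree]
    config: GBDTConfig
    n_features: int
    train_deviance: list[float] = field(default_factory=list)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise GBDTError(
                f"expected {self.n_features} features, got {X.shape[1]}"
            )
        f = np.full(X.shape[0], self.f0)
        for tree in self.trees:
            f += self.config.shrinkage * tree.apply(X)
        return f

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """P(interacting) = 1 / (1 + exp(-2 f(x))) per row."""
        return 1.0 / (1.0 + np.exp(-2.0 * self.decision_function(X)))

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        """0/1 labels at the given probability threshold."""
        if not (0.0 < threshold < 1.0):
            raise GBDTError("threshold must lie strictly in (0, 1)")
        return (self.predict_proba(X) >= threshold).astype(int)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        def node_dict(n: _Node) -> dict:
            if n.is_leaf:
                return {"value": n.value}
            return {
                "feature": n.feature,
                "threshold": n.threshold,
                "left": node_dict(n.left),
                "right": node_dict(n.right),
            }

        return {
            "format_version": _FORMAT_VERSION,
            "model": "gbdt-binary-deviance",
            "f0": self.f0,
            "n_features": self.n_features,
            "config": {
                "n_trees": self.config.n_trees,
                "max_depth": self.config.max_depth,
                "min_samples_leaf": self.config.min_samples_leaf,
                "shrinkage": self.config.shrinkage,
                "seed": self.config.seed,
                "loss": self.config.loss,
            },
            "trees": [node_dict(t.root) for t in self.trees],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "GBDTModel":
        if data.get("format_version") != _FORMAT_VERSION:
            raise GBDTError(
                f"unsupported model format version {data.get('format_version')!r}"
            )

        def build(d: dict) -> _Node:
            if "value" in d:
                return _Node(value=float(d["value"]), is_leaf=True)
            return _Node(
                feature=int(d["feature"]),
                threshold=float(d["threshold"]),
                left=build(d["left"]),
                right=build(d["right"]),
                is_leaf=False,
            )

        return cls(
            f0=float(data["f0"]),
            trees=[RegressionTree(root=build(t)) for t in data["trees"]],
            config=GBDTConfig(**data["config"]),
            n_features=int(data["n_features"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "GBDTModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _deviance(y_pm: np.ndarray, f: np.ndarray) -> float:
    """Mean two-class deviance log(1 + exp(-2 y f)), computed stably."""
    z = -2.0 * y_pm * f
    return float(np.mean(np.logaddexp(0.0, z)))


def fit_gbdt(
    X: np.ndarray, y: Sequence[int] | np.ndarray, config: GBDTConfig | None = None
) -> GBDTModel:
    """Fit the boosted-tree binary classifier.

    ``y`` may be given as {0, 1} or {-1, +1}; both classes must be present.
    The per-iteration mean training deviance is recorded on the returned
    model's ``train_deviance`` (index 0 is the deviance of f0 alone).
    """
    config = config or GBDTConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    if X.shape[0] != y.shape[0]:
        raise GBDTError("X and y row counts differ")
    if set(np.unique(y)) <= {0, 1}:
        y_pm = np.where(y == 1, 1.0, -1.0)
    elif set(np.unique(y)) <= {-1, 1}:
        y_pm = y.astype(float)
    else:
        raise GBDTError("labels must be binary ({0,1} or {-1,+1})")
    if np.unique(y_pm).size < 2:
        raise GBDTError(
            "training labels contain a single class; f0 is undefined"
        )

    ybar = y_pm.mean()
    f0 = 0.5 * np.log((1.0 + ybar) / (1.0 - ybar))
    f = np.full(X.shape[0], f0)
    trees: list[RegressionTree] = []
    deviance_trace = [_deviance(y_pm, f)]

    for _ in range(config.n_trees):
        residuals = negative_gradient(y_pm, f)
        tree = fit_regression_tree(
            X, residuals, config.max_depth, config.min_samples_leaf
        )
        # Newton step per leaf on the deviance, replacing the provisional
        # mean-residual leaf values.
        assignment = tree.apply_leaves(X)
        leaves = tree.leaves()
        for j, leaf in enumerate(leaves):
            r = residuals[assignment == j]
            denom = np.sum(np.abs(r) * (2.0 - np.abs(r)))
            leaf.value = float(r.sum() / denom) if denom > 0 else 0.0
        leaf_values = np.array([leaf.value for leaf in leaves])
        f += config.shrinkage * leaf_values[assignment]
        trees.append(tree)
        deviance_trace.append(_deviance(y_pm, f))

    return GBDTModel(
        f0=float(f0),
        trees=trees,
        config=config,
        n_features=X.shape[1],
        train_deviance=deviance_trace,
    )


def predict_score(model: GBDTModel, x: np.ndarray) -> np.ndarray | float:
    """Raw additive score f_M(x); scalar for a single sample."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    scores = model.decision_function(np.atleast_2d(x))
    return float(scores[0]) if single else scores


def predict_label(
    model: GBDTModel, x: np.ndarray, threshold: float = 0.5
) -> tuple[np.ndarray | int, np.ndarray | float]:
    """(label, probability) at the given threshold; scalars for one sample."""
    if not (0.0 < threshold < 1.0):
        raise GBDTError("threshold must lie strictly in (0, 1)")
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    proba = model.predict_proba(np.atleast_2d(x))
    labels = (proba >= threshold).astype(int)
    if single:
        return int(labels[0]), float(proba[0])
    return labels, proba
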