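"""Gradient boosting with regression-tree base learners, written from first
principles.

Stagewise additive modelling under squared-error loss: the model starts at
the target mean F0 and at each stage fits a shallow regression tree to the
current residuals (the negative gradient of ½(y − F)²), then takes the
exact line-search step (which equals 1 when leaves carry residual means)
scaled by the shrinkage ν. Splits minimize the weighted two-sided SSE

    Σ_{x<τ} w (θ − ζ1)² + Σ_{x≥τ} w (θ − ζ2)²

over midpoints of sorted unique feature values, with ζ1/ζ2 the weighted
means of each side. Ties break toward the smallest feature index, then the
smallest τ, so fits are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .records_io import InputError

__all__ = ["GBAConfig", "GBAModel", "learn_split", "fit", "predict"]


@dataclass(frozen=True)
class GBAConfig:
    num_iter: int = 50  # boosting stages M
    shrinkage: float = 0.1  # ν in (0, 1]
    max_depth: int = 2
    min_leaf: int = 5

    def __post_init__(self) -> None:
        if self.num_iter < 1 or self.max_depth < 1:
            raise InputError("num_iter and max_depth must be ≥ 1")
        if not (0.0 < self.shrinkage <= 1.0):
            raise InputError("shrinkage must lie in (0, 1]")


@dataclass
class _Node:
    feature: int = -1  # -1 marks a leaf
    tau: float = 0.0
    value: float = 0.0  # leaf prediction
    left: Optional["_Node"] = None
    right: Optional["_Node"] = None


@dataclass
class GBAModel:
    f0: float
    stages: List[_Node] = field(default_factory=list)
    shrinkage: float = 0.1
    n_features: int = 0


def learn_split(
    x_col: np.ndarray, targets: np.ndarray, weights: Optional[np.ndarray] = None
) -> Optional[Tuple[float, float, float, float]]:
    """Best weighted split of one feature column.

    Returns (τ, ζ1, ζ2, weighted SSE) minimizing the two-sided weighted
    squared error over midpoints of sorted unique x, or None when all x are
    identical (leaf sentinel). ζ are weighted means of each side, so the
    result is invariant to rescaling all weights.
    """
    x = np.asarray(x_col, dtype=float)
    th = np.asarray(targets, dtype=float)
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    order = np.argsort(x, kind="stable")
    xs, ts, ws = x[order], th[order], w[order]
    # candidate boundaries where x strictly increases
    bounds = np.nonzero(np.diff(xs) > 0)[0]
    if bounds.size == 0:
        return None
    cw = np.cumsum(ws)
    cwt = np.cumsum(ws * ts)
    cwt2 = np.cumsum(ws * ts * ts)
    W, WT, WT2 = cw[-1], cwt[-1], cwt2[-1]
    wl, wtl, wt2l = cw[bounds], cwt[bounds], cwt2[bounds]
    wr, wtr, wt2r = W - wl, WT - wtl, WT2 - wt2l
    with np.errstate(divide="ignore", invalid="ignore"):
        zl = wtl / wl
        zr = wtr / wr
        sse = (wt2l - wl * zl**2) + (wt2r - wr * zr**2)
    sse = np.where((wl > 0) & (wr > 0), sse, np.inf)
    k = int(np.argmin(sse))  # first minimum → smallest τ on ties
    b = bounds[k]
    tau = 0.5 * (xs[b] + xs[b + 1])
    return float(tau), float(zl[k]), float(zr[k]), float(max(sse[k], 0.0))


def _grow(X: np.ndarray, th: np.ndarray, w: np.ndarray, depth: int, cfg: GBAConfig) -> _Node:
    node = _Node(value=float(np.average(th, weights=w)) if th.size else 0.0)
    if depth >= cfg.max_depth or len(th) < 2 * cfg.min_leaf:
        return node
    best = None
    for j in range(X.shape[1]):
        res = learn_split(X[:, j], th, w)
        if res is None:
            continue
        tau, z1, z2, sse = res
        left = X[:, j] < tau
        if left.sum() < cfg.min_leaf or (~left).sum() < cfg.min_leaf:
            continue
        if best is None or sse < best[0] - 1e-15:  # strict: earlier j wins ties
            best = (sse, j, tau)
    if best is None:
        return node
    _, j, tau = best
    left = X[:, j] < tau
    node.feature, node.tau = j, tau
    node.left = _grow(X[left], th[left], w[left], depth + 1, cfg)
    node.right = _grow(X[~left], th[~left], w[~left], depth + 1, cfg)
    return node


def _eval_tree(node: _Node, X: np.ndarray) -> np.ndarray:
    if node.feature < 0:
        return np.full(len(X), node.value)
    out = np.empty(len(X))
    left = X[:, node.feature] < node.tau
    out[left] = _eval_tree(node.left, X[left])
    out[~left] = _eval_tree(node.right, X[~left])
    return out


def fit(X, y, cfg: GBAConfig = GBAConfig(), seed: int = 0) -> GBAModel:
    """Fit the boosted-tree ensemble.

    ``seed`` is threaded for future stochastic options; the default
    configuration is fully deterministic. For squared loss the exact
    line-search step is 1, applied with shrinkage ν.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y) or len(y) < 2:
        raise InputError("X must be 2-D with rows(X) == len(y) ≥ 2")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise InputError("non-finite inputs")
    model = GBAModel(f0=float(np.mean(y)), shrinkage=cfg.shrinkage, n_features=X.shape[1])
    F = np.full(len(y), model.f0)
    w = np.ones(len(y))
    for _ in range(cfg.num_iter):
        resid = y - F  # negative gradient of ½(y−F)²
        if np.allclose(resid, 0.0):
            break
        tree = _grow(X, resid, w, 0, cfg)
        F = F + cfg.shrinkage * _eval_tree(tree, X)
        model.stages.append(tree)
    return model


def predict(model: GBAModel, X) -> np.ndarray:
    """F0 + ν·Σ_m h_m(x)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise InputError(
            f"feature count mismatch: model has {model.n_features}, got {X.shape}"
        )
    out = np.full(len(X), model.f0)
    for tree in model.stages:
        out += model.shrinkage * _eval_tree(tree, X)
    return out
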