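"""Base SVM kernels, correlation-based feature weights, and the weighted
composite kernel.

Four base families are supported: linear ``x . y``, quadratic
``(x . y + 1)^2``, third-order polynomial ``(x . y + 1)^3`` and the radial
basis kernel ``exp(-gamma ||x - y||^2)`` with gamma = 1/(2 sigma^2).  The
weighted ("composite") variant applies each family per feature coordinate
and mixes the scalar kernels with nonnegative weights summing to one,

    K_c(x, y) = sum_p c_p K_p(x_p, y_p),

a conic combination of valid kernels, hence itself positive semidefinite.
The weights come from the magnitude of the point-biserial (Pearson)
correlation between each feature and the class label: strongly class-
associated features count more.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["KernelSpec", "KERNEL_FAMILIES", "base_kernel", "weighted_kernel", "correlation_weights", "gram_matrix", "validate_weights"]

KERNEL_FAMILIES = ("linear", "quadratic", "poly3", "rbf")
_POLY_DEGREE = {"quadratic": 2, "poly3": 3}


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family + weighting flag; gamma applies to the rbf family only."""

    family: str = "poly3"
    weighted: bool = False
    gamma: float = 0.5  # 1/(2 sigma^2) with sigma = 1 on standardized features

    def __post_init__(self) -> None:
        if self.family not in KERNEL_FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}; choose from {KERNEL_FAMILIES}")
        if self.family == "rbf" and self.gamma <= 0:
            raise ValueError("gamma must be > 0 for the rbf family")

    def to_dict(self) -> dict:
        return {"family": self.family, "weighted": self.weighted, "gamma": self.gamma}

    @classmethod
    def from_dict(cls, d: dict) -> "KernelSpec":
        return cls(**d)


def validate_weights(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise ValueError("kernel weights must be nonnegative")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("kernel weights must sum to 1")
    return w


def base_kernel(x: np.ndarray, y: np.ndarray, spec: KernelSpec) -> float:
    """Prime (unweighted) kernel between two feature vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same dimension")
    if spec.family == "linear":
        return float(x @ y)
    if spec.family in _POLY_DEGREE:
        return float((x @ y + 1.0) ** _POLY_DEGREE[spec.family])
    return float(np.exp(-spec.gamma * np.sum((x - y) ** 2)))


def weighted_kernel(x: np.ndarray, y: np.ndarray, weights: np.ndarray, spec: KernelSpec) -> float:
    """Composite kernel: weight-mixed scalar base kernels, one per feature."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = validate_weights(weights)
    if not (x.shape == y.shape == w.shape):
        raise ValueError("x, y and weights must share one dimension")
    if spec.family == "linear":
        k = x * y
    elif spec.family in _POLY_DEGREE:
        k = (x * y + 1.0) ** _POLY_DEGREE[spec.family]
    else:
        k = np.exp(-spec.gamma * (x - y) ** 2)
    return float(w @ k)


def correlation_weights(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Normalized |Pearson r| between each feature column and the 0/1 label.

    Constant columns get zero weight.  If every correlation vanishes the
    weights fall back to uniform (with a warning): no feature is then more
    informative than another.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D with one label per row")
    if len(np.unique(y)) < 2 or min(np.sum(y == 0), np.sum(y == 1)) < 2:
        raise ValueError("need at least 2 rows per class to correlate")
    yc = y - y.mean()
    xc = X - X.mean(axis=0)
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc.T @ yc) / (sx * sy)
    r = np.where(sx < 1e-12, 0.0, r)
    mag = np.abs(r)
    if mag.sum() < 1e-12:
        warnings.warn("all feature-label correlations are zero; using uniform weights")
        return np.full(X.shape[1], 1.0 / X.shape[1])
    return mag / mag.sum()


def gram_matrix(
    X: np.ndarray,
    spec: KernelSpec,
    weights: np.ndarray | None = None,
    Y: np.ndarray | None = None,
) -> np.ndarray:
    """Pairwise kernel matrix K[i, j] = K(X_i, Y_j) (Y defaults to X).

    Vectorized over pairs; the weighted composite loops over the (few)
    feature coordinates.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = X if Y is None else np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError("X and Y must share the feature dimension")
    if weights is None:
        if spec.weighted:
            raise ValueError("spec.weighted is set but no weights were given")
        if spec.family == "linear":
            return X @ Y.T
        if spec.family in _POLY_DEGREE:
            return (X @ Y.T + 1.0) ** _POLY_DEGREE[spec.family]
        sq = np.sum(X**2, axis=1)[:, None] + np.sum(Y**2, axis=1)[None, :] - 2.0 * (X @ Y.T)
        return np.exp(-spec.gamma * np.maximum(sq, 0.0))
    w = validate_weights(weights)
    if w.shape[0] != X.shape[1]:
        raise ValueError("weights must have one entry per feature")
    G = np.zeros((X.shape[0], Y.shape[0]))
    for p in range(X.shape[1]):
        outer = np.outer(X[:, p], Y[:, p])
        if spec.family == "linear":
            G += w[p] * outer
        elif spec.family in _POLY_DEGREE:
            G += w[p] * (outer + 1.0) ** _POLY_DEGREE[spec.family]
        else:
            diff = X[:, p][:, None] - Y[:, p][None, :]
            G += w[p] * np.exp(-spec.gamma * diff**2)
    return G
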