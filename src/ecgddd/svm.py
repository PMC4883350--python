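"""Dual SVM training on a precomputed Gram matrix, and a scikit-learn-style
classifier wrapping standardization, correlation weighting and the solver.

The dual problem solved (labels b_i in {-1, +1}):

    max_a  sum_i a_i - 1/2 sum_ij a_i a_j b_i b_j K(x_i, x_j)
    s.t.   0 <= a_i <= C,   sum_i a_i b_i = 0

The canonical statement of the problem is hard-margin (no upper bound);
real beat windows overlap between classes, so a soft-margin box is used,
with C = inf available to recover the hard-margin problem.  The default
C = 10 gives both prime kernels (whose Gram entries scale with the feature
count on standardized data) and the weight-normalized composite kernel
(entries of order 1) enough capacity to fit the class boundary.  The
solver is SMO with maximal-violating-pair working-set selection and a
second-order gain rule on a precomputed Gram matrix (the composite kernel
is custom, so precomputation is the natural layout).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .features import Dataset
from .kernels import KernelSpec, correlation_weights, gram_matrix

__all__ = ["solve_dual", "WeightedKernelSVC", "TrainedModel", "train", "predict", "save_model", "load_model"]

_SV_TOL = 1e-8


class ConvergenceError(RuntimeError):
    pass


def solve_dual(
    gram: np.ndarray,
    b: np.ndarray,
    C: float = 10.0,
    tol: float = 1e-7,
    max_passes: int = 10_000,
) -> tuple[np.ndarray, float]:
    """SMO solution (alphas, bias) of the dual problem for one Gram matrix.

    Convergence: the maximal KKT violating pair gap m(a) - M(a) drops below
    ``tol``.  The bias is the average of b_s - sum_i a_i b_i K_is over
    margin vectors (0 < a_s < C); if none exist it is the midpoint of the
    feasibility interval.  ``max_passes`` caps working-set iterations at
    max_passes * n.
    """
    G = np.asarray(gram, dtype=float)
    b = np.asarray(b, dtype=float)
    n = len(b)
    if G.shape != (n, n):
        raise ValueError("gram must be n x n")
    if not set(np.unique(b)) <= {-1.0, 1.0} or len(np.unique(b)) < 2:
        raise ValueError("labels must contain both -1 and +1")
    if C <= 0:
        raise ValueError("C must be positive (use np.inf for hard margin)")

    Q = (b[:, None] * b[None, :]) * G
    alpha = np.zeros(n)
    grad = -np.ones(n)  # gradient of 1/2 a'Qa - e'a

    finite_C = math.isfinite(C)
    max_iter = max_passes * n
    for it in range(max_iter):
        if it and it % (50 * n) == 0:
            grad = Q @ alpha - 1.0  # refresh against incremental-update drift
        up = (b == 1) & (alpha < C - _SV_TOL) | (b == -1) & (alpha > _SV_TOL)
        low = (b == -1) & (alpha < C - _SV_TOL) | (b == 1) & (alpha > _SV_TOL)
        if not up.any() or not low.any():
            break
        minus_bg = -b * grad
        i = int(np.flatnonzero(up)[np.argmax(minus_bg[up])])
        m = minus_bg[i]
        M = np.min(minus_bg[low])
        if m - M < tol:
            break
        cand = np.flatnonzero(low & (minus_bg < m - 1e-16))
        if cand.size == 0:
            break
        # second-order gain rule; fall back to the maximal violating pair in
        # the late phase, where gain-based zigzag between near-bound alphas
        # can stall progress
        if it % (10 * n) < 9 * n:
            diff = m - minus_bg[cand]
            a_quad = Q[i, i] + Q[cand, cand] - 2.0 * b[i] * b[cand] * Q[i, cand]
            a_quad = np.maximum(a_quad, 1e-12)
            j = int(cand[np.argmax(diff**2 / a_quad)])
        else:
            j = int(cand[np.argmin(minus_bg[cand])])

        # analytic update of the pair along d = b_i e_i - b_j e_j, which
        # preserves sum_k alpha_k b_k
        quad = max(Q[i, i] + Q[j, j] - 2.0 * b[i] * b[j] * Q[i, j], 1e-12)
        t = (m - minus_bg[j]) / quad
        ai_old, aj_old = alpha[i], alpha[j]
        # box clipping for both coordinates
        if b[i] == 1:
            t = min(t, C - ai_old) if finite_C else t
        else:
            t = min(t, ai_old)
        if b[j] == 1:
            t = min(t, aj_old)
        else:
            t = min(t, C - aj_old) if finite_C else t
        if t <= 0:
            break
        alpha[i] = ai_old + (t if b[i] == 1 else -t)
        alpha[j] = aj_old + (-t if b[j] == 1 else t)
        grad += Q[:, i] * (alpha[i] - ai_old) + Q[:, j] * (alpha[j] - aj_old)
    else:
        raise ConvergenceError(f"SMO did not converge within {max_iter} iterations (gap {m - M:.3g})")

    # bias from margin vectors; fall back to the feasibility midpoint
    f = (alpha * b) @ G  # decision values without bias
    margin = (alpha > _SV_TOL) & (alpha < C - _SV_TOL if finite_C else np.ones(n, bool))
    if margin.any():
        bias = float(np.mean(b[margin] - f[margin]))
    else:
        minus_bg = -b * grad
        up = (b == 1) & (alpha < C - _SV_TOL) | (b == -1) & (alpha > _SV_TOL)
        low = (b == -1) & (alpha < C - _SV_TOL) | (b == 1) & (alpha > _SV_TOL)
        hi = np.max(minus_bg[up]) if up.any() else 0.0
        lo = np.min(minus_bg[low]) if low.any() else 0.0
        bias = float((hi + lo) / 2.0)
    return alpha, bias


def kkt_violation(gram: np.ndarray, b: np.ndarray, alpha: np.ndarray, C: float) -> float:
    """Maximal violating-pair gap m(a) - M(a); <= 0 at the exact optimum."""
    Q = (b[:, None] * b[None, :]) * np.asarray(gram, float)
    grad = Q @ alpha - 1.0
    minus_bg = -b * grad
    up = (b == 1) & (alpha < C - _SV_TOL) | (b == -1) & (alpha > _SV_TOL)
    low = (b == -1) & (alpha < C - _SV_TOL) | (b == 1) & (alpha > _SV_TOL)
    if not up.any() or not low.any():
        return 0.0
    return float(np.max(minus_bg[up]) - np.min(minus_bg[low]))


def dual_objective(gram: np.ndarray, b: np.ndarray, alpha: np.ndarray) -> float:
    Q = (b[:, None] * b[None, :]) * np.asarray(gram, float)
    return float(alpha.sum() - 0.5 * alpha @ Q @ alpha)


class WeightedKernelSVC(BaseEstimator, ClassifierMixin):
    """Binary SVM with a prime or correlation-weighted composite kernel.

    Parameters
    ----------
    kernel : {"linear", "quadratic", "poly3", "rbf"}
        Base kernel family.
    weighted : bool
        If True, the composite per-feature kernel is used, with weights set
        from the |Pearson r| of each feature against the training labels.
    C : float
        Soft-margin box bound; ``np.inf`` recovers the hard-margin dual.
    gamma : float
        RBF width parameter, 1/(2 sigma^2).
    standardize : bool
        Z-score features using training statistics before the kernel.

    Attributes (after ``fit``)
    --------------------------
    support_vectors_, dual_alpha_, dual_labels_, intercept_, weights_,
    scaler_mean_, scaler_scale_, classes_, n_features_in_
    """

    def __init__(
        self,
        kernel: str = "poly3",
        weighted: bool = True,
        C: float = 10.0,
        gamma: float = 0.5,
        standardize: bool = True,
        tol: float = 1e-7,
        max_passes: int = 10_000,
    ):
        self.kernel = kernel
        self.weighted = weighted
        self.C = C
        self.gamma = gamma
        self.standardize = standardize
        self.tol = tol
        self.max_passes = max_passes

    def _spec(self) -> KernelSpec:
        return KernelSpec(family=self.kernel, weighted=self.weighted, gamma=self.gamma)

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("WeightedKernelSVC is a binary classifier; need exactly 2 classes")
        yy = np.where(y == self.classes_[1], 1.0, -1.0)
        spec = self._spec()

        if self.standardize:
            self.scaler_mean_ = X.mean(axis=0)
            sd = X.std(axis=0)
            self.scaler_scale_ = np.where(sd < 1e-12, 1.0, sd)
        else:
            self.scaler_mean_ = np.zeros(X.shape[1])
            self.scaler_scale_ = np.ones(X.shape[1])
        Xs = (X - self.scaler_mean_) / self.scaler_scale_

        self.weights_ = correlation_weights(Xs, (yy > 0).astype(float)) if self.weighted else None
        G = gram_matrix(Xs, spec, self.weights_)
        alpha, bias = solve_dual(G, yy, C=self.C, tol=self.tol, max_passes=self.max_passes)

        sv = alpha > _SV_TOL
        self.support_ = np.flatnonzero(sv)
        self.support_vectors_ = Xs[sv]
        self.dual_alpha_ = alpha[sv]
        self.dual_labels_ = yy[sv]
        self.intercept_ = bias
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "support_vectors_")
        X = check_array(X)
        Xs = (X - self.scaler_mean_) / self.scaler_scale_
        K = gram_matrix(self.support_vectors_, self._spec(), self.weights_, Xs)
        return (self.dual_alpha_ * self.dual_labels_) @ K + self.intercept_

    def predict(self, X) -> np.ndarray:
        # ties (f == 0) resolve to the negative ("normal") class
        f = self.decision_function(X)
        return np.where(f > 0, self.classes_[1], self.classes_[0])


@dataclass
class TrainedModel:
    """Serializable trained classifier (thin functional facade over the estimator)."""

    clf: WeightedKernelSVC

    def predict(self, X) -> np.ndarray:
        return self.clf.predict(X)

    def decision_function(self, X) -> np.ndarray:
        return self.clf.decision_function(X)


def train(ds: Dataset, spec: KernelSpec, C: float = 10.0, **kw) -> TrainedModel:
    """Train on a Dataset with leakage-free standardization and weighting."""
    clf = WeightedKernelSVC(kernel=spec.family, weighted=spec.weighted, C=C, gamma=spec.gamma, **kw)
    clf.fit(ds.X, ds.y)
    return TrainedModel(clf)


def predict(model: TrainedModel, X) -> np.ndarray:
    return model.predict(X)


def save_model(model: TrainedModel, path) -> None:
    clf = model.clf
    check_is_fitted(clf, "support_vectors_")
    payload = {
        "kernel_spec": clf._spec().to_dict(),
        "C": clf.C if math.isfinite(clf.C) else "inf",
        "support_vectors": clf.support_vectors_.tolist(),
        "alphas": clf.dual_alpha_.tolist(),
        "labels": clf.dual_labels_.tolist(),
        "bias": clf.intercept_,
        "weights": None if clf.weights_ is None else clf.weights_.tolist(),
        "scaler_mean": clf.scaler_mean_.tolist(),
        "scaler_scale": clf.scaler_scale_.tolist(),
        "classes": clf.classes_.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def load_model(path) -> TrainedModel:
    with open(path) as fh:
        d = json.load(fh)
    spec = KernelSpec.from_dict(d["kernel_spec"])
    clf = WeightedKernelSVC(
        kernel=spec.family,
        weighted=spec.weighted,
        C=math.inf if d["C"] == "inf" else float(d["C"]),
        gamma=spec.gamma,
    )
    clf.support_vectors_ = np.asarray(d["support_vectors"], float)
    clf.dual_alpha_ = np.asarray(d["alphas"], float)
    clf.dual_labels_ = np.asarray(d["labels"], float)
    clf.intercept_ = float(d["bias"])
    clf.weights_ = None if d["weights"] is None else np.asarray(d["weights"], float)
    clf.scaler_mean_ = np.asarray(d["scaler_mean"], float)
    clf.scaler_scale_ = np.asarray(d["scaler_scale"], float)
    clf.classes_ = np.asarray(d["classes"])
    clf.support_ = np.arange(len(clf.dual_alpha_))
    clf.n_features_in_ = clf.support_vectors_.shape[1]
    return TrainedModel(clf)
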