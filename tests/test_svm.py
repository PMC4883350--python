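"""Dual SVM solver vs brute-force QP oracle; estimator contracts."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize
from sklearn.svm import SVC

from ecgddd.kernels import KernelSpec, gram_matrix
from ecgddd.svm import (
    WeightedKernelSVC,
    dual_objective,
    kkt_violation,
    load_model,
    save_model,
    solve_dual,
    train,
)
from ecgddd.features import Dataset


def qp_oracle(G, b, C):
    """Generic constrained maximization of the dual via SLSQP (independent of SMO)."""
    n = len(b)
    Q = np.outer(b, b) * G

    def neg_obj(a):
        return -(a.sum() - 0.5 * a @ Q @ a)

    def neg_grad(a):
        return -(np.ones(n) - Q @ a)

    cons = [{"type": "eq", "fun": lambda a: a @ b, "jac": lambda a: b}]
    bounds = [(0.0, None if math.isinf(C) else C)] * n
    best = None
    for x0 in (np.zeros(n), np.full(n, min(C, 1.0) / 2 if math.isfinite(C) else 0.5)):
        res = minimize(neg_obj, x0, jac=neg_grad, bounds=bounds, constraints=cons,
                       method="SLSQP", options={"maxiter": 500, "ftol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    return -best.fun, best.x


def toy_instances():
    rng = np.random.default_rng(42)
    instances = []
    for n, family, C in [
        (6, "linear", 1.0),
        (8, "rbf", 10.0),
        (10, "poly3", 1.0),
        (12, "quadratic", 5.0),
        (8, "linear", math.inf),
        (12, "rbf", 0.5),
    ]:
        X = rng.normal(size=(n, 3))
        b = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
        X[b > 0] += 1.0  # partial separation
        G = gram_matrix(X, KernelSpec(family, gamma=0.5))
        instances.append((G, b, C, family))
    return instances


class TestSolveDual:
    def test_analytic_two_point_hard_margin(self):
        G = np.array([[1.0, -1.0], [-1.0, 1.0]])  # x = -1, +1; linear kernel
        alpha, bias = solve_dual(G, np.array([-1.0, 1.0]), C=math.inf)
        assert np.allclose(alpha, [0.5, 0.5], atol=1e-8)
        assert bias == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("idx", range(6))
    def test_objective_matches_qp_oracle(self, idx):
        G, b, C, family = toy_instances()[idx]
        alpha, _ = solve_dual(G, b, C)
        obj = dual_objective(G, b, alpha)
        obj_oracle, _ = qp_oracle(G, b, C)
        assert obj >= obj_oracle - 1e-4
        assert abs(obj - obj_oracle) < 1e-3

    @pytest.mark.parametrize("idx", range(6))
    def test_kkt_residuals_below_tolerance(self, idx):
        G, b, C, _ = toy_instances()[idx]
        alpha, _ = solve_dual(G, b, C)
        assert kkt_violation(G, b, alpha, C) < 1e-5
        assert abs(alpha @ b) < 1e-6
        assert np.all(alpha >= -1e-12)
        if math.isfinite(C):
            assert np.all(alpha <= C + 1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            solve_dual(np.eye(3), np.ones(3), 1.0)

    def test_agrees_with_sklearn_precomputed(self):
        """Independent cross-check: decision values match sklearn's SVC on the
        same precomputed Gram matrix."""
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 4))
        y = (X[:, 0] + 0.3 * rng.normal(size=30) > 0).astype(int)
        G = gram_matrix(X, KernelSpec("rbf", gamma=0.5))
        b = np.where(y == 1, 1.0, -1.0)
        alpha, bias = solve_dual(G, b, C=10.0)
        ref = SVC(kernel="precomputed", C=10.0, tol=1e-8).fit(G, y)
        ours = (alpha * b) @ G + bias
        theirs = ref.decision_function(G)
        assert np.allclose(ours, theirs, atol=1e-3)


class TestWeightedKernelSVC:
    def _toy(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 5))
        y = (X[:, 0] > 0).astype(int)
        X[y == 1, 0] += 2.0  # wide margin
        return X, y

    def test_separable_training_accuracy(self):
        X, y = self._toy()
        clf = WeightedKernelSVC(kernel="linear", weighted=False).fit(X, y)
        assert (clf.predict(X) == y).mean() == 1.0

    def test_prime_model_has_no_weights(self):
        X, y = self._toy()
        clf = WeightedKernelSVC(kernel="linear", weighted=False).fit(X, y)
        assert clf.weights_ is None
        wclf = WeightedKernelSVC(kernel="linear", weighted=True).fit(X, y)
        assert wclf.weights_.shape == (5,) and wclf.weights_.sum() == pytest.approx(1.0)

    def test_duplicating_points_leaves_decision_unchanged(self):
        X, y = self._toy(n=24)
        a = WeightedKernelSVC(kernel="linear", weighted=False, C=math.inf).fit(X, y)
        b = WeightedKernelSVC(kernel="linear", weighted=False, C=math.inf).fit(
            np.vstack([X, X]), np.concatenate([y, y])
        )
        probe = np.random.default_rng(2).normal(size=(50, 5))
        assert np.allclose(a.decision_function(probe), b.decision_function(probe), atol=1e-5)

    def test_two_point_model_predicts_sign(self):
        X = np.array([[-1.0], [1.0]])
        y = np.array([0, 1])
        clf = WeightedKernelSVC(kernel="linear", weighted=False, C=math.inf, standardize=False).fit(X, y)
        assert clf.predict(np.array([[2.0]]))[0] == 1
        assert clf.predict(np.array([[-2.0]]))[0] == 0
        # margin support vectors have |f| = 1
        assert np.allclose(np.abs(clf.decision_function(X)), 1.0, atol=1e-6)

    def test_prediction_invariant_to_feature_scaling(self):
        X, y = self._toy(seed=3)
        probe = np.random.default_rng(4).normal(size=(20, 5))
        a = WeightedKernelSVC(kernel="poly3", weighted=True).fit(X, y).predict(probe)
        b = WeightedKernelSVC(kernel="poly3", weighted=True).fit(X * 1000.0, y).predict(probe * 1000.0)
        assert np.array_equal(a, b)

    def test_tie_breaks_to_normal_class(self):
        clf = WeightedKernelSVC()
        clf.classes_ = np.array([0, 1])
        clf.support_vectors_ = np.zeros((1, 2))
        clf.dual_alpha_ = np.array([0.0])
        clf.dual_labels_ = np.array([1.0])
        clf.intercept_ = 0.0
        clf.weights_ = None
        clf.weighted = False
        clf.scaler_mean_ = np.zeros(2)
        clf.scaler_scale_ = np.ones(2)
        clf.n_features_in_ = 2
        assert clf.predict(np.zeros((1, 2)))[0] == 0  # f(x) = 0 -> normal

    def test_sklearn_param_interface(self):
        clf = WeightedKernelSVC(kernel="rbf", C=3.0)
        assert clf.get_params()["C"] == 3.0
        clf.set_params(C=7.0)
        assert clf.C == 7.0

    def test_model_json_round_trip(self, tmp_path):
        X, y = self._toy()
        ds = Dataset(X, y)
        model = train(ds, KernelSpec("poly3", weighted=True), C=10.0)
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        probe = np.random.default_rng(5).normal(size=(20, 5))
        assert np.allclose(model.decision_function(probe), back.decision_function(probe))
        # byte-identical on re-serialization (determinism of the artifact)
        save_model(back, tmp_path / "model2.json")
        assert (tmp_path / "model.json").read_bytes() == (tmp_path / "model2.json").read_bytes()
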