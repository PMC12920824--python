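"""Kernels, decision function, and the SMO dual solver."""

import numpy as np
import pytest
from scipy.optimize import minimize

from thermoclass.svm import (BinarySVM, KernelSpec, SVMModel, kernel_eval,
                             kernel_matrix, svm_decision, svm_train)


# --------------------------------------------------------------------------
# kernels

def test_rbf_kernel_of_identical_points_is_one():
    x = np.array([0.3, -1.2, 4.0])
    assert kernel_eval(x, x, KernelSpec(kind="rbf", gamma=0.7)) == pytest.approx(1.0)


def test_linear_kernel_orthogonal_vectors():
    assert kernel_eval(np.array([1.0, 0.0]), np.array([0.0, 3.0]),
                       KernelSpec(kind="linear")) == 0.0


def test_polynomial_kernel_matches_expansion():
    x1, x2 = np.array([1.0, 2.0]), np.array([0.5, -1.0])
    spec = KernelSpec(kind="polynomial", gamma=0.5, coef0=1.0, degree=2)
    expected = (0.5 * (1.0 * 0.5 + 2.0 * -1.0) + 1.0) ** 2
    assert kernel_eval(x1, x2, spec) == pytest.approx(expected)


def test_kernel_dimension_mismatch_rejected():
    with pytest.raises(ValueError):
        kernel_eval(np.zeros(2), np.zeros(3), KernelSpec(kind="linear"))


# --------------------------------------------------------------------------
# decision function

def machine(alphas, labels, vectors, bias, spec):
    return BinarySVM(support_vectors=np.asarray(vectors, float),
                     support_alphas=np.asarray(alphas, float),
                     support_labels=np.asarray(labels, float),
                     bias=bias, kernel=spec)


def test_zero_support_coefficients_give_bias():
    m = machine([], [], np.zeros((0, 2)), bias=0.75, spec=KernelSpec(kind="linear"))
    assert m.decision(np.array([[1.0, 2.0]]))[0] == 0.75


def test_single_support_vector_linear_decision_is_dot_product():
    sv = np.array([[2.0, -1.0]])
    m = machine([1.0], [1.0], sv, bias=0.0, spec=KernelSpec(kind="linear"))
    x = np.array([[0.5, 3.0]])
    assert m.decision(x)[0] == pytest.approx(float((sv @ x.T)[0, 0]))


def test_decision_matches_term_by_term_summation():
    spec = KernelSpec(kind="rbf", gamma=0.4)
    sv = np.array([[0.0, 0.0], [1.0, 1.0], [-1.0, 0.5]])
    alphas, labels, b = [0.3, 0.7, 0.4], [1.0, -1.0, 1.0], -0.2
    m = machine(alphas, labels, sv, b, spec)
    x = np.array([0.2, -0.3])
    expected = sum(a * y * kernel_eval(s, x, spec)
                   for a, y, s in zip(alphas, labels, sv)) + b
    assert m.decision(x)[0] == pytest.approx(expected, abs=1e-12)


# --------------------------------------------------------------------------
# training

def two_clusters(n=10, gap=4.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 0.3, (n, 2)), rng.normal(gap, 0.3, (n, 2))])
    y = np.repeat([0, 1], n)
    return X, y


def test_separable_clusters_reach_perfect_training_accuracy():
    X, y = two_clusters()
    model = svm_train(X, y, KernelSpec(kind="linear"), C=1.0, seed=0)
    assert np.array_equal(model.predict(X), y)


def test_dual_feasibility_invariants():
    X, y = two_clusters(n=8)
    model = svm_train(X, y, KernelSpec(kind="rbf", gamma=0.5), C=1.0, seed=0)
    for c, m in model.machines.items():
        assert np.all(m.support_alphas >= -1e-12)
        assert np.all(m.support_alphas <= 1.0 + 1e-9)
        assert abs(np.sum(m.support_alphas * m.support_labels)) < 1e-9


def test_duplicated_dataset_gives_same_decision_function():
    X, y = two_clusters(n=6)
    grid = np.random.default_rng(5).normal(1.5, 2.0, (20, 2))
    m1 = svm_train(X, y, KernelSpec(kind="linear"), C=10.0, seed=0)
    m2 = svm_train(np.vstack([X, X]), np.concatenate([y, y]),
                   KernelSpec(kind="linear"), C=10.0, seed=0)
    d1 = m1.decision_values(grid)
    d2 = m2.decision_values(grid)
    assert np.allclose(d1, d2, atol=5e-2)


def dual_qp_oracle(X, y_pm, C, spec):
    """Independent dual solve: SLSQP on the exact QP with box and
    equality constraints, bias from free support vectors."""
    K = kernel_matrix(X, X, spec)
    Q = (y_pm[:, None] * y_pm[None, :]) * K
    n = len(y_pm)

    def obj(a):
        return 0.5 * a @ Q @ a - a.sum()

    def grad(a):
        return Q @ a - np.ones(n)

    res = minimize(obj, np.full(n, C / 2), jac=grad, method="SLSQP",
                   bounds=[(0.0, C)] * n,
                   constraints=[{"type": "eq", "fun": lambda a: a @ y_pm,
                                 "jac": lambda a: y_pm}],
                   options={"maxiter": 500, "ftol": 1e-12})
    a = res.x
    free = (a > 1e-6) & (a < C - 1e-6)
    dec_no_b = (a * y_pm) @ K
    if free.any():
        b = np.mean(y_pm[free] - dec_no_b[free])
    else:
        b = np.mean(y_pm - dec_no_b)
    return a, b, dec_no_b + b


def test_smo_matches_exhaustive_dual_oracle():
    """Decision values of the SMO solver agree with an independent QP solve
    on a 6-point problem within 1e-3."""
    X = np.array([[0.0, 0.0], [0.5, 0.2], [0.2, 0.6],
                  [2.0, 2.0], [2.5, 1.8], [1.8, 2.4]])
    y = np.array([0, 0, 0, 1, 1, 1])
    spec = KernelSpec(kind="rbf", gamma=0.5)
    model = svm_train(X, y, spec, C=1.0, tol=1e-5, max_passes=50, seed=0)
    y_pm = np.where(y == 1, 1.0, -1.0)
    _, _, dec_oracle = dual_qp_oracle(X, y_pm, 1.0, spec)
    dec_smo = model.machines[1].decision(X)
    assert np.allclose(dec_smo, dec_oracle, atol=1e-3)


def test_smo_agrees_with_reference_svc():
    from sklearn.svm import SVC

    X, y = two_clusters(n=7, gap=2.5, seed=3)
    spec = KernelSpec(kind="rbf", gamma=0.8)
    ours = svm_train(X, y, spec, C=1.0, tol=1e-5, max_passes=50, seed=0)
    ref = SVC(kernel="rbf", gamma=0.8, C=1.0, tol=1e-6).fit(X, np.where(y == 1, 1, -1))
    grid = np.random.default_rng(6).normal(1.2, 1.5, (15, 2))
    assert np.allclose(ours.machines[1].decision(grid),
                       ref.decision_function(grid), atol=1e-2)


def test_single_class_rejected():
    with pytest.raises(ValueError):
        svm_train(np.zeros((4, 2)), np.zeros(4, dtype=int))


def test_one_vs_one_scheme_votes():
    X, y = two_clusters(n=6)
    model = svm_train(X, y, KernelSpec(kind="linear"), scheme="ovo", seed=0)
    assert np.array_equal(model.predict(X), y)


def test_prediction_tie_breaks_to_lowest_class_index():
    spec = KernelSpec(kind="linear")
    m = machine([], [], np.zeros((0, 2)), bias=0.5, spec=spec)
    model = SVMModel(classes=[0, 1], machines={0: m, 1: m}, scheme="ovr")
    assert model.predict(np.array([[1.0, 1.0]]))[0] == 0


def test_untrained_class_decision_raises():
    model = SVMModel(classes=[0, 1], machines={}, scheme="ovr")
    with pytest.raises(RuntimeError):
        svm_decision(np.zeros(2), model, 0)
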