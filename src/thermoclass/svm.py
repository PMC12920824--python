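"""Kernel support-vector machine with an in-package SMO dual solver.

The binary decision function is

    f(x) = Σ_i α_i y_i K(x_i, x) + b,

with dual variables 0 ≤ α_i ≤ C satisfying Σ_i α_i y_i = 0.  The solver is
a simplified sequential-minimal-optimization (SMO) ascent: pairs of dual
variables are updated jointly so the equality constraint is preserved
exactly at every step.  Multi-class problems use one-vs-rest by default
(one binary machine per class, prediction by the largest decision value);
one-vs-one is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family and parameters.

    linear: K = x1·x2; polynomial: K = (γ x1·x2 + c0)^d;
    rbf: K = exp(−γ ‖x1−x2‖²).  γ=None means 1/n_features.
    """

    kind: str = "rbf"
    gamma: float | None = None
    coef0: float = 0.0
    degree: int = 3

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "polynomial", "rbf"):
            raise ValueError(f"unknown kernel {self.kind!r}")


def _gamma(spec: KernelSpec, n_features: int) -> float:
    return spec.gamma if spec.gamma is not None else 1.0 / n_features


def kernel_eval(x1: np.ndarray, x2: np.ndarray, spec: KernelSpec) -> float:
    """Kernel value for a single pair of equal-length vectors."""
    x1 = np.asarray(x1, dtype=np.float64)
    x2 = np.asarray(x2, dtype=np.float64)
    if x1.shape != x2.shape:
        raise ValueError("kernel arguments must have equal dimension")
    return float(kernel_matrix(x1[None, :], x2[None, :], spec)[0, 0])


def kernel_matrix(X1: np.ndarray, X2: np.ndarray, spec: KernelSpec) -> np.ndarray:
    X1 = np.atleast_2d(np.asarray(X1, dtype=np.float64))
    X2 = np.atleast_2d(np.asarray(X2, dtype=np.float64))
    if X1.shape[1] != X2.shape[1]:
        raise ValueError("kernel arguments must have equal dimension")
    if spec.kind == "linear":
        return X1 @ X2.T
    g = _gamma(spec, X1.shape[1])
    if spec.kind == "polynomial":
        return (g * (X1 @ X2.T) + spec.coef0) ** spec.degree
    sq = (np.sum(X1 ** 2, axis=1)[:, None] + np.sum(X2 ** 2, axis=1)[None, :]
          - 2.0 * X1 @ X2.T)
    return np.exp(-g * np.maximum(sq, 0.0))


# --------------------------------------------------------------------------

@dataclass
class BinarySVM:
    """One trained binary machine: support data and bias for f(x)."""

    support_vectors: np.ndarray
    support_alphas: np.ndarray  # α_i ≥ 0
    support_labels: np.ndarray  # y_i ∈ {−1, +1}
    bias: float
    kernel: KernelSpec

    def decision(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if self.support_vectors.shape[0] == 0:
            return np.full(X.shape[0], self.bias)
        K = kernel_matrix(self.support_vectors, X, self.kernel)
        return (self.support_alphas * self.support_labels) @ K + self.bias


@dataclass
class SVMModel:
    """Multi-class margin classifier (one binary machine per class pair/rest)."""

    classes: list
    machines: dict = field(default_factory=dict)  # class -> BinarySVM (OvR)
    scheme: str = "ovr"

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        """(n_samples, n_classes) decision scores in fixed class order."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if self.scheme == "ovr":
            return np.column_stack([self.machines[c].decision(X) for c in self.classes])
        votes = np.zeros((X.shape[0], len(self.classes)))
        for (i, j), machine in self.machines.items():
            d = machine.decision(X)
            votes[:, i] += (d > 0)
            votes[:, j] += (d <= 0)
        return votes

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Class with the largest decision value; ties go to the lowest index."""
        return np.argmax(self.decision_values(X), axis=1)


def svm_decision(x: np.ndarray, model: SVMModel, class_index: int) -> float:
    """One-vs-rest decision value f(x) for the given class."""
    if model.scheme != "ovr":
        raise ValueError("per-class decision values require the one-vs-rest scheme")
    c = model.classes[class_index]
    if c not in model.machines:
        raise RuntimeError(f"no trained machine for class {c!r}")
    return float(model.machines[c].decision(x)[0])


# --------------------------------------------------------------------------
# SMO solver

def _smo_binary(K: np.ndarray, y: np.ndarray, C: float, tol: float,
                max_passes: int, rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Simplified SMO on a precomputed kernel matrix.

    Maintains Σ α_i y_i = 0 by updating (α_i, α_j) pairs jointly with box
    clipping; terminates after ``max_passes`` sweeps without a KKT
    violation larger than ``tol``.
    """
    n = len(y)
    alpha = np.zeros(n)
    b = 0.0
    passes = 0
    max_total = 200 * max(n, 10)
    total = 0
    while passes < max_passes and total < max_total:
        changed = 0
        total += 1
        for i in range(n):
            Ei = (alpha * y) @ K[:, i] + b - y[i]
            if not ((y[i] * Ei < -tol and alpha[i] < C) or (y[i] * Ei > tol and alpha[i] > 0)):
                continue
            j = int(rng.integers(n - 1))
            if j >= i:
                j += 1
            Ej = (alpha * y) @ K[:, j] + b - y[j]
            ai_old, aj_old = alpha[i], alpha[j]
            if y[i] != y[j]:
                L, H = max(0.0, aj_old - ai_old), min(C, C + aj_old - ai_old)
            else:
                L, H = max(0.0, ai_old + aj_old - C), min(C, ai_old + aj_old)
            if H - L < 1e-12:
                continue
            eta = 2.0 * K[i, j] - K[i, i] - K[j, j]
            if eta >= 0:
                continue
            aj = np.clip(aj_old - y[j] * (Ei - Ej) / eta, L, H)
            if abs(aj - aj_old) < 1e-7:
                continue
            ai = ai_old + y[i] * y[j] * (aj_old - aj)
            alpha[i], alpha[j] = ai, aj
            b1 = b - Ei - y[i] * (ai - ai_old) * K[i, i] - y[j] * (aj - aj_old) * K[i, j]
            b2 = b - Ej - y[i] * (ai - ai_old) * K[i, j] - y[j] * (aj - aj_old) * K[j, j]
            if 0 < ai < C:
                b = b1
            elif 0 < aj < C:
                b = b2
            else:
                b = 0.5 * (b1 + b2)
            changed += 1
        passes = passes + 1 if changed == 0 else 0
    return alpha, b


def _fit_binary(X: np.ndarray, y_pm: np.ndarray, kernel: KernelSpec, C: float,
                tol: float, max_passes: int, rng: np.random.Generator) -> BinarySVM:
    K = kernel_matrix(X, X, kernel)
    alpha, b = _smo_binary(K, y_pm.astype(np.float64), C, tol, max_passes, rng)
    sv = alpha > 1e-10
    return BinarySVM(support_vectors=X[sv], support_alphas=alpha[sv],
                     support_labels=y_pm[sv].astype(np.float64), bias=b,
                     kernel=kernel)


def svm_train(X: np.ndarray, y: np.ndarray, kernel: KernelSpec = KernelSpec(),
              C: float = 1.0, tol: float = 1e-4, max_passes: int = 10,
              scheme: str = "ovr", seed: int = 0) -> SVMModel:
    """Train the multi-class margin classifier on embeddings/features.

    ``y`` holds integer class indices.  Deterministic for a fixed seed
    (the SMO working-pair choice is the only randomized ingredient).
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=np.int64)
    classes = sorted(np.unique(y).tolist())
    if len(classes) < 2:
        raise ValueError("svm_train requires at least two classes")

    model = SVMModel(classes=classes, scheme=scheme)
    if scheme == "ovr":
        for c in classes:
            rng = np.random.default_rng(np.random.SeedSequence([seed, c]))
            y_pm = np.where(y == c, 1.0, -1.0)
            model.machines[c] = _fit_binary(X, y_pm, kernel, C, tol, max_passes, rng)
    elif scheme == "ovo":
        for a_idx in range(len(classes)):
            for b_idx in range(a_idx + 1, len(classes)):
                rng = np.random.default_rng(np.random.SeedSequence([seed, a_idx, b_idx]))
                mask = (y == classes[a_idx]) | (y == classes[b_idx])
                y_pm = np.where(y[mask] == classes[a_idx], 1.0, -1.0)
                model.machines[(a_idx, b_idx)] = _fit_binary(
                    X[mask], y_pm, kernel, C, tol, max_passes, rng)
    else:
        raise ValueError("scheme must be 'ovr' or 'ovo'")
    return model
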