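"""Dataset splitting, classification metrics, ROC/AUC and k-fold CV.

Splitting uses largest-remainder apportionment so fractional per-class
targets round to integer counts that are reproducible and seed-independent
(only *which* records land in each partition is shuffled).  Metrics are
one-vs-rest per class; ratios with zero denominators are reported as
undefined (None) and excluded from macro averages rather than silently
zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

PARTITIONS = ("train", "test", "validation")


# --------------------------------------------------------------------------
# stratified splitting

def largest_remainder(total: int, fractions: tuple[float, ...]) -> list[int]:
    """Apportion ``total`` into integer counts proportional to ``fractions``.

    Floors first, then hands the leftover units to the largest fractional
    remainders; remainder ties go to the earlier position.
    """
    exact = [f * total for f in fractions]
    counts = [int(np.floor(e)) for e in exact]
    leftover = total - sum(counts)
    remainders = sorted(range(len(fractions)),
                        key=lambda i: (-(exact[i] - counts[i]), i))
    for i in remainders[:leftover]:
        counts[i] += 1
    return counts


@dataclass
class DatasetSplit:
    """Per-partition record indices; disjoint, covering all records."""

    train: np.ndarray
    test: np.ndarray
    validation: np.ndarray
    per_class_counts: dict = field(default_factory=dict)

    def counts(self) -> tuple[int, int, int]:
        return len(self.train), len(self.test), len(self.validation)


def stratified_split(labels, fractions: tuple[float, float, float] = (0.70, 0.20, 0.10),
                     seed: int = 0) -> DatasetSplit:
    """Split record indices into train/test/validation, stratified by class.

    Within each class the target counts come from largest-remainder
    apportionment of fraction × class_total (counts are therefore
    seed-independent); the assignment of individual records is shuffled
    with the seed.
    """
    labels = np.asarray(labels)
    fractions = tuple(float(f) for f in fractions)
    if any(f <= 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be positive and sum to 1")

    rng = np.random.default_rng(seed)
    parts: dict[str, list[int]] = {p: [] for p in PARTITIONS}
    per_class: dict = {}
    # iterate classes in stable first-appearance order
    seen = list(dict.fromkeys(labels.tolist()))
    for cls in seen:
        idx = np.flatnonzero(labels == cls)
        counts = largest_remainder(len(idx), fractions)
        per_class[cls] = tuple(counts)
        idx = idx[rng.permutation(len(idx))]
        start = 0
        for part, c in zip(PARTITIONS, counts):
            parts[part].extend(idx[start: start + c].tolist())
            start += c
    return DatasetSplit(train=np.array(sorted(parts["train"]), dtype=np.int64),
                        test=np.array(sorted(parts["test"]), dtype=np.int64),
                        validation=np.array(sorted(parts["validation"]), dtype=np.int64),
                        per_class_counts=per_class)


# --------------------------------------------------------------------------
# confusion matrix and derived metrics

def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    """Count grid with rows = true class, columns = predicted class."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size and (y_true.min() < 0 or y_true.max() >= n_classes
                        or y_pred.min() < 0 or y_pred.max() >= n_classes):
        raise ValueError("labels out of range")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


@dataclass
class MetricsReport:
    """Accuracy plus per-class and macro one-vs-rest metrics.

    Per-class entries are None when the defining ratio is 0/0 (e.g.
    precision with no predicted positives); macro averages are taken over
    the defined classes only, and ``undefined`` records which class/metric
    pairs were excluded.
    """

    accuracy: float
    precision: list
    sensitivity: list
    specificity: list
    f1: list
    macro_precision: float | None
    macro_sensitivity: float | None
    macro_specificity: float | None
    macro_f1: float | None
    undefined: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "f1": self.f1,
            "macro_precision": self.macro_precision,
            "macro_sensitivity": self.macro_sensitivity,
            "macro_specificity": self.macro_specificity,
            "macro_f1": self.macro_f1,
            "undefined": self.undefined,
        }


def _ratio(num: float, den: float):
    return None if den == 0 else num / den


def compute_metrics(cm: np.ndarray, average: str = "macro") -> MetricsReport:
    """One-vs-rest precision/sensitivity/specificity/F1 from a confusion matrix."""
    cm = np.asarray(cm, dtype=np.float64)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    n = cm.shape[0]
    accuracy = float(np.trace(cm) / total)

    precision, sensitivity, specificity, f1, undefined = [], [], [], [], []
    for c in range(n):
        tp = cm[c, c]
        fn = cm[c, :].sum() - tp
        fp = cm[:, c].sum() - tp
        tn = total - tp - fn - fp
        p = _ratio(tp, tp + fp)
        r = _ratio(tp, tp + fn)
        s = _ratio(tn, tn + fp)
        if p is None:
            undefined.append((c, "precision"))
        if r is None:
            undefined.append((c, "sensitivity"))
        if s is None:
            undefined.append((c, "specificity"))
        if p is None or r is None or (p + r) == 0:
            f = None
            undefined.append((c, "f1"))
        else:
            f = 2 * p * r / (p + r)
        precision.append(p); sensitivity.append(r)
        specificity.append(s); f1.append(f)

    if average == "micro":
        # micro one-vs-rest: pooled TP/FP/FN over classes
        tp_all = np.trace(cm)
        macro_p = macro_r = float(tp_all / total)
        macro_f = macro_p
        tn_all = sum(total - cm[c, :].sum() - cm[:, c].sum() + cm[c, c] for c in range(n))
        macro_s = float(tn_all / (tn_all + (total - tp_all)))
    else:
        def _macro(vals):
            defined = [v for v in vals if v is not None]
            return float(np.mean(defined)) if defined else None
        macro_p, macro_r = _macro(precision), _macro(sensitivity)
        macro_s, macro_f = _macro(specificity), _macro(f1)

    return MetricsReport(accuracy=accuracy, precision=precision,
                         sensitivity=sensitivity, specificity=specificity,
                         f1=f1, macro_precision=macro_p,
                         macro_sensitivity=macro_r, macro_specificity=macro_s,
                         macro_f1=macro_f, undefined=undefined)


# --------------------------------------------------------------------------
# ROC / AUC

def roc_curve_auc(scores, labels) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """ROC points and trapezoidal AUC for one binary problem.

    Returns (fpr, tpr, thresholds, auc).  Tied scores move along the curve
    together (one point per distinct threshold).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thr = _sk_roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, thr, auc


def per_class_auc(decision_values: np.ndarray, y_true, n_classes: int) -> list:
    """One-vs-rest AUC per class (None when a class is absent) and their macro mean."""
    y_true = np.asarray(y_true)
    aucs = []
    for c in range(n_classes):
        binary = (y_true == c).astype(int)
        if binary.min() == binary.max():
            aucs.append(None)
            continue
        aucs.append(roc_curve_auc(decision_values[:, c], binary)[3])
    return aucs


# --------------------------------------------------------------------------
# cross-validation

@dataclass
class FoldResult:
    fold_index: int  # 1-based
    metrics: MetricsReport
    confusion: np.ndarray
    n_errors: int
    auc_per_class: list
    macro_auc: float | None

    def __post_init__(self) -> None:
        assert self.n_errors == int(self.confusion.sum() - np.trace(self.confusion))


def kfold_indices(labels, k: int = 5, seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold (train_idx, held_out_idx) pairs, seed-shuffled."""
    labels = np.asarray(labels)
    counts = np.bincount(labels.astype(np.int64))
    if counts[counts > 0].min() < k:
        raise ValueError(f"every class needs at least k={k} samples")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(labels)), labels)]


def kfold_cross_validate(X: np.ndarray, y: np.ndarray, fit_predict,
                         k: int = 5, seed: int = 0) -> list[FoldResult]:
    """Generic stratified k-fold driver.

    ``fit_predict(X_train, y_train, X_test, fold_seed)`` must return
    ``(y_pred, decision_values)`` with decision values shaped
    (n_test, n_classes).  Every sample is held out exactly once.
    """
    y = np.asarray(y, dtype=np.int64)
    n_classes = int(y.max()) + 1
    results = []
    for f, (tr, te) in enumerate(kfold_indices(y, k, seed)):
        y_pred, dec = fit_predict(X[tr], y[tr], X[te], seed + 1000 * (f + 1))
        cm = confusion_matrix(y[te], y_pred, n_classes)
        aucs = per_class_auc(dec, y[te], n_classes) if dec is not None else [None] * n_classes
        defined = [a for a in aucs if a is not None]
        results.append(FoldResult(
            fold_index=f + 1, metrics=compute_metrics(cm), confusion=cm,
            n_errors=int(cm.sum() - np.trace(cm)), auc_per_class=aucs,
            macro_auc=float(np.mean(defined)) if defined else None))
    return results


def error_histogram(folds: list[FoldResult]) -> tuple[list[int], float, float | None]:
    """Per-fold error counts with their mean and sample (n−1) std.

    The std is None for a single fold (degenerate).
    """
    if not folds:
        raise ValueError("no folds")
    errors = [f.n_errors for f in folds]
    mean = float(np.mean(errors))
    std = float(np.std(errors, ddof=1)) if len(errors) > 1 else None
    return errors, mean, std
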