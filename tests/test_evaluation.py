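"""Splitting, metrics, ROC/AUC, cross-validation, error accounting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thermoclass.evaluation import (FoldResult, compute_metrics, confusion_matrix,
                                    error_histogram, kfold_cross_validate,
                                    kfold_indices, largest_remainder,
                                    roc_curve_auc, stratified_split)


# --------------------------------------------------------------------------
# stratified splitting

def test_split_reproduces_published_class_table():
    """(350, 300, 250, 439) at (0.7, 0.2, 0.1) apportions to the exact
    per-class and total partition counts of the study design."""
    labels = np.repeat(np.arange(4), [350, 300, 250, 439])
    split = stratified_split(labels, (0.70, 0.20, 0.10), seed=5)
    assert split.per_class_counts[0] == (245, 70, 35)
    assert split.per_class_counts[1] == (210, 60, 30)
    assert split.per_class_counts[2] == (175, 50, 25)
    assert split.per_class_counts[3] == (307, 88, 44)
    assert split.counts() == (937, 268, 134)
    assert sum(split.counts()) == 1339


def test_split_counts_are_seed_independent():
    labels = np.repeat([0, 1], [439, 17])
    c1 = stratified_split(labels, seed=1).per_class_counts
    c2 = stratified_split(labels, seed=99).per_class_counts
    assert c1 == c2


def test_largest_remainder_single_class_of_ten():
    assert largest_remainder(10, (0.7, 0.2, 0.1)) == [7, 2, 1]


def test_largest_remainder_tie_goes_to_earlier_partition():
    # 5 * (0.5, 0.3, 0.2) = (2.5, 1.5, 1.0): remainders tie at 0.5
    assert largest_remainder(5, (0.5, 0.3, 0.2)) == [3, 1, 1]


@settings(deadline=None, max_examples=60)
@given(st.lists(st.integers(0, 3), min_size=1, max_size=80),
       st.integers(0, 1000))
def test_split_conservation_property(labels, seed):
    labels = np.asarray(labels)
    split = stratified_split(labels, (0.70, 0.20, 0.10), seed=seed)
    all_idx = np.concatenate([split.train, split.test, split.validation])
    assert len(all_idx) == len(labels)
    assert len(np.unique(all_idx)) == len(labels)
    for cls, counts in split.per_class_counts.items():
        assert sum(counts) == int((labels == cls).sum())


def test_split_rejects_bad_fractions():
    with pytest.raises(ValueError):
        stratified_split([0, 1], (0.5, 0.5, 0.5))


# --------------------------------------------------------------------------
# confusion matrix and metrics

def test_confusion_perfect_predictions_are_diagonal():
    y = np.array([0, 1, 2, 2, 1])
    cm = confusion_matrix(y, y, 3)
    assert np.trace(cm) == 5 and cm.sum() == 5


def test_confusion_empty_inputs_give_zero_matrix():
    assert confusion_matrix([], [], 3).sum() == 0


def test_confusion_matches_hand_tally():
    y_true = [0, 0, 1, 2, 2, 2]
    y_pred = [0, 1, 1, 2, 0, 2]
    cm = confusion_matrix(y_true, y_pred, 3)
    assert np.array_equal(cm, [[1, 1, 0], [0, 1, 0], [1, 0, 2]])


def test_confusion_label_out_of_range():
    with pytest.raises(ValueError):
        confusion_matrix([0, 3], [0, 1], 3)


def test_metrics_perfect_matrix_all_ones():
    rep = compute_metrics(np.diag([5, 3, 7]))
    assert rep.accuracy == 1.0
    assert rep.macro_precision == rep.macro_sensitivity == rep.macro_f1 == 1.0
    assert rep.macro_specificity == 1.0


def test_metrics_binary_formula_values():
    cm = np.array([[8, 2], [1, 9]])  # TP=8 FN=2 / FP=1 TN=9 for class 0
    rep = compute_metrics(cm)
    assert rep.sensitivity[0] == pytest.approx(0.8)
    assert rep.specificity[0] == pytest.approx(0.9)
    assert rep.precision[0] == pytest.approx(8 / 9)
    p, r = 8 / 9, 0.8
    assert rep.f1[0] == pytest.approx(2 * p * r / (p + r), abs=1e-12)


def test_accuracy_invariant_under_class_permutation(rng):
    cm = rng.integers(0, 20, (4, 4))
    perm = rng.permutation(4)
    a1 = compute_metrics(cm).accuracy
    a2 = compute_metrics(cm[np.ix_(perm, perm)]).accuracy
    assert a1 == pytest.approx(a2)


def test_zero_denominator_metrics_flagged_not_zeroed():
    # class 2 never predicted and never true
    cm = np.array([[3, 0, 0], [0, 4, 0], [0, 0, 0]])
    rep = compute_metrics(cm)
    assert rep.precision[2] is None and rep.sensitivity[2] is None
    assert (2, "precision") in rep.undefined
    assert rep.macro_precision == 1.0  # average over defined classes only


def test_metrics_bounds_on_random_matrices(rng):
    for _ in range(200):
        cm = rng.integers(0, 30, (3, 3))
        if cm.sum() == 0:
            continue
        rep = compute_metrics(cm)
        for vals in (rep.precision, rep.sensitivity, rep.specificity, rep.f1):
            for v in vals:
                assert v is None or 0.0 <= v <= 1.0
        assert 0.0 <= rep.accuracy <= 1.0


def test_micro_average_equals_accuracy():
    cm = np.array([[5, 1, 0], [2, 6, 1], [0, 1, 4]])
    rep = compute_metrics(cm, average="micro")
    assert rep.macro_precision == pytest.approx(rep.accuracy)


# --------------------------------------------------------------------------
# ROC / AUC

def mann_whitney_auc(scores, labels):
    """Tie-aware pair-counting AUC oracle."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_perfect_separation_auc_one():
    scores = [0.1, 0.2, 0.8, 0.9]
    labels = [0, 0, 1, 1]
    assert roc_curve_auc(scores, labels)[3] == pytest.approx(1.0)


def test_constant_scores_auc_half():
    assert roc_curve_auc([0.5] * 6, [0, 1, 0, 1, 0, 1])[3] == pytest.approx(0.5)


def test_auc_matches_pair_counting_oracle():
    scores = [0.9, 0.8, 0.8, 0.6, 0.55, 0.5, 0.3, 0.2]
    labels = [1, 1, 0, 1, 0, 0, 1, 0]
    assert roc_curve_auc(scores, labels)[3] == pytest.approx(
        mann_whitney_auc(scores, labels), abs=1e-12)


def test_auc_equivalence_random_scores_with_ties(rng):
    for _ in range(30):
        scores = rng.integers(0, 5, 20) / 4.0  # heavy ties
        labels = rng.integers(0, 2, 20)
        if labels.min() == labels.max():
            continue
        assert roc_curve_auc(scores, labels)[3] == pytest.approx(
            mann_whitney_auc(scores, labels), abs=1e-12)


def test_single_class_labels_rejected():
    with pytest.raises(ValueError):
        roc_curve_auc([0.1, 0.9], [1, 1])


# --------------------------------------------------------------------------
# cross-validation

@pytest.mark.parametrize("k", [2, 3, 5])
def test_kfold_partition_covers_dataset_disjointly(k, rng):
    labels = rng.integers(0, 3, 60)
    folds = kfold_indices(labels, k=k, seed=4)
    held = np.concatenate([te for _, te in folds])
    assert len(held) == 60 and len(np.unique(held)) == 60
    for tr, te in folds:
        assert len(np.intersect1d(tr, te)) == 0


def test_kfold_deterministic_for_seed(rng):
    labels = rng.integers(0, 4, 40)
    f1 = kfold_indices(labels, 5, seed=2)
    f2 = kfold_indices(labels, 5, seed=2)
    for (tr1, te1), (tr2, te2) in zip(f1, f2):
        assert np.array_equal(te1, te2)


def test_kfold_small_class_rejected():
    with pytest.raises(ValueError):
        kfold_indices([0, 0, 0, 1], k=3)


def test_kfold_driver_collects_metrics():
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(0, 0.3, (10, 2)), rng.normal(3, 0.3, (10, 2))])
    y = np.repeat([0, 1], 10)

    def fit_predict(X_tr, y_tr, X_te, seed):
        centers = [X_tr[y_tr == c].mean(axis=0) for c in (0, 1)]
        d = np.stack([-np.linalg.norm(X_te - c, axis=1) for c in centers], axis=1)
        return np.argmax(d, axis=1), d

    folds = kfold_cross_validate(X, y, fit_predict, k=5, seed=0)
    assert len(folds) == 5
    for f in folds:
        assert f.metrics.accuracy == 1.0 and f.n_errors == 0
        assert f.macro_auc == pytest.approx(1.0)


# --------------------------------------------------------------------------
# error histogram

def make_fold(idx, n_errors, n=10):
    cm = np.diag([n - n_errors, n])
    cm[0, 1] = n_errors
    return FoldResult(fold_index=idx, metrics=compute_metrics(cm), confusion=cm,
                      n_errors=n_errors, auc_per_class=[None, None], macro_auc=None)


def test_error_histogram_published_style_summary():
    folds = [make_fold(i + 1, e) for i, e in enumerate([1, 1, 1, 2, 2])]
    errors, mean, std = error_histogram(folds)
    assert errors == [1, 1, 1, 2, 2]
    assert mean == pytest.approx(1.4)
    assert std == pytest.approx(0.5477, abs=1e-4)


def test_error_histogram_zero_errors():
    folds = [make_fold(i + 1, 0) for i in range(3)]
    assert error_histogram(folds) == ([0, 0, 0], 0.0, 0.0)


def test_error_histogram_single_fold_std_degenerate():
    _, mean, std = error_histogram([make_fold(1, 2)])
    assert mean == 2.0 and std is None
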