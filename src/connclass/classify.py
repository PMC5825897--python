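"""Leakage-safe leave-one-out classification and permutation significance.

Each LOOCV fold re-runs the whole feature-selection stage (one-sample
screen, pair-concordance ranking, top-k cut) on the n-1 training subjects
only; the held-out subject is projected onto the fold's selected features
and scored.  Pooled held-out predictions give the confusion counts,
accuracy / recall / specificity / F1, and one ROC curve whose AUC is the
trapezoidal area (equal, absent ties, to the Mann-Whitney exceedance
probability).

Significance of the observed accuracy comes from a label-permutation null:
each replicate permutes the class labels across the whole cohort, re-runs
the full wrapped pipeline, and the p-value is

    p = (#{acc(permuted) > acc(observed)} + 1) / (m + 1)

so the attainable floor is 1/(m+1) — about 1e-4 at the conventional
m = 10,000.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.neighbors import KNeighborsClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .errors import (
    ConfigurationError,
    DegenerateInputError,
    InsufficientDataError,
    ShapeError,
)
from .selection import (
    FeatureTable,
    SelectionConfig,
    rank_features,
    screen_one_sample,
    select_top_k,
)

__all__ = [
    "ClassifierSpec",
    "ConfusionCounts",
    "Metrics",
    "FoldRecord",
    "CVResult",
    "PermutationResult",
    "loocv_classify",
    "confusion_counts",
    "metrics",
    "roc_auc",
    "permutation_test",
]

logger = logging.getLogger("connclass")

_FAMILIES = ("linear_svm", "nonlinear_svm", "knn", "logistic")


@dataclass
class ClassifierSpec:
    """Classifier family plus optional hyperparameter overrides.

    Defaults follow common toolkit settings: SVMs at C=1 (RBF width
    1/(k * feature variance), the toolkit's "scale"), 5 Euclidean neighbors
    for KNN, L2-penalized logistic regression at unit strength.
    """

    family: str = "linear_svm"
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ConfigurationError(
                f"unknown classifier family {self.family!r}; choose from {_FAMILIES}"
            )

    def build(self):
        h = self.hyperparameters
        if self.family == "linear_svm":
            return SVC(kernel="linear", C=h.get("C", 1.0))
        if self.family == "nonlinear_svm":
            return SVC(kernel="rbf", C=h.get("C", 1.0), gamma=h.get("gamma", "scale"))
        if self.family == "knn":
            return KNeighborsClassifier(n_neighbors=h.get("n_neighbors", 5))
        return LogisticRegression(C=h.get("C", 1.0), max_iter=h.get("max_iter", 1000))


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class Metrics:
    accuracy: float
    recall: float
    specificity: float
    f1: float


@dataclass
class FoldRecord:
    subject_id: str
    true_label: bool
    predicted_label: bool
    decision_score: float
    selected_features: np.ndarray
    linear_weights: np.ndarray | None


@dataclass
class CVResult:
    folds: list[FoldRecord]
    feature_names: list[str]
    counts: ConfusionCounts
    accuracy: float
    recall: float
    specificity: float
    f1: float
    auc: float
    roc_points: np.ndarray

    @property
    def predictions(self) -> np.ndarray:
        return np.array([f.predicted_label for f in self.folds])

    @property
    def truths(self) -> np.ndarray:
        return np.array([f.true_label for f in self.folds])


@dataclass
class PermutationResult:
    m_permutations: int
    observed_accuracy: float
    null_accuracies: list[float]
    p_value: float


def confusion_counts(
    predicted: Sequence[bool], truth: Sequence[bool]
) -> ConfusionCounts:
    """Counts with patients positive: tp = patients predicted patients, etc."""
    pred = np.asarray(predicted, dtype=bool)
    true = np.asarray(truth, dtype=bool)
    if pred.shape != true.shape:
        raise ShapeError("predicted and truth must have equal length")
    return ConfusionCounts(
        tp=int(np.sum(pred & true)),
        fp=int(np.sum(pred & ~true)),
        tn=int(np.sum(~pred & ~true)),
        fn=int(np.sum(~pred & true)),
    )


def metrics(c: ConfusionCounts) -> Metrics:
    """Accuracy, recall, specificity, F1 as exact ratios.

    A ratio with a zero denominator is undefined and reported as NaN, never
    as 0.
    """
    if c.total == 0:
        raise InsufficientDataError("no evaluated samples")
    acc = (c.tp + c.tn) / c.total
    rec = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else math.nan
    spe = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else math.nan
    f1 = 2 * c.tp / (2 * c.tp + c.fp + c.fn) if (2 * c.tp + c.fp + c.fn) else math.nan
    return Metrics(accuracy=acc, recall=rec, specificity=spe, f1=f1)


def roc_auc(
    scores: Sequence[float], truth: Sequence[bool]
) -> tuple[np.ndarray, float]:
    """ROC over all score thresholds and its trapezoidal area.

    Returns an (n_points, 2) array of (false-positive rate, true-positive
    rate) and the AUC.  Tied scores move the curve diagonally in one step.
    """
    true = np.asarray(truth, dtype=bool)
    if true.all() or not true.any():
        raise DegenerateInputError("ROC needs both classes in the truth labels")
    fpr, tpr, _ = _sk_roc_curve(true.astype(int), np.asarray(scores, dtype=float))
    return np.column_stack([fpr, tpr]), float(_sk_auc(fpr, tpr))


def _decision_score(clf, spec: ClassifierSpec, x_row: np.ndarray) -> float:
    if spec.family in ("linear_svm", "nonlinear_svm"):
        return float(clf.decision_function(x_row)[0])
    proba = clf.predict_proba(x_row)[0]
    pos_col = int(np.flatnonzero(clf.classes_ == 1)[0])
    return float(proba[pos_col])


def loocv_classify(
    table: FeatureTable, spec: ClassifierSpec, fs: SelectionConfig
) -> CVResult:
    """Leave-one-out cross-validation with per-fold feature selection.

    Subjects are processed in sorted-id order so the result does not depend
    on row order.  If no feature survives a fold's screen the fold falls
    back to ranking all features (logged via warning by ``select_top_k``
    when k then clips).
    """
    labels = table.labels
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise InsufficientDataError("need at least 2 subjects per class")
    if fs.k < 1:
        raise ConfigurationError("k must be at least 1")

    order = np.argsort(np.asarray(table.subjects, dtype=object))
    global_screen = (
        screen_one_sample(table, fs.alpha) if fs.unwrapped_screen else None
    )

    folds: list[FoldRecord] = []
    n_clipped = 0
    for i in order:
        train_mask = np.ones(table.n_subjects, dtype=bool)
        train_mask[i] = False
        if labels[train_mask].sum() == 0 or (~labels[train_mask]).sum() == 0:
            raise InsufficientDataError(
                f"training fold for {table.subjects[i]} lost a whole class"
            )
        tr = table.subset(train_mask)
        screen = global_screen if global_screen is not None else screen_one_sample(tr, fs.alpha)
        if not screen.any():
            screen = np.ones(table.n_features, dtype=bool)
        ranking = rank_features(tr, screen)
        # aggregate per-fold clip warnings into one log line per run
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            sel = select_top_k(ranking, fs.k)
        n_clipped += bool(caught)
        clf = spec.build()
        clf.fit(tr.values[:, sel], tr.labels.astype(int))
        x_test = table.values[i, sel][None, :]
        pred = bool(clf.predict(x_test)[0])
        score = _decision_score(clf, spec, x_test)
        weights = None
        if spec.family == "linear_svm":
            weights = np.asarray(clf.coef_).ravel().copy()
        folds.append(
            FoldRecord(
                subject_id=table.subjects[i],
                true_label=bool(labels[i]),
                predicted_label=pred,
                decision_score=score,
                selected_features=sel,
                linear_weights=weights,
            )
        )

    if n_clipped:
        logger.warning(
            "k=%d exceeded the surviving feature count in %d of %d folds; clipped",
            fs.k, n_clipped, len(folds),
        )
    pred = np.array([f.predicted_label for f in folds])
    true = np.array([f.true_label for f in folds])
    scores = np.array([f.decision_score for f in folds])
    counts = confusion_counts(pred, true)
    m = metrics(counts)
    roc_points, auc_val = roc_auc(scores, true)
    return CVResult(
        folds=folds,
        feature_names=list(table.feature_names),
        counts=counts,
        accuracy=m.accuracy,
        recall=m.recall,
        specificity=m.specificity,
        f1=m.f1,
        auc=auc_val,
        roc_points=roc_points,
    )


def permutation_test(
    table: FeatureTable,
    spec: ClassifierSpec,
    fs: SelectionConfig,
    m: int = 10_000,
    seed: int | None = None,
) -> PermutationResult:
    """Label-permutation null for the LOOCV accuracy.

    Each of the m replicates permutes the labels across the whole cohort and
    re-runs screening, ranking, top-k selection and LOOCV from scratch; the
    retained-feature count k is held fixed at its configured value.
    """
    if m < 1:
        raise ConfigurationError("need at least one permutation")
    observed = loocv_classify(table, spec, fs).accuracy
    rng = np.random.default_rng(seed)
    null_acc = []
    for _ in range(m):
        perm = rng.permutation(table.n_subjects)
        shuffled = table.with_labels(table.labels[perm])
        null_acc.append(loocv_classify(shuffled, spec, fs).accuracy)
    exceed = int(np.sum(np.asarray(null_acc) > observed))
    return PermutationResult(
        m_permutations=m,
        observed_accuracy=observed,
        null_accuracies=null_acc,
        p_value=(exceed + 1) / (m + 1),
    )
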