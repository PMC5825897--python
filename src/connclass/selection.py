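"""Two-stage univariate feature reduction for two-group connectome tables.

Stage one screens each feature with a one-sample t-test against zero and
drops features whose population value is indistinguishable from zero
(connections that carry no signal in either group).  Stage two ranks the
survivors by a pair-concordance weight: over all m*n patient-control pairs,
count pairs whose value ordering agrees with the group labels (concordant,
``n_c``) and pairs whose ordering disagrees (discordant, ``n_d``), and weight
feature i by

    w_i = |n_c - n_d| / (m * n)

with m patients and n controls.  Tied pairs count as neither, the standard
Kendall convention.  Absent ties this is the absolute rank-biserial
correlation, i.e. ``|2U/(mn) - 1|`` for the Mann-Whitney statistic U, so the
weight is invariant under any strictly increasing transform of a feature.

The top-k cut and the coarse-to-fine search for k live here as well; the
cross-validated evaluation they need is injected as a callable so this module
stays independent of any particular classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, IntegrityError, ShapeError

__all__ = [
    "FeatureTable",
    "FeatureWeightRanking",
    "KSearchResult",
    "SelectionConfig",
    "screen_one_sample",
    "pair_concordance_weight",
    "rank_features",
    "select_top_k",
    "search_k",
]


@dataclass
class FeatureTable:
    """Subjects x named-features matrix with binary class labels.

    ``labels`` is boolean with ``True`` marking the positive class
    (patients).  ``label_names`` maps (negative, positive) to the text tags
    used on disk.
    """

    subjects: list[str]
    labels: np.ndarray
    values: np.ndarray
    feature_names: list[str]
    label_names: tuple[str, str] = ("HC", "MDD")

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=bool)
        self.values = np.asarray(self.values, dtype=float)
        n, f = self.values.shape
        if len(self.subjects) != n:
            raise ShapeError(f"{len(self.subjects)} subject ids for {n} rows")
        if self.labels.shape != (n,):
            raise ShapeError("labels length does not match subject count")
        if len(self.feature_names) != f:
            raise ShapeError(f"{len(self.feature_names)} names for {f} features")
        if len(set(self.subjects)) != n:
            raise IntegrityError("duplicate subject ids")
        if len(set(self.feature_names)) != f:
            raise IntegrityError("duplicate feature names")
        if not (self.labels.any() and (~self.labels).any()):
            raise IntegrityError("both classes must be present")
        if np.isnan(self.values).any():
            raise IntegrityError("feature table contains missing values")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def patients(self) -> np.ndarray:
        return self.values[self.labels]

    def controls(self) -> np.ndarray:
        return self.values[~self.labels]

    def subset(self, row_mask: np.ndarray) -> "FeatureTable":
        """Row subset (e.g. a training fold); feature axis untouched."""
        idx = np.flatnonzero(row_mask) if row_mask.dtype == bool else row_mask
        return FeatureTable(
            subjects=[self.subjects[i] for i in idx],
            labels=self.labels[idx],
            values=self.values[idx],
            feature_names=list(self.feature_names),
            label_names=self.label_names,
        )

    def with_labels(self, labels: np.ndarray) -> "FeatureTable":
        return replace(self, labels=np.asarray(labels, dtype=bool))

    def to_frame(self) -> pd.DataFrame:
        neg, pos = self.label_names
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "label", np.where(self.labels, pos, neg))
        df.insert(0, "subject_id", self.subjects)
        return df


@dataclass
class FeatureWeightRanking:
    """Pair-concordance weights plus the descending order of survivors.

    ``weights`` has one entry per original feature (NaN where screened out);
    ``order`` is a permutation of the surviving feature indices, descending
    in weight with ties broken by ascending index.
    """

    weights: np.ndarray
    order: np.ndarray
    screen_mask: np.ndarray


@dataclass
class KSearchResult:
    k_grid: list[int]
    accuracy_curve: list[float]
    best_k: int
    coarse_step: int
    fine_step: int


@dataclass
class SelectionConfig:
    """Feature-selection settings carried through cross-validation.

    ``unwrapped_screen`` reproduces the screen-on-everyone variant (leaks the
    held-out subject into the screen); the default keeps every selection step
    inside the training fold.
    """

    k: int
    alpha: float = 0.05
    unwrapped_screen: bool = False


def screen_one_sample(table: FeatureTable, alpha: float = 0.05) -> np.ndarray:
    """Boolean mask of features whose mean differs from zero at level alpha.

    Two-sided one-sample t-test per feature.  Degenerate conventions:
    a feature constant at a nonzero value is retained (the test statistic
    diverges), a feature constant at zero is removed.
    """
    if table.n_subjects < 2:
        raise InsufficientDataError("screening needs at least 2 subjects")
    x = table.values
    sd = x.std(axis=0, ddof=1)
    degenerate = sd == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_1samp(x, 0.0, axis=0)
    mask = np.asarray(p) <= alpha
    mask[degenerate] = x[0, degenerate] != 0.0
    return mask


def pair_concordance_weight(
    x_patients: Sequence[float], x_controls: Sequence[float]
) -> float:
    """Kendall-pair weight ``|n_c - n_d| / (m*n)`` for one feature.

    Every patient value is compared with every control value; ties count as
    neither concordant nor discordant, shrinking the weight toward zero.
    Returns a value in [0, 1]; 1 iff the groups are perfectly separated.
    """
    xp = np.asarray(x_patients, dtype=float)
    xc = np.asarray(x_controls, dtype=float)
    if xp.size == 0 or xc.size == 0:
        raise InsufficientDataError("both groups need at least one value")
    # n_c - n_d is (up to sign) the sum of sign(x_patient - x_control) over
    # all cross-group pairs; the absolute value makes the label orientation
    # immaterial.
    s = np.sign(xp[:, None] - xc[None, :]).sum()
    return float(abs(s)) / (xp.size * xc.size)


def _pair_weights_bulk(
    x_patients: np.ndarray, x_controls: np.ndarray, block: int = 2048
) -> np.ndarray:
    """Vectorized pair-concordance weights, one per feature column."""
    m, f = x_patients.shape
    n = x_controls.shape[0]
    out = np.empty(f)
    for lo in range(0, f, block):
        hi = min(lo + block, f)
        diff = x_patients[:, None, lo:hi] - x_controls[None, :, lo:hi]
        out[lo:hi] = np.abs(np.sign(diff).sum(axis=(0, 1))) / (m * n)
    return out


def rank_features(table: FeatureTable, screen: np.ndarray) -> FeatureWeightRanking:
    """Weight every surviving feature and sort descending (ties: low index)."""
    screen = np.asarray(screen, dtype=bool)
    if screen.shape != (table.n_features,):
        raise ShapeError("screen mask length must equal feature count")
    xp, xc = table.patients(), table.controls()
    if xp.shape[0] == 0 or xc.shape[0] == 0:
        raise InsufficientDataError("both groups need at least one subject")
    weights = np.full(table.n_features, np.nan)
    surv = np.flatnonzero(screen)
    if surv.size:
        weights[surv] = _pair_weights_bulk(xp[:, surv], xc[:, surv])
        order = surv[np.lexsort((surv, -weights[surv]))]
    else:
        order = surv
    return FeatureWeightRanking(weights=weights, order=order, screen_mask=screen)


def select_top_k(ranking: FeatureWeightRanking, k: int) -> np.ndarray:
    """First k entries of the ranking; clipped (with a warning) if k exceeds it."""
    if k < 1:
        raise ValueError("k must be at least 1")
    n_surv = ranking.order.size
    if k > n_surv:
        warnings.warn(
            f"requested k={k} exceeds {n_surv} surviving features; clipping",
            stacklevel=2,
        )
        k = n_surv
    return ranking.order[:k].copy()


def search_k(
    table: FeatureTable,
    classifier_spec,
    coarse_step: int,
    fine_step: int,
    evaluate: Callable[[FeatureTable, object, int], float] | None = None,
    alpha: float = 0.05,
) -> KSearchResult:
    """Coarse-to-fine search for the retained-feature count k.

    A coarse grid over ``[fine_step, n_surviving]`` with step ``coarse_step``
    locates the best interval; a fine grid with step ``fine_step`` inside
    ``[best - coarse_step, best + coarse_step]`` (clipped) refines it.  Ties
    resolve to the smallest k.  ``evaluate(table, spec, k)`` must return the
    cross-validated accuracy; the default runs the wrapped leave-one-out
    pipeline from :mod:`connclass.classify`.
    """
    if not (coarse_step >= fine_step >= 1):
        raise ValueError("require coarse_step >= fine_step >= 1")
    if evaluate is None:
        from .classify import loocv_classify

        def evaluate(tab, spec, k):  # noqa: ANN001 - injected contract
            cfg = SelectionConfig(k=k, alpha=alpha)
            return loocv_classify(tab, spec, cfg).accuracy

    n_surv = int(screen_one_sample(table, alpha).sum())
    if n_surv < 1:
        raise InsufficientDataError("no features survive the screen")

    scores: dict[int, float] = {}

    def _eval(k: int) -> float:
        if k not in scores:
            scores[k] = float(evaluate(table, classifier_spec, k))
        return scores[k]

    coarse = list(range(fine_step, n_surv + 1, coarse_step)) or [n_surv]
    for k in coarse:
        _eval(k)
    best_coarse = min(coarse, key=lambda k: (-scores[k], k))
    lo = max(1, best_coarse - coarse_step)
    hi = min(n_surv, best_coarse + coarse_step)
    for k in range(lo, hi + 1, fine_step):
        _eval(k)

    k_grid = sorted(scores)
    best_k = min(k_grid, key=lambda k: (-scores[k], k))
    return KSearchResult(
        k_grid=k_grid,
        accuracy_curve=[scores[k] for k in k_grid],
        best_k=best_k,
        coarse_step=coarse_step,
        fine_step=fine_step,
    )
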