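"""Post-hoc interpretation of a cross-validated classification run.

Consensus features are the features selected in *every* cross-validation
fold; for a linear max-margin classifier their importance is the mean
absolute primal coefficient over the folds that selected them.  Region
weights attribute half of each connection's weight to each endpoint region
(a self-connection contributes its full weight to its single region), so
total region weight always equals total connection weight.  A per-edge
Welch two-sample t-test compares directed coupling strengths between
groups, exposing sign flips and significant group differences edge by edge.
"""

from __future__ import annotations

import re
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import CVResult
from .connectivity import DirectedCouplingSet, vectorize_coupling
from .errors import ConfigurationError, InsufficientDataError, IntegrityError

__all__ = [
    "consensus_features",
    "aggregate_linear_weights",
    "parse_feature_endpoints",
    "region_weights",
    "edge_group_test",
]

_DIRECTED = re.compile(r"^(?:(?P<net>[^:]+):)?(?P<src>.+?)->(?P<dst>.+)$")
_UNDIRECTED = re.compile(r"^(?P<a>.+?)--(?P<b>.+)$")


def consensus_features(cv: CVResult) -> list[str]:
    """Features selected in every fold, ordered by mean within-fold rank."""
    if len(cv.folds) < 2:
        raise IntegrityError("consensus needs at least 2 folds")
    if any(f.selected_features is None or len(f.selected_features) == 0 for f in cv.folds):
        raise IntegrityError("a fold has no recorded feature selection")
    common = set(cv.folds[0].selected_features.tolist())
    for f in cv.folds[1:]:
        common &= set(f.selected_features.tolist())
    if not common:
        return []
    mean_rank = {
        idx: float(
            np.mean(
                [np.flatnonzero(f.selected_features == idx)[0] for f in cv.folds]
            )
        )
        for idx in common
    }
    ordered = sorted(common, key=lambda idx: (mean_rank[idx], idx))
    return [cv.feature_names[i] for i in ordered]


def aggregate_linear_weights(
    cv: CVResult, features: Sequence[str] | None = None
) -> pd.Series:
    """Mean |primal coefficient| per consensus feature, descending.

    Only defined for the linear max-margin classifier, whose per-fold weight
    vectors align with that fold's selected features.
    """
    if any(f.linear_weights is None for f in cv.folds):
        raise ConfigurationError(
            "linear weights unavailable: classifier family was not linear_svm"
        )
    if features is None:
        features = consensus_features(cv)
    name_to_idx = {n: i for i, n in enumerate(cv.feature_names)}
    agg = {}
    for name in features:
        idx = name_to_idx[name]
        vals = []
        for f in cv.folds:
            pos = np.flatnonzero(f.selected_features == idx)
            if pos.size:
                vals.append(abs(f.linear_weights[pos[0]]))
        if vals:
            agg[name] = float(np.mean(vals))
    s = pd.Series(agg, dtype=float)
    return s.sort_values(ascending=False)


def parse_feature_endpoints(name: str) -> tuple[str, str]:
    """Endpoints of a canonical edge name ("A--B" or "net:src->dst")."""
    m = _DIRECTED.match(name)
    if m:
        return m.group("src"), m.group("dst")
    m = _UNDIRECTED.match(name)
    if m:
        return m.group("a"), m.group("b")
    raise ConfigurationError(f"cannot parse endpoints from feature name {name!r}")


def region_weights(
    feature_weights: Mapping[str, float],
    edge_map: Mapping[str, tuple[str, str]] | None = None,
) -> pd.Series:
    """Half of each connection's weight to each endpoint region.

    A self-connection contributes its full weight to its single region
    (half + half).  The total over regions equals the total over
    connections exactly.
    """
    out: dict[str, float] = {}
    for name, w in feature_weights.items():
        if edge_map is not None:
            if name not in edge_map:
                raise ConfigurationError(f"feature {name!r} missing from edge map")
            a, b = edge_map[name]
        else:
            a, b = parse_feature_endpoints(name)
        out[a] = out.get(a, 0.0) + w / 2.0
        out[b] = out.get(b, 0.0) + w / 2.0
    return pd.Series(out, dtype=float).sort_values(ascending=False)


def edge_group_test(
    patients: Sequence[DirectedCouplingSet],
    controls: Sequence[DirectedCouplingSet],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Welch two-sample t-test per directed edge.

    Returns one row per edge with group means (so sign flips between groups
    are visible), the t statistic, two-sided p, and a significance flag at
    ``alpha``.  Edges degenerate in both groups get NaN statistics and an
    unset flag.
    """
    if len(patients) < 2 or len(controls) < 2:
        raise InsufficientDataError("need at least 2 subjects per group")
    vec_p = [vectorize_coupling(s) for s in patients]
    vec_c = [vectorize_coupling(s) for s in controls]
    names = vec_p[0].feature_names
    if any(v.feature_names != names for v in vec_p + vec_c):
        raise IntegrityError("subjects have inconsistent coupling layouts")
    xp = np.vstack([v.values for v in vec_p])
    xc = np.vstack([v.values for v in vec_c])
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(xp, xc, axis=0, equal_var=False)
    p = np.asarray(p, dtype=float)
    degenerate = (xp.std(axis=0) == 0) & (xc.std(axis=0) == 0)
    t = np.where(degenerate, np.nan, t)
    p = np.where(degenerate, np.nan, p)
    return pd.DataFrame(
        {
            "edge": names,
            "mean_patients": xp.mean(axis=0),
            "mean_controls": xc.mean(axis=0),
            "t": t,
            "p": p,
            "significant": np.where(np.isnan(p), False, p <= alpha),
        }
    )
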