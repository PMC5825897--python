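"""Two-group synthetic cohorts with known planted structure.

Every generator emulates the study conditions of a balanced clinical
resting-state cohort — 24 patients and 24 controls by default, 235 retained
volumes at TR = 2 s — and plants a configurable group difference whose
ground truth is returned alongside the data, so every downstream stage
(screening, ranking, cross-validated classification, consensus reporting)
has a known recovery target.

Randomness fans out from one global seed through ``numpy.random.SeedSequence``
substreams: child 0 drives population-level draws shared by everyone (feature
means, correlation templates), child 1+i drives subject i (patients first,
then controls).  Subject data therefore never depend on how many other
subjects exist after them, and equal seeds give bit-identical output.

Models, deliberately minimal:

* feature tables — per-feature population mean ``mu_i ~ N(0, 1)`` shared by
  both groups (so a realistic fraction of features carries a nonzero typical
  value, as Fisher-z connectivity does), subject noise ``N(0, noise_sd)``;
  planted features shift the patient mean by ``direction * d * noise_sd``;
* region time series — i.i.d. multivariate-normal rows from a group
  correlation template (no temporal autocorrelation; hemodynamics are out of
  scope), planted pairs differing between group templates by ``delta_r``
  split symmetrically, templates repaired to the nearest valid correlation
  matrix (repair may shrink the planted difference; the realized template
  differences are reported in the returned ground truth);
* directed coupling sets — per-edge population mean ``N(0, noise_sd)``,
  self-connections ``N(self_connection_mean, noise_sd)`` truncated negative
  (DCM stability convention), planted directed edges shifted additively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as _stats
from statsmodels.stats import correlation_tools

from .connectivity import (
    DirectedCouplingSet,
    Network,
    ROITimeSeriesSet,
    coupling_feature_names,
    fc_feature_names,
)
from .errors import ConfigurationError, ShapeError
from .selection import FeatureTable

__all__ = [
    "SyntheticCohortConfig",
    "PlantedEffect",
    "SyntheticTimeSeriesConfig",
    "SyntheticCouplingConfig",
    "DEFAULT_NETWORK_LAYOUT",
    "generate_feature_dataset",
    "generate_group_timeseries",
    "generate_coupling_dataset",
    "nearest_valid_correlation",
]

# Node names for the default 4+4+4+3 resting-state-network layout: default
# mode, dorsal attention, fronto-parietal, salience.
DEFAULT_NETWORK_LAYOUT: list[tuple[str, list[str]]] = [
    ("DMN", ["MPFC", "PCC", "LP_L", "LP_R"]),
    ("DAN", ["FEF_L", "FEF_R", "IPS_L", "IPS_R"]),
    ("FPN", ["LPFC_L", "LPFC_R", "PPC_L", "PPC_R"]),
    ("SN", ["ACC", "RPFC_L", "RPFC_R"]),
]


@dataclass
class SyntheticCohortConfig:
    """Balanced two-group cohort; patients are the positive class."""

    n_patients: int = 24
    n_controls: int = 24
    seed: int = 0
    label_positive: str = "MDD"
    label_negative: str = "HC"

    def __post_init__(self) -> None:
        if self.n_patients < 2 or self.n_controls < 2:
            raise ConfigurationError("each group needs at least 2 subjects")

    @property
    def n_subjects(self) -> int:
        return self.n_patients + self.n_controls

    def subject_ids(self) -> list[str]:
        return [f"sub-P{i + 1:03d}" for i in range(self.n_patients)] + [
            f"sub-C{i + 1:03d}" for i in range(self.n_controls)
        ]

    def labels(self) -> np.ndarray:
        return np.array([True] * self.n_patients + [False] * self.n_controls)


@dataclass
class PlantedEffect:
    """Ground truth for a planted group difference.

    ``effect_size`` is a standardized mean difference (Cohen's d units) for
    feature/coupling generators and the template correlation difference
    delta-r for the time-series generator.  ``direction`` gives the sign per
    feature (+1: patients higher), defaulting to +1.  ``measured`` is filled
    by generators whose realized effect can differ from the request (template
    repair) and maps feature name -> realized difference.
    """

    feature_ids: list = field(default_factory=list)
    effect_size: float = 0.0
    direction: list[int] | None = None
    measured: dict | None = None

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be non-negative")
        if self.direction is not None and len(self.direction) != len(self.feature_ids):
            raise ConfigurationError("direction must match feature_ids in length")

    def signs(self) -> np.ndarray:
        if self.direction is None:
            return np.ones(len(self.feature_ids))
        return np.asarray(self.direction, dtype=float)


@dataclass
class SyntheticTimeSeriesConfig:
    n_regions: int = 15
    n_timepoints: int = 235  # 240 acquired volumes minus 5 discarded
    tr_seconds: float = 2.0
    base_correlation: float = 0.1
    planted: PlantedEffect = field(default_factory=PlantedEffect)
    noise_sd: float = 1.0
    region_names: list[str] | None = None

    def names(self) -> list[str]:
        if self.region_names is not None:
            if len(self.region_names) != self.n_regions:
                raise ConfigurationError("region_names length must equal n_regions")
            return list(self.region_names)
        return [f"R{i + 1:03d}" for i in range(self.n_regions)]


@dataclass
class SyntheticCouplingConfig:
    network_sizes: list[int] = field(default_factory=lambda: [4, 4, 4, 3])
    self_connection_mean: float = -0.5
    planted: PlantedEffect = field(default_factory=PlantedEffect)
    noise_sd: float = 0.2

    def __post_init__(self) -> None:
        if not self.network_sizes:
            raise ConfigurationError("network_sizes must be non-empty")
        if any(s < 1 for s in self.network_sizes):
            raise ConfigurationError("all network sizes must be >= 1")

    def layout(self) -> list[tuple[str, list[str]]]:
        default_sizes = [len(nodes) for _, nodes in DEFAULT_NETWORK_LAYOUT]
        if self.network_sizes == default_sizes:
            return [(name, list(nodes)) for name, nodes in DEFAULT_NETWORK_LAYOUT]
        return [
            (f"NET{i + 1}", [f"NET{i + 1}_n{j + 1}" for j in range(s)])
            for i, s in enumerate(self.network_sizes)
        ]


def _streams(seed: int, n_subjects: int):
    """Population rng + one rng per subject, from one SeedSequence fan-out."""
    children = np.random.SeedSequence(seed).spawn(n_subjects + 1)
    return (
        np.random.default_rng(children[0]),
        [np.random.default_rng(c) for c in children[1:]],
    )


def _resolve_ids(feature_ids: Sequence, names: list[str]) -> np.ndarray:
    """Planted features may be given as indices or canonical names."""
    idx = []
    lookup = {n: i for i, n in enumerate(names)}
    for fid in feature_ids:
        if isinstance(fid, (int, np.integer)):
            if not 0 <= fid < len(names):
                raise ConfigurationError(f"planted feature index {fid} out of range")
            idx.append(int(fid))
        else:
            if fid not in lookup:
                raise ConfigurationError(f"planted feature {fid!r} not in feature space")
            idx.append(lookup[fid])
    return np.asarray(idx, dtype=int)


def generate_feature_dataset(
    cohort: SyntheticCohortConfig,
    n_features: int,
    planted: PlantedEffect | None = None,
    noise_sd: float = 1.0,
) -> tuple[FeatureTable, PlantedEffect]:
    """Generic two-group feature table with planted mean shifts.

    Non-planted features are exchangeable between groups; planted features
    differ in group mean by ``effect_size * noise_sd`` in the stated
    direction (applied to the patient group).
    """
    planted = planted or PlantedEffect()
    if noise_sd <= 0:
        raise ConfigurationError("noise_sd must be positive")
    names = [f"f{i + 1:04d}" for i in range(n_features)]
    idx = _resolve_ids(planted.feature_ids, names)
    pop_rng, subj_rngs = _streams(cohort.seed, cohort.n_subjects)
    mu = pop_rng.normal(0.0, 1.0, size=n_features)
    shift = np.zeros(n_features)
    shift[idx] = planted.signs() * planted.effect_size * noise_sd
    labels = cohort.labels()
    rows = [
        mu + (shift if is_patient else 0.0) + rng.normal(0.0, noise_sd, size=n_features)
        for is_patient, rng in zip(labels, subj_rngs)
    ]
    table = FeatureTable(
        subjects=cohort.subject_ids(),
        labels=labels,
        values=np.vstack(rows),
        feature_names=names,
        label_names=(cohort.label_negative, cohort.label_positive),
    )
    truth = PlantedEffect(
        feature_ids=[names[i] for i in idx],
        effect_size=planted.effect_size,
        direction=[int(v) for v in planted.signs()] if len(idx) else None,
    )
    return table, truth


def nearest_valid_correlation(
    candidate: np.ndarray, tolerance: float = 1e-8
) -> np.ndarray:
    """Project a symmetric matrix onto the valid correlation matrices.

    Returns the input (diagonal snapped to 1) when it is already valid;
    otherwise a Higham-style nearest-correlation projection (via
    statsmodels) whose smallest eigenvalue is >= -tolerance.
    """
    c = np.asarray(candidate, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ShapeError("candidate must be square")
    if not np.allclose(c, c.T, atol=1e-10):
        raise ShapeError("candidate must be symmetric")
    c = (c + c.T) / 2.0
    np.fill_diagonal(c, 1.0)
    eig = np.linalg.eigvalsh(c)
    if eig[0] >= -tolerance and np.abs(c).max() <= 1.0 + 1e-12:
        return c
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # projection may hit its iteration cap
        out = correlation_tools.corr_nearest(c, threshold=max(tolerance, 1e-15), n_fact=200)
    out = np.asarray((out + out.T) / 2.0)
    np.fill_diagonal(out, 1.0)
    if np.linalg.eigvalsh(out)[0] < -tolerance:
        out = np.asarray(correlation_tools.corr_clipped(c, threshold=max(tolerance, 1e-15)))
        out = (out + out.T) / 2.0
        np.fill_diagonal(out, 1.0)
    return out


def _group_templates(cfg: SyntheticTimeSeriesConfig):
    names = cfg.names()
    pair_names = fc_feature_names(names)
    base = np.full((cfg.n_regions, cfg.n_regions), cfg.base_correlation)
    np.fill_diagonal(base, 1.0)
    tpl_hc, tpl_pat = base.copy(), base.copy()
    idx = _resolve_ids(cfg.planted.feature_ids, pair_names)
    signs = cfg.planted.signs()
    pos = {name: k for k, name in enumerate(pair_names)}
    iu = np.triu_indices(cfg.n_regions, k=1)
    for j, fid in enumerate(idx):
        i, k = iu[0][fid], iu[1][fid]
        delta = signs[j] * cfg.planted.effect_size
        hi = np.clip(cfg.base_correlation + delta / 2.0, -0.99, 0.99)
        lo = np.clip(cfg.base_correlation - delta / 2.0, -0.99, 0.99)
        tpl_pat[i, k] = tpl_pat[k, i] = hi
        tpl_hc[i, k] = tpl_hc[k, i] = lo
    tpl_hc = nearest_valid_correlation(tpl_hc)
    tpl_pat = nearest_valid_correlation(tpl_pat)
    measured = {
        pair_names[fid]: float(tpl_pat[iu[0][fid], iu[1][fid]] - tpl_hc[iu[0][fid], iu[1][fid]])
        for fid in idx
    }
    return names, pair_names, tpl_hc, tpl_pat, idx, measured


def generate_group_timeseries(
    cohort: SyntheticCohortConfig, ts_config: SyntheticTimeSeriesConfig
) -> tuple[list[ROITimeSeriesSet], PlantedEffect]:
    """Per-subject region time series from group correlation templates."""
    names, pair_names, tpl_hc, tpl_pat, idx, measured = _group_templates(ts_config)
    chol = {}
    for key, tpl in (("HC", tpl_hc), ("PAT", tpl_pat)):
        jitter = 1e-10 * np.eye(ts_config.n_regions)
        chol[key] = np.linalg.cholesky(tpl + jitter)
    _, subj_rngs = _streams(cohort.seed, cohort.n_subjects)
    labels = cohort.labels()
    out = []
    for sid, is_patient, rng in zip(cohort.subject_ids(), labels, subj_rngs):
        z = rng.standard_normal((ts_config.n_timepoints, ts_config.n_regions))
        series = ts_config.noise_sd * (z @ chol["PAT" if is_patient else "HC"].T)
        out.append(
            ROITimeSeriesSet(
                subject_id=sid,
                group=cohort.label_positive if is_patient else cohort.label_negative,
                series=series,
                region_names=names,
                tr_seconds=ts_config.tr_seconds,
            )
        )
    truth = PlantedEffect(
        feature_ids=[pair_names[i] for i in idx],
        effect_size=ts_config.planted.effect_size,
        direction=[int(v) for v in ts_config.planted.signs()] if len(idx) else None,
        measured=measured,
    )
    return out, truth


def generate_coupling_dataset(
    cohort: SyntheticCohortConfig, cfg: SyntheticCouplingConfig
) -> tuple[list[DirectedCouplingSet], PlantedEffect]:
    """Per-subject directed coupling matrices with planted edge shifts."""
    layout = cfg.layout()
    template_nets = [Network(name, nodes, np.zeros((len(nodes), len(nodes)))) for name, nodes in layout]
    names = coupling_feature_names(template_nets)
    idx = _resolve_ids(cfg.planted.feature_ids, names)
    pop_rng, subj_rngs = _streams(cohort.seed, cohort.n_subjects)
    n_feat = len(names)
    sizes = [len(nodes) for _, nodes in layout]
    # flat indices of self-connections in the vectorized layout
    self_idx, off = [], 0
    for s in sizes:
        self_idx.extend(off + j * s + j for j in range(s))
        off += s * s
    self_mask = np.zeros(n_feat, dtype=bool)
    self_mask[self_idx] = True

    mu = pop_rng.normal(0.0, cfg.noise_sd, size=n_feat)
    mu[self_mask] = cfg.self_connection_mean
    shift = np.zeros(n_feat)
    shift[idx] = cfg.planted.signs() * cfg.planted.effect_size * cfg.noise_sd

    # standard-normal truncation bound so self-connections stay negative
    labels = cohort.labels()
    subjects = []
    for sid, is_patient, rng in zip(cohort.subject_ids(), labels, subj_rngs):
        mean = mu + (shift if is_patient else 0.0)
        vec = mean + rng.normal(0.0, cfg.noise_sd, size=n_feat)
        b = (0.0 - mean[self_mask]) / cfg.noise_sd
        vec[self_mask] = _stats.truncnorm.ppf(
            rng.uniform(size=self_mask.sum()), a=-np.inf, b=b,
            loc=mean[self_mask], scale=cfg.noise_sd,
        )
        nets, off = [], 0
        for name, nodes in layout:
            s = len(nodes)
            nets.append(Network(name, list(nodes), vec[off : off + s * s].reshape(s, s)))
            off += s * s
        subjects.append(DirectedCouplingSet(subject_id=sid, networks=nets))
    truth = PlantedEffect(
        feature_ids=[names[i] for i in idx],
        effect_size=cfg.planted.effect_size,
        direction=[int(v) for v in cfg.planted.signs()] if len(idx) else None,
    )
    return subjects, truth
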