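"""End-to-end pipelines tying simulation, featurization, selection,
classification, permutation testing and reporting together.

Three named pipelines mirror the study designs:

* ``fc_atlas`` — whole-brain functional connectivity from an atlas of
  ``n_regions`` regions (R(R-1)/2 undirected features);
* ``rsn_fc`` — the same machinery on a small resting-state-network ROI set
  (15 regions -> 105 features);
* ``coupling`` — directed-coupling features from per-network matrices
  (4+4+4+3 layout -> 57 features).

``run_pipeline`` either consumes a pre-computed feature table or simulates
one, then optionally searches the retained-feature count k, runs wrapped
leave-one-out classification, a label-permutation test, and consensus /
region-weight reporting, and returns one JSON-serializable summary that
echoes the effective configuration.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .classify import ClassifierSpec, loocv_classify, permutation_test
from .connectivity import (
    correlation_matrix,
    fisher_z,
    normalize_subject_vector,
    preprocess_timeseries,
    vectorize_coupling,
    vectorize_fc,
)
from .errors import ConfigurationError
from .io import cv_result_record, read_feature_table, write_run_summary
from .reporting import aggregate_linear_weights, consensus_features, region_weights
from .selection import FeatureTable, SelectionConfig, search_k
from .synthetic import (
    PlantedEffect,
    SyntheticCohortConfig,
    SyntheticCouplingConfig,
    SyntheticTimeSeriesConfig,
    generate_coupling_dataset,
    generate_feature_dataset,
    generate_group_timeseries,
)

__all__ = ["PipelineConfig", "run_pipeline", "featurize_timeseries", "featurize_coupling"]

logger = logging.getLogger("connclass")

_PIPELINES = ("fc_atlas", "rsn_fc", "coupling")


@dataclass
class PipelineConfig:
    pipeline: str = "coupling"
    # cohort / simulation
    n_patients: int = 24
    n_controls: int = 24
    seed: int = 0
    n_regions: int = 116          # fc_atlas; rsn_fc uses 15
    network_sizes: list[int] = field(default_factory=lambda: [4, 4, 4, 3])
    planted: PlantedEffect = field(default_factory=PlantedEffect)
    noise_sd: float = 1.0
    # preprocessing band (Hz)
    low_hz: float = 0.01
    high_hz: float = 0.08
    # selection
    alpha: float = 0.05
    k: int | None = None          # fixed k; None searches coarse-to-fine
    coarse_step: int = 200
    fine_step: int = 10
    unwrapped_screen: bool = False
    # classification
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    permutations: int = 0         # 0 skips the permutation test
    # input (overrides simulation when set)
    feature_table_path: str | None = None

    def __post_init__(self) -> None:
        if self.pipeline not in _PIPELINES:
            raise ConfigurationError(
                f"unknown pipeline {self.pipeline!r}; choose from {_PIPELINES}"
            )


def featurize_timeseries(subjects, low_hz=0.01, high_hz=0.08, positive_label="MDD") -> FeatureTable:
    """Preprocess, correlate, Fisher-z, vectorize and standardize each subject."""
    rows, ids, labels = [], [], []
    names = None
    for ts in subjects:
        clean = preprocess_timeseries(ts, low_hz=low_hz, high_hz=high_hz)
        vec = normalize_subject_vector(vectorize_fc(fisher_z(correlation_matrix(clean))))
        names = vec.feature_names
        rows.append(vec.values)
        ids.append(ts.subject_id)
        labels.append(ts.group == positive_label)
    negative = next((ts.group for ts in subjects if ts.group != positive_label), "HC")
    return FeatureTable(
        subjects=ids,
        labels=np.array(labels),
        values=np.vstack(rows),
        feature_names=names,
        label_names=(negative, positive_label),
    )


def featurize_coupling(subjects, groups: dict[str, str], positive_label="MDD") -> FeatureTable:
    """Vectorize each subject's coupling set into one table (no rescaling:
    coupling parameters are already on a common 1/s scale)."""
    rows, ids, labels = [], [], []
    names = None
    for d in subjects:
        vec = vectorize_coupling(d)
        names = vec.feature_names
        rows.append(vec.values)
        ids.append(d.subject_id)
        labels.append(groups[d.subject_id] == positive_label)
    negative = next((g for g in groups.values() if g != positive_label), "HC")
    return FeatureTable(
        subjects=ids,
        labels=np.array(labels),
        values=np.vstack(rows),
        feature_names=names,
        label_names=(negative, positive_label),
    )


def _simulate_table(config: PipelineConfig) -> tuple[FeatureTable, PlantedEffect]:
    cohort = SyntheticCohortConfig(
        n_patients=config.n_patients, n_controls=config.n_controls, seed=config.seed
    )
    if config.pipeline == "coupling":
        cfg = SyntheticCouplingConfig(
            network_sizes=list(config.network_sizes),
            planted=config.planted,
            noise_sd=config.noise_sd if config.noise_sd != 1.0 else 0.2,
        )
        subjects, truth = generate_coupling_dataset(cohort, cfg)
        groups = {
            s.subject_id: (cohort.label_positive if lab else cohort.label_negative)
            for s, lab in zip(subjects, cohort.labels())
        }
        return featurize_coupling(subjects, groups, cohort.label_positive), truth
    n_regions = 15 if config.pipeline == "rsn_fc" else config.n_regions
    ts_cfg = SyntheticTimeSeriesConfig(
        n_regions=n_regions, planted=config.planted, noise_sd=config.noise_sd
    )
    subjects, truth = generate_group_timeseries(cohort, ts_cfg)
    return featurize_timeseries(subjects, config.low_hz, config.high_hz, cohort.label_positive), truth


def run_pipeline(config: PipelineConfig, out_path: str | Path | None = None) -> dict:
    """Execute one full pipeline and return (optionally write) its summary."""
    logger.info("pipeline=%s seed=%d", config.pipeline, config.seed)
    truth = None
    if config.feature_table_path:
        table = read_feature_table(config.feature_table_path)
    else:
        table, truth = _simulate_table(config)
    logger.info("feature table: %d subjects x %d features", table.n_subjects, table.n_features)

    if config.k is None:
        ks = search_k(
            table, config.classifier, config.coarse_step, config.fine_step,
            alpha=config.alpha,
        )
        k = ks.best_k
        k_search = dataclasses.asdict(ks)
        logger.info("k search: best_k=%d", k)
    else:
        k, k_search = config.k, None

    fs = SelectionConfig(k=k, alpha=config.alpha, unwrapped_screen=config.unwrapped_screen)
    cv = loocv_classify(table, config.classifier, fs)
    logger.info("LOOCV accuracy=%.4f auc=%.4f", cv.accuracy, cv.auc)

    summary: dict = {
        "config": {
            **{
                f.name: getattr(config, f.name)
                for f in dataclasses.fields(config)
                if f.name not in ("classifier", "planted")
            },
            "classifier": dataclasses.asdict(config.classifier),
            "planted": dataclasses.asdict(config.planted),
            "effective_k": k,
        },
        "version": __version__,
        "n_features": table.n_features,
        "k_search": k_search,
        "cv": cv_result_record(cv),
        "ground_truth": dataclasses.asdict(truth) if truth is not None else None,
    }

    consensus = consensus_features(cv)
    summary["consensus_features"] = consensus
    if config.classifier.family == "linear_svm" and consensus:
        weights = aggregate_linear_weights(cv, consensus)
        summary["consensus_weights"] = weights.to_dict()
        summary["region_weights"] = region_weights(weights.to_dict()).to_dict()

    if config.permutations > 0:
        perm = permutation_test(
            table, config.classifier, fs, m=config.permutations, seed=config.seed
        )
        logger.info("permutation p=%.5f (m=%d)", perm.p_value, perm.m_permutations)
        summary["permutation"] = {
            "m": perm.m_permutations,
            "observed_accuracy": perm.observed_accuracy,
            "p_value": perm.p_value,
        }

    if out_path is not None:
        write_run_summary(summary, out_path)
    return summary
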