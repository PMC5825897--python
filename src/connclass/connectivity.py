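"""Connectivity feature construction.

Functional connectivity: region-averaged time series are detrended,
confound-regressed and band-pass filtered (resting-state band 0.01-0.08 Hz
by default), correlated pairwise (Pearson), Fisher r-to-z transformed, and
the strict upper triangle is vectorized into a named feature vector; the
subject's vector is standardized to zero mean / unit variance.  For R
regions this yields R(R-1)/2 features: 6,670 for a 116-region atlas, 36,856
for a 272-region atlas, 105 for a 15-region network set.

Effective connectivity: per-network directed coupling matrices (DCM
A-matrix convention, units 1/s, self-connections on the diagonal) are
vectorized row-major including the diagonal, giving sum(n_k^2) features —
57 for the 4+4+4+3 resting-state-network layout.  Coupling estimation
itself is upstream; matrices arrive as data.

Feature naming is canonical and index-free: undirected edges are
``"A--B"`` with A before B in region order, directed edges are
``"network:src->dst"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

from .errors import (
    ConfigurationError,
    DegenerateInputError,
    IntegrityError,
    ShapeError,
)

__all__ = [
    "ROITimeSeriesSet",
    "ConnectivityMatrix",
    "Network",
    "DirectedCouplingSet",
    "FeatureVector",
    "preprocess_timeseries",
    "correlation_matrix",
    "fisher_z",
    "vectorize_fc",
    "unvectorize_fc",
    "normalize_subject_vector",
    "vectorize_coupling",
    "model_space_size",
    "fc_feature_names",
    "coupling_feature_names",
]


@dataclass
class ROITimeSeriesSet:
    """One subject's regional time series (time x region) with metadata."""

    subject_id: str
    group: str
    series: np.ndarray
    region_names: list[str]
    tr_seconds: float

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if self.series.ndim != 2:
            raise ShapeError("series must be a time x region matrix")
        t, r = self.series.shape
        if len(self.region_names) != r:
            raise ShapeError(f"{len(self.region_names)} names for {r} regions")
        if len(set(self.region_names)) != r:
            raise IntegrityError("region names must be unique")
        if t < 8:
            raise ShapeError("need at least 8 time points")
        if np.isnan(self.series).any():
            raise IntegrityError("time series contain missing values")
        if self.tr_seconds <= 0:
            raise ConfigurationError("tr_seconds must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.series.shape[0]

    @property
    def n_regions(self) -> int:
        return self.series.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric region x region association matrix.

    ``scale`` is ``"pearson_r"`` (entries in [-1, 1], unit diagonal) or
    ``"fisher_z"`` (atanh scale, diagonal stored as 0 by convention).
    """

    values: np.ndarray
    scale: str
    region_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        r = len(self.region_names)
        if self.values.shape != (r, r):
            raise ShapeError("matrix shape must match region count")
        if self.scale not in ("pearson_r", "fisher_z"):
            raise ConfigurationError(f"unknown scale {self.scale!r}")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise IntegrityError("connectivity matrix must be symmetric")


@dataclass
class Network:
    name: str
    node_names: list[str]
    coupling: np.ndarray

    def __post_init__(self) -> None:
        self.coupling = np.asarray(self.coupling, dtype=float)
        n = len(self.node_names)
        if self.coupling.shape != (n, n):
            raise ShapeError(f"network {self.name}: coupling must be {n}x{n}")
        if len(set(self.node_names)) != n:
            raise IntegrityError(f"network {self.name}: duplicate node names")


@dataclass
class DirectedCouplingSet:
    """Per-network directed coupling matrices (1/s) for one subject."""

    subject_id: str
    networks: list[Network]

    @property
    def n_features(self) -> int:
        return sum(len(net.node_names) ** 2 for net in self.networks)


@dataclass
class FeatureVector:
    values: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size != len(self.feature_names):
            raise ShapeError("values and feature_names lengths must match")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise IntegrityError("feature names must be unique")


def preprocess_timeseries(
    ts: ROITimeSeriesSet,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    confounds: np.ndarray | None = None,
) -> ROITimeSeriesSet:
    """Detrend, regress confounds, band-pass filter each region's series.

    Order of operations: linear detrend, then least-squares confound
    regression (residuals, intercept included), then a zero-phase
    second-order Butterworth band-pass.  Confounds are regressed unfiltered.
    """
    nyquist = 0.5 / ts.tr_seconds
    if not (0 <= low_hz < high_hz < nyquist):
        raise ConfigurationError(
            f"band [{low_hz}, {high_hz}] Hz must sit inside (0, {nyquist}) Hz"
        )
    x = signal.detrend(ts.series, axis=0, type="linear")
    if confounds is not None and np.size(confounds):
        c = np.asarray(confounds, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        if c.shape[0] != ts.n_timepoints:
            raise ShapeError(
                f"confounds have {c.shape[0]} rows for {ts.n_timepoints} time points"
            )
        design = np.column_stack([np.ones(c.shape[0]), c])
        beta, *_ = np.linalg.lstsq(design, x, rcond=None)
        x = x - design @ beta
    sos = signal.butter(
        2, [low_hz, high_hz], btype="bandpass", fs=1.0 / ts.tr_seconds, output="sos"
    )
    x = signal.sosfiltfilt(sos, x, axis=0)
    return ROITimeSeriesSet(
        subject_id=ts.subject_id,
        group=ts.group,
        series=x,
        region_names=list(ts.region_names),
        tr_seconds=ts.tr_seconds,
    )


def correlation_matrix(ts: ROITimeSeriesSet) -> ConnectivityMatrix:
    """Pearson correlation between every region pair."""
    sd = ts.series.std(axis=0)
    dead = [name for name, s in zip(ts.region_names, sd) if s == 0.0]
    if dead:
        raise DegenerateInputError(f"zero-variance regions: {', '.join(dead)}")
    r = np.corrcoef(ts.series, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(values=r, scale="pearson_r", region_names=list(ts.region_names))


def fisher_z(c: ConnectivityMatrix, clamp_epsilon: float = 1e-7) -> ConnectivityMatrix:
    """Fisher r-to-z transform; |r| clamped to 1 - clamp_epsilon, diagonal 0."""
    if c.scale != "pearson_r":
        raise ConfigurationError("fisher_z expects a pearson_r matrix")
    r = np.clip(c.values, -1.0 + clamp_epsilon, 1.0 - clamp_epsilon)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(values=z, scale="fisher_z", region_names=list(c.region_names))


def fc_feature_names(region_names: Sequence[str]) -> list[str]:
    """Canonical undirected edge names, strict upper triangle row-major."""
    return [
        f"{a}--{b}"
        for i, a in enumerate(region_names)
        for b in list(region_names)[i + 1 :]
    ]


def vectorize_fc(c: ConnectivityMatrix, atol: float = 1e-8) -> FeatureVector:
    """Strict upper triangle, row-major: R(R-1)/2 named features."""
    v = c.values
    if not np.allclose(v, v.T, atol=atol):
        raise IntegrityError("matrix asymmetric beyond tolerance")
    iu = np.triu_indices(v.shape[0], k=1)
    return FeatureVector(values=v[iu].copy(), feature_names=fc_feature_names(c.region_names))


def unvectorize_fc(
    vec: FeatureVector, region_names: Sequence[str], scale: str = "fisher_z"
) -> ConnectivityMatrix:
    """Inverse of :func:`vectorize_fc`; diagonal 0 (fisher_z) or 1 (pearson_r)."""
    r = len(region_names)
    if vec.values.size != r * (r - 1) // 2:
        raise ShapeError("vector length does not match region count")
    m = np.zeros((r, r))
    iu = np.triu_indices(r, k=1)
    m[iu] = vec.values
    m = m + m.T
    np.fill_diagonal(m, 1.0 if scale == "pearson_r" else 0.0)
    return ConnectivityMatrix(values=m, scale=scale, region_names=list(region_names))


def normalize_subject_vector(v: FeatureVector) -> FeatureVector:
    """Standardize one subject's vector to mean 0, variance 1 (population sd).

    Applied per subject, so no information crosses subjects and the step is
    leakage-free by construction.
    """
    if v.values.size < 2:
        raise ShapeError("normalization needs at least 2 features")
    sd = v.values.std()
    if sd == 0.0:
        raise DegenerateInputError("constant feature vector cannot be normalized")
    return FeatureVector(
        values=(v.values - v.values.mean()) / sd,
        feature_names=list(v.feature_names),
    )


def coupling_feature_names(networks: Sequence[Network]) -> list[str]:
    """Canonical directed edge names: network:src->dst, row-major per network."""
    return [
        f"{net.name}:{src}->{dst}"
        for net in networks
        for src in net.node_names
        for dst in net.node_names
    ]


def vectorize_coupling(d: DirectedCouplingSet) -> FeatureVector:
    """Concatenate each network's full coupling matrix row-major.

    Self-connections are included, so the length is sum of squared network
    sizes (57 for the 4+4+4+3 layout).
    """
    values = np.concatenate([net.coupling.ravel(order="C") for net in d.networks])
    return FeatureVector(values=values, feature_names=coupling_feature_names(d.networks))


def model_space_size(n_free_parameters: int, search_cap: int = 8) -> int:
    """Number of reduced models enumerated by the post-hoc search.

    All on/off combinations of the free coupling parameters are scored
    unless there are 16 or more, in which case a greedy pass restricts the
    enumeration to ``search_cap`` parameters: 2^8 = 256 models for a fully
    connected 4-node network, 2^9 = 512 for a 3-node network.
    """
    if n_free_parameters < 1:
        raise ConfigurationError("need at least one free parameter")
    if n_free_parameters >= 16:
        return 2**search_cap
    return 2**n_free_parameters
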