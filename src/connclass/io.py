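"""Tab-separated / JSON readers and writers for every pipeline artifact.

All on-disk formats are plain text and name-addressed (region and feature
names, never indices): subject manifests, region time series, square
matrices, feature tables, coupling sets (one TSV per network plus an index),
and the JSON run summary.  Readers validate headers and labels and raise
:class:`~connclass.errors.ParseError` with file context on malformed input.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import CVResult
from .connectivity import DirectedCouplingSet, Network, ROITimeSeriesSet
from .errors import ParseError
from .selection import FeatureTable

__all__ = [
    "write_manifest",
    "read_manifest",
    "write_timeseries",
    "read_timeseries",
    "write_matrix",
    "read_matrix",
    "write_feature_table",
    "read_feature_table",
    "write_coupling_set",
    "read_coupling_set",
    "cv_result_record",
    "write_run_summary",
    "read_run_summary",
]


def write_manifest(rows: Sequence[tuple[str, str, str]], path: str | Path) -> None:
    """Rows of (subject_id, group, file path) as TSV with header."""
    df = pd.DataFrame(rows, columns=["subject_id", "group", "path"])
    df.to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path, require_files: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    expect = ["subject_id", "group", "path"]
    if list(df.columns) != expect:
        raise ParseError(f"{path}: manifest header must be {expect}, got {list(df.columns)}")
    if df["subject_id"].duplicated().any():
        dup = df["subject_id"][df["subject_id"].duplicated()].iloc[0]
        raise ParseError(f"{path}: duplicate subject id {dup!r}")
    groups = sorted(df["group"].unique())
    if len(groups) != 2:
        raise ParseError(f"{path}: expected exactly 2 groups, found {groups}")
    if require_files:
        base = Path(path).parent
        for i, p in enumerate(df["path"]):
            target = Path(p) if Path(p).is_absolute() else base / p
            if not target.exists():
                raise ParseError(
                    f"{path} line {i + 2}: missing file for subject "
                    f"{df['subject_id'][i]!r}: {target}"
                )
    return df


def write_timeseries(ts: ROITimeSeriesSet, path: str | Path) -> None:
    pd.DataFrame(ts.series, columns=ts.region_names).to_csv(path, sep="\t", index=False)


def read_timeseries(
    path: str | Path, subject_id: str, group: str, tr_seconds: float
) -> ROITimeSeriesSet:
    df = pd.read_csv(path, sep="\t")
    if df.isna().any().any():
        raise ParseError(f"{path}: ragged or missing values in time series")
    return ROITimeSeriesSet(
        subject_id=subject_id,
        group=group,
        series=df.to_numpy(dtype=float),
        region_names=list(df.columns),
        tr_seconds=tr_seconds,
    )


def write_matrix(values: np.ndarray, names: Sequence[str], path: str | Path) -> None:
    pd.DataFrame(values, index=list(names), columns=list(names)).to_csv(path, sep="\t")


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ParseError(f"{path}: row and column names disagree")
    return df.to_numpy(dtype=float), list(df.columns)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_feature_table(
    path: str | Path, positive_label: str | None = None
) -> FeatureTable:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["subject_id", "label"]:
        raise ParseError(f"{path}: first columns must be subject_id, label")
    labels_txt = df["label"].astype(str)
    observed = sorted(labels_txt.unique())
    if len(observed) != 2:
        raise ParseError(f"{path}: label column must hold exactly 2 values, found {observed}")
    if positive_label is None:
        positive_label = "MDD" if "MDD" in observed else observed[1]
    if positive_label not in observed:
        raise ParseError(f"{path}: positive label {positive_label!r} not in {observed}")
    negative_label = next(v for v in observed if v != positive_label)
    values = df.iloc[:, 2:]
    if values.isna().any().any():
        raise ParseError(f"{path}: missing values in feature columns")
    return FeatureTable(
        subjects=df["subject_id"].astype(str).tolist(),
        labels=(labels_txt == positive_label).to_numpy(),
        values=values.to_numpy(dtype=float),
        feature_names=list(values.columns),
        label_names=(negative_label, positive_label),
    )


def write_coupling_set(d: DirectedCouplingSet, out_dir: str | Path) -> Path:
    """One TSV per network plus an index file; returns the index path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    index = []
    for net in d.networks:
        fname = f"{d.subject_id}_{net.name}.tsv"
        write_matrix(net.coupling, net.node_names, out / fname)
        index.append({"network": net.name, "file": fname})
    index_path = out / f"{d.subject_id}_index.json"
    index_path.write_text(json.dumps({"subject_id": d.subject_id, "networks": index}, indent=1))
    return index_path


def read_coupling_set(index_path: str | Path) -> DirectedCouplingSet:
    index_path = Path(index_path)
    meta = json.loads(index_path.read_text())
    nets = []
    for entry in meta["networks"]:
        values, names = read_matrix(index_path.parent / entry["file"])
        nets.append(Network(entry["network"], names, values))
    return DirectedCouplingSet(subject_id=meta["subject_id"], networks=nets)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def cv_result_record(cv: CVResult) -> dict:
    """CVResult flattened into a JSON-safe dict (fold details included)."""
    return {
        "folds": [
            {
                "subject_id": f.subject_id,
                "true_label": bool(f.true_label),
                "predicted_label": bool(f.predicted_label),
                "decision_score": float(f.decision_score),
                "selected_features": [cv.feature_names[i] for i in f.selected_features],
            }
            for f in cv.folds
        ],
        "confusion": dataclasses.asdict(cv.counts),
        "accuracy": cv.accuracy,
        "recall": cv.recall,
        "specificity": cv.specificity,
        "f1": cv.f1,
        "auc": cv.auc,
        "roc_points": cv.roc_points.tolist(),
    }


def write_run_summary(summary: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(summary), indent=1, allow_nan=True))


def read_run_summary(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
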