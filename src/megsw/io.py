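"""Plain-text on-disk formats for signals, connectivity matrices and tables.

Signals and connectivity matrices are stored as tab-delimited numeric matrices
with a JSON sidecar of the same basename carrying metadata (sampling rate,
ROI labels, subject, condition, band, epoch counts). Tables are CSV. These
formats are deliberately text-only and diff-friendly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import BandDefinition, ConnectivityMatrix, RoiTimeSeries, ValidationError, band_by_name

__all__ = [
    "write_signal",
    "read_signal",
    "write_connectivity",
    "read_connectivity",
    "write_table",
    "read_table",
]

_FMT = "%.8g"


def _sidecar_path(base: Path) -> Path:
    return base.with_suffix(".json")


def write_signal(ts: RoiTimeSeries, base: str | Path) -> Path:
    """Write ``<base>.tsv`` (samples x ROIs) and ``<base>.json`` metadata."""
    base = Path(base)
    base.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(base.with_suffix(".tsv"), ts.data, fmt=_FMT, delimiter="\t")
    meta = {
        "fs": ts.fs,
        "labels": list(ts.labels),
        "subject": ts.subject_id,
        "condition": ts.condition,
    }
    _sidecar_path(base).write_text(json.dumps(meta, indent=1))
    return base.with_suffix(".tsv")


def _load_sidecar(base: Path, required: tuple[str, ...]) -> dict:
    sidecar = _sidecar_path(base)
    if not sidecar.exists():
        raise ValidationError(f"{sidecar}: missing JSON sidecar")
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"{sidecar}: malformed JSON sidecar ({exc})") from exc
    for key in required:
        if key not in meta:
            raise ValidationError(f"{sidecar}: sidecar missing required field {key!r}")
    return meta


def read_signal(base: str | Path) -> RoiTimeSeries:
    base = Path(base)
    if base.suffix == ".tsv":
        base = base.with_suffix("")
    meta = _load_sidecar(base, ("fs", "labels", "subject", "condition"))
    data = np.loadtxt(base.with_suffix(".tsv"), delimiter="\t", ndmin=2)
    return RoiTimeSeries(
        data=data,
        fs=float(meta["fs"]),
        labels=meta["labels"],
        subject_id=meta["subject"],
        condition=meta["condition"],
    )


def write_connectivity(cm: ConnectivityMatrix, base: str | Path) -> Path:
    base = Path(base)
    base.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(base.with_suffix(".tsv"), cm.weights, fmt=_FMT, delimiter="\t")
    meta = {
        "band": cm.band.name,
        "f_lo": cm.band.f_lo,
        "f_hi": cm.band.f_hi,
        "subject": cm.subject_id,
        "condition": cm.condition,
        "n_epochs": cm.n_epochs_averaged,
        "labels": list(cm.labels),
    }
    _sidecar_path(base).write_text(json.dumps(meta, indent=1))
    return base.with_suffix(".tsv")


def read_connectivity(base: str | Path) -> ConnectivityMatrix:
    base = Path(base)
    if base.suffix == ".tsv":
        base = base.with_suffix("")
    meta = _load_sidecar(base, ("band", "subject", "condition", "n_epochs"))
    weights = np.loadtxt(base.with_suffix(".tsv"), delimiter="\t", ndmin=2)
    if "f_lo" in meta and "f_hi" in meta:
        band = BandDefinition(meta["band"], float(meta["f_lo"]), float(meta["f_hi"]))
    else:
        band = band_by_name(meta["band"])
    return ConnectivityMatrix(
        weights=weights,
        band=band,
        subject_id=meta["subject"],
        condition=meta["condition"],
        n_epochs_averaged=int(meta["n_epochs"]),
        labels=meta.get("labels", []),
    )


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{path}: file not found")
    return pd.read_csv(path)
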