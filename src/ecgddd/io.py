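"""Text-format I/O: ECG CSV records, annotation sidecars, feature TSVs,
cohort manifests and JSON reports with seed/config provenance."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, Dataset
from .simulate import ECGRecord

__all__ = [
    "load_ecg_csv",
    "save_ecg_csv",
    "load_annotations",
    "save_annotations",
    "save_feature_table",
    "load_feature_table",
    "write_report",
    "config_hash",
]


def load_ecg_csv(path) -> ECGRecord:
    """Read a `time_s,voltage_mV` CSV; sampling rate = 1 / median time step.

    Rejects missing columns, non-monotone time, and records shorter than 5 s.
    A sidecar ``<stem>.ann`` file of beat times (one per line, seconds) is
    picked up automatically when present.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("time_s", "voltage_mV"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    t = df["time_s"].to_numpy(float)
    if len(t) < 2 or np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: time_s must be strictly increasing")
    fs = 1.0 / float(np.median(np.diff(t)))
    if t[-1] - t[0] < 5.0:
        raise ValueError(f"{path}: need at least 5 s of data")
    beats = None
    ann = path.with_suffix(".ann")
    if ann.exists():
        beats = load_annotations(ann)
    return ECGRecord(fs, df["voltage_mV"].to_numpy(float), beats)


def save_ecg_csv(record: ECGRecord, path) -> None:
    path = Path(path)
    pd.DataFrame({"time_s": record.time_s, "voltage_mV": record.voltage}).to_csv(
        path, index=False, float_format="%.12g"
    )
    if record.beat_times is not None:
        save_annotations(record.beat_times, path.with_suffix(".ann"))


def load_annotations(path) -> np.ndarray:
    return np.loadtxt(path, ndmin=1)


def save_annotations(beat_times: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(beat_times), fmt="%.9g")


def save_feature_table(ds: Dataset, path) -> None:
    ds.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")


def load_feature_table(path) -> Dataset:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in FEATURE_NAMES + ["label"] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    groups = df["group"].to_numpy() if "group" in df.columns else None
    return Dataset(df[FEATURE_NAMES].to_numpy(float), df["label"].to_numpy(int), groups)


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable config for provenance stamps."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_report(payload: dict, path, config=None, seed: int | None = None) -> None:
    out = dict(payload)
    out["_provenance"] = {"config_hash": config_hash(config) if config is not None else None, "seed": seed}
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(out, fh, indent=1, sort_keys=True, default=float)
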