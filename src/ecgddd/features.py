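"""The 10-dimensional beat-window feature vector and dataset assembly.

Features per window of W consecutive valid beats, in fixed column order:
mean and variance of the P, R and S peak amplitudes (mV, mV^2), mean and
variance of the R-R intervals (s, s^2), and the P-wave statistics Pmax (ms)
and Pd (ms).  Variances use the population convention (divisor W).  A
single heartbeat cannot carry a variance or a dispersion, so the window is
the sampling unit; one vector is emitted per window position (sliding, with
a configurable stride).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .delineate import compute_pmax_pd

__all__ = ["FEATURE_NAMES", "Dataset", "extract_window_features", "build_dataset", "balance_classes", "standardize", "true_duration_variance"]

FEATURE_NAMES = [
    "mean_P_amp",
    "var_P_amp",
    "mean_R_amp",
    "var_R_amp",
    "mean_S_amp",
    "var_S_amp",
    "mean_RR",
    "var_RR",
    "Pmax",
    "Pd",
]


@dataclass
class Dataset:
    """Feature matrix with labels, window provenance, and optional z-score stats."""

    X: np.ndarray
    y: np.ndarray
    groups: np.ndarray | None = None
    provenance: pd.DataFrame | None = None
    stats: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("rows of X must align with labels")
        if self.groups is not None:
            self.groups = np.asarray(self.groups)

    def __len__(self) -> int:
        return len(self.y)

    def subset(self, idx: np.ndarray) -> "Dataset":
        return Dataset(
            self.X[idx],
            self.y[idx],
            None if self.groups is None else self.groups[idx],
            None if self.provenance is None else self.provenance.iloc[idx].reset_index(drop=True),
            self.stats,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=FEATURE_NAMES)
        df["label"] = self.y
        return df


def _debias_durations(d: np.ndarray, noise_var: np.ndarray, s2_true: float | None = None) -> np.ndarray:
    """Shrink within-window duration deviations by the known measurement noise.

    Each delineated duration carries an uncertainty (the delineator's fit
    covariance).  Order statistics such as Pmax and Pd are inflated by that
    measurement noise; the classical disattenuation correction rescales
    deviations from the window mean by sqrt(s2_true / (s2_true + v_i)), so
    the window dispersion estimates the dispersion of the *underlying* P
    durations rather than of their noisy measurements.  The shrinkage is
    per beat because the noise is heteroscedastic and max/min statistics
    preferentially pick the noisiest beats.

    ``s2_true``, the variance of the underlying durations, is estimated
    from the window itself when not supplied; the per-record estimate
    (~100 beats, see ``true_duration_variance``) is far less noisy.
    """
    if len(d) < 2 or not np.any(np.isfinite(noise_var)):
        return d
    v = np.where(np.isfinite(noise_var), noise_var, float(np.nanmean(noise_var)))
    if s2_true is None:
        s2_true = max(float(np.var(d, ddof=1)) - float(np.mean(v)), 0.0)
    if s2_true <= 0:
        return np.full_like(d, d.mean())
    shrink = np.sqrt(s2_true / (s2_true + v))
    return d.mean() + (d - d.mean()) * shrink


def true_duration_variance(durations: np.ndarray, noise_var: np.ndarray) -> float:
    """Record-level variance of the underlying P durations.

    The per-beat duration jitter of one recording is a single population
    property, so it is best estimated from all of the record's valid beats:
    var(observed) minus the mean measurement-noise variance, floored at 0.
    """
    keep = np.isfinite(durations) & np.isfinite(noise_var)
    if keep.sum() < 3:
        return math.nan
    return max(float(np.var(durations[keep], ddof=1)) - float(np.mean(noise_var[keep])), 0.0)


def extract_window_features(beats: pd.DataFrame, s2_true: float | None = None) -> np.ndarray:
    """Feature vector of one window of >= 3 consecutive valid beats.

    ``beats`` needs columns r_time_s, P_amp, R_amp, S_amp, P_dur_ms (and
    optionally P_dur_var, the delineator's per-beat duration noise variance,
    used to debias the Pmax/Pd order statistics; ``s2_true`` supplies the
    record-level underlying-duration variance for that correction).  R-R
    intervals are the W-1 successive differences of the R times.
    """
    if len(beats) < 3:
        raise ValueError("a feature window needs at least 3 valid beats")
    p = beats["P_amp"].to_numpy(float)
    r = beats["R_amp"].to_numpy(float)
    s = beats["S_amp"].to_numpy(float)
    rr = np.diff(beats["r_time_s"].to_numpy(float))
    dur = beats["P_dur_ms"].to_numpy(float)
    if "P_dur_var" in beats.columns:
        s2 = s2_true if s2_true is not None and np.isfinite(s2_true) else None
        dur = _debias_durations(dur, beats["P_dur_var"].to_numpy(float), s2)
    pmax, pd_ = compute_pmax_pd(dur)
    return np.array(
        [
            p.mean(), p.var(),
            r.mean(), r.var(),
            s.mean(), s.var(),
            rr.mean(), rr.var(),
            pmax, pd_,
        ]
    )


def build_dataset(beat_tables: list[pd.DataFrame], labels: list[int | None], W: int = 10, stride: int = 1,
                  groups: list | None = None) -> Dataset:
    """Assemble window features from per-record beat tables.

    Windows slide over each record's *valid* beats; a record with no label
    contributes nothing (with a warning).  ``groups`` (e.g. subject ids)
    propagate to every window of the record for group-aware splitting.
    """
    if W < 3 or stride < 1:
        raise ValueError("W must be >= 3 and stride >= 1")
    rows, ys, gs, prov = [], [], [], []
    for i, (table, label) in enumerate(zip(beat_tables, labels)):
        if label is None:
            warnings.warn(f"record {i} has no class label; skipped")
            continue
        valid = table[table["core_valid"]].reset_index(drop=True)
        beat_no = valid["beat"].to_numpy() if "beat" in valid.columns else np.arange(len(valid))
        s2_rec = None
        if "P_dur_var" in valid.columns and len(valid) >= 3:
            s2_rec = true_duration_variance(
                valid["P_dur_ms"].to_numpy(float), valid["P_dur_var"].to_numpy(float)
            )
        for start in range(0, len(valid) - W + 1, stride):
            # only runs of consecutive record beats: a gap of rejected beats
            # would otherwise masquerade as a long R-R interval
            if beat_no[start + W - 1] - beat_no[start] != W - 1:
                continue
            rows.append(extract_window_features(valid.iloc[start : start + W], s2_true=s2_rec))
            ys.append(int(label))
            gs.append(groups[i] if groups is not None else i)
            prov.append({"record": i, "window_start": start})
    if not rows:
        return Dataset(np.empty((0, len(FEATURE_NAMES))), np.empty(0, dtype=int), np.empty(0), pd.DataFrame(prov))
    return Dataset(np.vstack(rows), np.array(ys), np.array(gs), pd.DataFrame(prov))


def balance_classes(ds: Dataset, seed: int = 0) -> Dataset:
    """Randomly subsample the majority class to the minority count (seeded).

    Mirrors the fairness requirement that both classes contribute equally to
    SVM training; feature values are untouched, only row membership changes.
    """
    idx0 = np.flatnonzero(ds.y == 0)
    idx1 = np.flatnonzero(ds.y == 1)
    if len(idx0) == len(idx1):
        return ds
    rng = np.random.default_rng(seed)
    if len(idx0) > len(idx1):
        idx0 = rng.choice(idx0, size=len(idx1), replace=False)
    else:
        idx1 = rng.choice(idx1, size=len(idx0), replace=False)
    keep = np.sort(np.concatenate([idx0, idx1]))
    return ds.subset(keep)


def standardize(ds: Dataset, stats: tuple[np.ndarray, np.ndarray] | None = None) -> Dataset:
    """Z-score features; fit stats on these rows unless training stats are given.

    Constant columns get unit scale (leaving them at zero) and a warning:
    they carry no class information.
    """
    if stats is None:
        mean = ds.X.mean(axis=0)
        sd = ds.X.std(axis=0)
        if np.any(sd < 1e-12):
            warnings.warn("constant feature column(s) left at zero after standardization")
        sd = np.where(sd < 1e-12, 1.0, sd)
        stats = (mean, sd)
    mean, sd = stats
    return Dataset((ds.X - mean) / sd, ds.y, ds.groups, ds.provenance, stats)
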