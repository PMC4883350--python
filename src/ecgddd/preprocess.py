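"""QRS-detection preprocessing: filtering chain, adaptive R-peak detection,
and segregation of a record into one-beat segments.

The chain is the classic Pan-Tompkins sequence: DC removal / normalization,
5-15 Hz bandpass (the band where QRS energy concentrates), five-point
derivative, squaring, and a 150 ms moving-window integration whose output
drives adaptive signal/noise thresholds with a 200 ms refractory period and
a missed-beat searchback.  Detected triggers are refined to the local
maximum of the raw (DC-removed) signal so downstream amplitude features are
read off an undistorted trace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .simulate import ECGRecord

__all__ = [
    "FilteredSignal",
    "BeatSegment",
    "remove_dc_and_normalize",
    "bandpass_filter",
    "derivative_filter",
    "square",
    "moving_window_integrate",
    "detect_r_peaks",
    "segment_beats",
    "discard_initial",
    "reject_corrupted",
    "match_beats",
]


@dataclass
class FilteredSignal:
    stage: str
    values: np.ndarray
    sampling_rate: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass(frozen=True)
class BeatSegment:
    """Half-open sample span [start, end) of one heartbeat containing its R index."""

    record_id: str
    start: int
    end: int
    r_index: int

    def __post_init__(self) -> None:
        if not (self.start <= self.r_index < self.end):
            raise ValueError("R index must lie inside [start, end)")


def remove_dc_and_normalize(x: np.ndarray, fs: float = 1.0) -> FilteredSignal:
    """Subtract the mean and scale to unit maximum absolute value.

    A constant input has no waveform content; it maps to all zeros and is
    flagged degenerate rather than raising.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("signal is empty")
    y = x - x.mean()
    m = np.max(np.abs(y))
    if m < 1e-12:
        return FilteredSignal("dc_removed", np.zeros_like(y), fs, degenerate=True)
    return FilteredSignal("dc_removed", y / m, fs)


def bandpass_filter(x: np.ndarray, fs: float, low: float = 5.0, high: float = 15.0) -> FilteredSignal:
    """Zero-phase 2nd-order Butterworth bandpass isolating QRS energy."""
    if fs <= 2.0 * high:
        raise ValueError(f"sampling rate {fs} Hz too low for a {high} Hz band edge")
    sos = sps.butter(2, [low, high], btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, np.asarray(x, dtype=float))
    return FilteredSignal("bandpassed", y, fs)


_DERIV_KERNEL = np.array([-1.0, -2.0, 0.0, 2.0, 1.0]) / 8.0  # y(n) uses x(n-2..n+2)


def derivative_filter(x: np.ndarray, fs: float) -> FilteredSignal:
    """Five-point derivative: y(n) = fs/8 * [-x(n-2) - 2x(n-1) + 2x(n+1) + x(n+2)].

    Edges use symmetric padding so the output length matches the input.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 5:
        raise ValueError("derivative filter needs at least 5 samples")
    xp = np.pad(x, 2, mode="symmetric")
    # correlate with the kernel ordered x(n-2)..x(n+2)
    y = np.convolve(xp, _DERIV_KERNEL[::-1], mode="valid") * fs
    return FilteredSignal("differentiated", y, fs)


def square(x: np.ndarray, fs: float = 1.0) -> FilteredSignal:
    return FilteredSignal("squared", np.asarray(x, dtype=float) ** 2, fs)


def moving_window_integrate(x: np.ndarray, fs: float, window_ms: float = 150.0) -> FilteredSignal:
    """Trailing mean over a window of round(window_ms * fs / 1000) samples."""
    x = np.asarray(x, dtype=float)
    w = max(1, int(round(window_ms * fs / 1000.0)))
    kernel = np.ones(w) / w
    y = np.convolve(np.concatenate([np.zeros(w - 1), x]), kernel, mode="valid")
    return FilteredSignal("integrated", y, fs)


def _integrated_signal(voltage: np.ndarray, fs: float) -> np.ndarray:
    dc = remove_dc_and_normalize(voltage, fs)
    if dc.degenerate:
        return np.zeros_like(dc.values)
    bp = bandpass_filter(dc.values, fs)
    der = derivative_filter(bp.values, fs)
    sq = square(der.values, fs)
    return moving_window_integrate(sq.values, fs).values


def detect_r_peaks(
    record: ECGRecord,
    refractory_ms: float = 200.0,
    refine_ms: float = 50.0,
    window_ms: float = 150.0,
) -> np.ndarray:
    """Adaptive R-peak detection on the integrated Pan-Tompkins signal.

    Candidate peaks of the integrated signal are classified as signal or
    noise against running estimates (threshold = noise + 0.25 * (signal -
    noise)); a searchback at half threshold recovers beats whenever the gap
    since the last detection exceeds 1.66x the running median R-R.  Each
    accepted trigger (shifted by half the integration window to undo the
    trailing-window delay) is refined to the raw-signal maximum within
    +/- ``refine_ms``.  Thresholds are ratio-based, so detection is
    invariant to overall amplitude scaling.
    """
    fs = record.sampling_rate
    if record.duration_s < 5.0:
        raise ValueError("record must be at least 5 s long for adaptive detection")
    integ = _integrated_signal(record.voltage, fs)
    if np.max(integ) <= 0:
        warnings.warn("no signal activity found; returning no peaks")
        return np.array([], dtype=int)

    refractory = int(round(refractory_ms * fs / 1000.0))
    half_w = int(round(window_ms * fs / 1000.0)) // 2
    cand, _ = sps.find_peaks(integ, distance=max(1, refractory // 2))
    if cand.size == 0:
        warnings.warn("no candidate peaks found")
        return np.array([], dtype=int)

    head = integ[: int(2 * fs)]
    spki = float(np.max(head)) if head.size else float(np.max(integ))
    npki = float(np.mean(head)) if head.size else 0.0

    accepted: list[int] = []
    pending: list[int] = []  # sub-threshold candidates since the last beat
    rr_hist: list[int] = []

    def _accept(idx: int, peak_val: float, is_searchback: bool) -> None:
        nonlocal spki, npki
        if is_searchback:
            spki = 0.25 * peak_val + 0.75 * spki
        else:
            spki = 0.125 * peak_val + 0.875 * spki
        if accepted:
            rr_hist.append(idx - accepted[-1])
            del rr_hist[:-8]
        accepted.append(idx)

    for idx in cand:
        thr = npki + 0.25 * (spki - npki)
        since_last = idx - accepted[-1] if accepted else None
        if integ[idx] > thr and (since_last is None or since_last >= refractory):
            # searchback first: was a beat missed in a long gap?
            if rr_hist and since_last is not None and since_last > 1.66 * np.median(rr_hist):
                back = [p for p in pending if integ[p] > 0.5 * thr and p - accepted[-1] >= refractory and idx - p >= refractory]
                if back:
                    _accept(max(back, key=lambda p: integ[p]), integ[max(back, key=lambda p: integ[p])], True)
            _accept(idx, integ[idx], False)
            pending = []
        else:
            npki = 0.125 * integ[idx] + 0.875 * npki
            pending.append(idx)

    # undo the trailing-window group delay, then refine on the raw trace
    raw = record.voltage - np.mean(record.voltage)
    half_refine = int(round(refine_ms * fs / 1000.0))
    refined: list[int] = []
    for idx in accepted:
        center = idx - half_w
        lo = max(0, center - half_refine)
        hi = min(len(raw), center + half_refine + 1)
        if lo >= hi:
            continue
        r = lo + int(np.argmax(raw[lo:hi]))
        if not refined or r - refined[-1] >= refractory:
            refined.append(r)
    return np.asarray(sorted(set(refined)), dtype=int)


def segment_beats(record: ECGRecord, r_indices: np.ndarray, record_id: str = "") -> list[BeatSegment]:
    """Partition the spanned region into one beat per R peak.

    Boundaries fall at midpoints between adjacent R peaks; the outer edges
    of the first and last beat extend by half the median R-R interval,
    clipped to the record.
    """
    r = np.asarray(r_indices, dtype=int)
    if r.size < 2:
        raise ValueError("need at least 2 R peaks to segment beats")
    rr_med = int(np.median(np.diff(r)))
    mids = (r[:-1] + r[1:]) // 2
    starts = np.concatenate([[max(0, r[0] - rr_med // 2)], mids])
    ends = np.concatenate([mids, [min(len(record.voltage), r[-1] + rr_med // 2)]])
    return [BeatSegment(record_id, int(s), int(e), int(ri)) for s, e, ri in zip(starts, ends, r)]


def discard_initial(record: ECGRecord, seconds: float = 30.0) -> ECGRecord:
    """Drop the settling-in head of a recording; annotations shift with it."""
    if seconds < 0:
        raise ValueError("seconds must be >= 0")
    if seconds == 0:
        return record
    fs = record.sampling_rate
    cut = int(round(seconds * fs))
    beats = None
    if record.beat_times is not None:
        beats = record.beat_times[record.beat_times >= seconds] - cut / fs
    meta = dict(record.meta)
    if record.beat_times is not None and "true_p_sigma_ms" in meta:
        keep = record.beat_times >= seconds
        meta["true_p_sigma_ms"] = np.asarray(meta["true_p_sigma_ms"])[keep]
    return ECGRecord(fs, record.voltage[cut:], beats, record.class_label, meta)


def reject_corrupted(segments: list[BeatSegment], max_rr_deviation: float = 0.40) -> list[BeatSegment]:
    """Drop beats whose R-R to either neighbor deviates >40% from the record median.

    Emulates the removal of samples corrupted by electrode movement or
    friction; on clean synthetic data nothing is removed.
    """
    if len(segments) < 3:
        return list(segments)
    r = np.array([s.r_index for s in segments], dtype=float)
    rr = np.diff(r)
    med = np.median(rr)
    keep = []
    for i, seg in enumerate(segments):
        left = rr[i - 1] if i > 0 else None
        right = rr[i] if i < len(rr) else None
        bad = any(d is not None and abs(d - med) > max_rr_deviation * med for d in (left, right))
        if not bad:
            keep.append(seg)
    return keep


def match_beats(truth_s: np.ndarray, detected_s: np.ndarray, tol_s: float = 0.05) -> tuple[int, int, int]:
    """Greedy one-to-one matching of detections to ground truth.

    Returns (matched, n_truth, n_detected); sensitivity = matched/n_truth,
    positive predictivity = matched/n_detected.
    """
    truth = np.asarray(truth_s, dtype=float)
    det = np.sort(np.asarray(detected_s, dtype=float))
    used = np.zeros(det.size, dtype=bool)
    matched = 0
    for t in truth:
        i = np.searchsorted(det, t)
        best, best_d = -1, tol_s
        for j in (i - 1, i):
            if 0 <= j < det.size and not used[j] and abs(det[j] - t) <= best_d:
                best, best_d = j, abs(det[j] - t)
        if best >= 0:
            used[best] = True
            matched += 1
    return matched, truth.size, det.size
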