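"""Synthetic single-lead ECG cohorts for the drunk-vs-normal classification task.

Real volunteer recordings of sober and intoxicated drivers are not publicly
deposited, so this module generates annotated stand-in cohorts whose two
classes differ by controlled morphological effect sizes: P-, R- and S-peak
amplitudes, mean R-R interval, maximal P-wave duration (Pmax) and P-wave
dispersion (Pd).  Each heartbeat is a sum of five Gaussian bumps (P, Q, R,
S, T), which keeps every injected quantity available in closed form for
testing.

The drunk class is derived from the normal class *per subject*: the same
subject morphology is rendered twice, once unshifted and once with the
fractional deltas applied, mirroring a paired sober/intoxicated protocol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import integrate, stats

__all__ = [
    "WaveParams",
    "BeatMorphology",
    "DrunkDeltas",
    "NoiseConfig",
    "CohortConfig",
    "ECGRecord",
    "default_morphology",
    "synthesize_beat",
    "apply_drunk_shift",
    "synthesize_record",
    "expected_cohort_size",
    "generate_cohort",
    "expected_max_gaussian",
]

WAVE_ORDER = ("P", "Q", "R", "S", "T")

#: full width of a Gaussian bump measured at 10% of its peak height,
#: in units of sigma: 2 * sqrt(2 ln 10)
GAUSSIAN_10PCT_WIDTH = 2.0 * math.sqrt(2.0 * math.log(10.0))


class MorphologyError(ValueError):
    """Raised when a beat morphology violates its physiologic constraints."""


@dataclass(frozen=True)
class WaveParams:
    """One Gaussian component of the beat template.

    amplitude_mV : signed peak value (negative for Q and S deflections)
    center_ms    : bump center relative to the R peak
    width_ms     : Gaussian sigma
    """

    amplitude_mV: float
    center_ms: float
    width_ms: float


@dataclass(frozen=True)
class BeatMorphology:
    """Five-wave beat template plus the per-beat P-width jitter spread.

    ``p_width_jitter_ms`` is the standard deviation of the per-beat random
    perturbation of the P-wave sigma; it controls P-wave dispersion (Pd)
    at the population level, since dispersion is a property of a *set* of
    beats, not of any single beat.
    """

    waves: dict[str, WaveParams]
    p_width_jitter_ms: float = 3.0

    def __post_init__(self) -> None:
        missing = [w for w in WAVE_ORDER if w not in self.waves]
        if missing:
            raise MorphologyError(f"missing wave definitions: {missing}")
        for name, wp in self.waves.items():
            if wp.width_ms <= 0:
                raise MorphologyError(f"{name} wave width must be > 0, got {wp.width_ms}")
        if self.p_width_jitter_ms < 0:
            raise MorphologyError("p_width_jitter_ms must be >= 0")
        r = self.waves["R"].amplitude_mV
        if not (r > abs(self.waves["Q"].amplitude_mV) and r > abs(self.waves["S"].amplitude_mV)):
            raise MorphologyError("R amplitude must dominate |Q| and |S|")
        centers = [self.waves[w].center_ms for w in WAVE_ORDER]
        if not (centers[0] < centers[1] < 0.0 < centers[3] < centers[4]):
            raise MorphologyError("wave centers must satisfy P < Q < R(0) < S < T")
        if self.waves["R"].center_ms != 0.0:
            raise MorphologyError("R wave is the fiducial and must sit at offset 0")


def default_morphology() -> BeatMorphology:
    """Textbook lead-II-like template (amplitudes in mV, offsets from R in ms)."""
    return BeatMorphology(
        waves={
            "P": WaveParams(0.15, -170.0, 25.0),
            "Q": WaveParams(-0.10, -40.0, 9.0),
            "R": WaveParams(1.10, 0.0, 11.0),
            "S": WaveParams(-0.22, 40.0, 9.0),
            "T": WaveParams(0.30, 280.0, 45.0),
        },
        p_width_jitter_ms=3.0,
    )


@dataclass(frozen=True)
class DrunkDeltas:
    """Fractional class-1 vs class-0 shifts of the six affected quantities.

    Defaults are the averaged sober-to-intoxicated ECG variations this
    generator is designed to emulate: the P peak falls by 11.21%, the R and
    S peaks grow by 19.54% and 8.14%, the R-R interval shortens by 8.43%
    (faster heart rate), and the population P-wave statistics Pmax and Pd
    rise by 9.07% and 23.77%.
    """

    p_amp: float = -0.1121
    r_amp: float = +0.1954
    s_amp: float = +0.0814
    rr: float = -0.0843
    pmax: float = +0.0907
    pd: float = +0.2377


@dataclass(frozen=True)
class NoiseConfig:
    """Additive measurement noise; identical for both classes by design."""

    baseline_amp_mV: float = 0.05
    baseline_freq_hz: float = 0.3
    powerline_amp_mV: float = 0.0
    powerline_freq_hz: float = 50.0
    white_sd_mV: float = 0.02


@dataclass(frozen=True)
class CohortConfig:
    """Study design of a two-class synthetic cohort.

    One normal and one drunk record are produced per subject-session, from
    the *same* subject-level morphology (a paired design).  ``dispersion_window``
    is the number of consecutive beats over which Pmax/Pd are defined when
    calibrating the injected P-width distribution.
    """

    n_subjects: int = 50
    sessions_per_subject: int = 1
    record_minutes: float = 2.0
    mean_hr_bpm: float = 71.0
    hr_sd_bpm: float = 8.0
    rr_sd_ms: float = 30.0
    subject_amp_cv: float = 0.25
    subject_pwidth_sd_ms: float = 2.5
    drunk_deltas: DrunkDeltas = field(default_factory=DrunkDeltas)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    sampling_rate: float = 360.0
    dispersion_window: int = 10
    seed: int = 0
    morphology: BeatMorphology = field(default_factory=default_morphology)

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.sessions_per_subject < 1:
            raise ValueError("subject and session counts must be >= 1")
        if self.sampling_rate < 250.0:
            raise ValueError("sampling_rate must be >= 250 Hz")
        if self.record_minutes <= 0 or self.mean_hr_bpm <= 0:
            raise ValueError("record_minutes and mean_hr_bpm must be positive")
        if self.dispersion_window < 2:
            raise ValueError("dispersion_window must be >= 2")


@dataclass
class ECGRecord:
    """A sampled voltage trace with optional ground truth.

    beat_times are the R-peak times (seconds, strictly increasing, aligned
    to the sample grid).  meta carries generator provenance (subject,
    session, per-beat true P sigmas, subject amplitude scale) used only by
    tests and reports.
    """

    sampling_rate: float
    voltage: np.ndarray
    beat_times: np.ndarray | None = None
    class_label: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def duration_s(self) -> float:
        return len(self.voltage) / self.sampling_rate

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(len(self.voltage)) / self.sampling_rate

    def __post_init__(self) -> None:
        self.voltage = np.asarray(self.voltage, dtype=float)
        if self.beat_times is not None:
            self.beat_times = np.asarray(self.beat_times, dtype=float)
            if np.any(np.diff(self.beat_times) <= 0):
                raise ValueError("beat_times must be strictly increasing")


def expected_max_gaussian(n: int) -> float:
    """E[max of n iid standard normals], by numerical quadrature.

    Used to calibrate how a shift of the per-beat P-width distribution maps
    onto the window-level order statistics Pmax and Pd.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    pdf, cdf = stats.norm.pdf, stats.norm.cdf
    val, _ = integrate.quad(lambda x: n * x * pdf(x) * cdf(x) ** (n - 1), -12, 12)
    return float(val)


def synthesize_beat(morph: BeatMorphology, fs: float, span_ms: tuple[float, float] = (-350.0, 450.0)) -> np.ndarray:
    """Evaluate the five-Gaussian beat template on the sample grid.

    Returns the waveform on ``[span_ms[0], span_ms[1])`` around the R peak.
    """
    if fs < 250:
        raise ValueError("fs must be >= 250 Hz")
    t = np.arange(round(span_ms[0] * fs / 1000.0), round(span_ms[1] * fs / 1000.0)) * (1000.0 / fs)
    return _template(morph, t)


def _template(morph: BeatMorphology, t_ms: np.ndarray, p_width_ms: float | None = None) -> np.ndarray:
    out = np.zeros_like(t_ms, dtype=float)
    for name in WAVE_ORDER:
        wp = morph.waves[name]
        width = p_width_ms if (name == "P" and p_width_ms is not None) else wp.width_ms
        out += wp.amplitude_mV * np.exp(-0.5 * ((t_ms - wp.center_ms) / width) ** 2)
    return out


def apply_drunk_shift(morph: BeatMorphology, deltas: DrunkDeltas, window_beats: int = 10) -> BeatMorphology:
    """Return the intoxicated-class morphology implied by fractional deltas.

    Amplitudes scale directly: P by (1 + dP), R by (1 + dR), S by (1 + dS).
    The P width parameters are recalibrated so that over windows of
    ``window_beats`` beats the expected Pmax and Pd shift by the requested
    fractions.  With per-beat sigma ~ N(mu, s) and a 10%-height duration
    criterion, E[Pmax] = k (mu + c_n s) and E[Pd] = 2 k c_n s where
    k = 2 sqrt(2 ln 10) and c_n = E[max of n standard normals]; both
    identities are linear in (mu, s), so the shifted pair is solved exactly.
    """
    c_n = expected_max_gaussian(window_beats)
    mu, s = morph.waves["P"].width_ms, morph.p_width_jitter_ms
    s_new = s * (1.0 + deltas.pd)
    mu_new = (1.0 + deltas.pmax) * (mu + c_n * s) - c_n * s_new
    if mu_new <= 0:
        raise MorphologyError("drunk shift would produce a non-positive P width")
    waves = dict(morph.waves)
    for name, d in (("P", deltas.p_amp), ("R", deltas.r_amp), ("S", deltas.s_amp)):
        wp = waves[name]
        waves[name] = replace(wp, amplitude_mV=wp.amplitude_mV * (1.0 + d))
    waves["P"] = replace(waves["P"], width_ms=mu_new)
    return BeatMorphology(waves=waves, p_width_jitter_ms=s_new)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Gaussian draws truncated at +/- 3 SD (keeps R-R intervals ordered)."""
    if sd == 0:
        return np.full(size, mean)
    x = rng.normal(0.0, 1.0, size)
    return mean + sd * np.clip(x, -3.0, 3.0)


def synthesize_record(
    cfg: CohortConfig,
    class_label: int,
    seed: int,
    morphology: BeatMorphology | None = None,
    mean_hr_bpm: float | None = None,
) -> ECGRecord:
    """Render one labeled record: placed beats + additive noise.

    Class 1 applies the configured drunk deltas to the (subject) morphology
    and shortens the mean R-R interval by the rr delta.  Ground-truth R
    times are snapped to the sample grid so that each annotation coincides
    with a local maximum of the noiseless signal.
    """
    if class_label not in (0, 1):
        raise ValueError("class_label must be 0 or 1")
    rng = np.random.default_rng(seed)
    morph = morphology if morphology is not None else cfg.morphology
    hr = mean_hr_bpm if mean_hr_bpm is not None else cfg.mean_hr_bpm
    rr_mean = 60.0 / hr
    if class_label == 1:
        morph = apply_drunk_shift(morph, cfg.drunk_deltas, cfg.dispersion_window)
        rr_mean *= 1.0 + cfg.drunk_deltas.rr

    fs = cfg.sampling_rate
    duration = cfg.record_minutes * 60.0
    n_samples = int(round(duration * fs))

    # beat placement: accumulate truncated-Gaussian R-R intervals
    max_beats = int(duration / rr_mean * 1.5) + 8
    rr = _truncated_normal(rng, rr_mean, cfg.rr_sd_ms / 1000.0, max_beats)
    times = 0.45 + np.cumsum(np.concatenate([[0.0], rr]))
    times = times[times < duration - 0.45]
    beat_idx = np.round(times * fs).astype(int)
    beat_times = beat_idx / fs

    sigma_p = _truncated_normal(rng, morph.waves["P"].width_ms, morph.p_width_jitter_ms, len(beat_times))
    sigma_p = np.maximum(sigma_p, 1.0)

    voltage = np.zeros(n_samples)
    t_all = np.arange(n_samples) / fs
    half_span = 0.6  # seconds rendered around each R peak
    for bt, sp in zip(beat_times, sigma_p):
        lo = max(0, int((bt - half_span) * fs))
        hi = min(n_samples, int((bt + half_span) * fs) + 1)
        voltage[lo:hi] += _template(morph, (t_all[lo:hi] - bt) * 1000.0, p_width_ms=sp)

    nz = cfg.noise
    if nz.baseline_amp_mV > 0:
        voltage += nz.baseline_amp_mV * np.sin(2 * np.pi * nz.baseline_freq_hz * t_all + rng.uniform(0, 2 * np.pi))
    if nz.powerline_amp_mV > 0:
        voltage += nz.powerline_amp_mV * np.sin(2 * np.pi * nz.powerline_freq_hz * t_all + rng.uniform(0, 2 * np.pi))
    if nz.white_sd_mV > 0:
        voltage += rng.normal(0.0, nz.white_sd_mV, n_samples)

    return ECGRecord(
        sampling_rate=fs,
        voltage=voltage,
        beat_times=beat_times,
        class_label=class_label,
        meta={"true_p_sigma_ms": sigma_p, "morphology": morph, "rr_mean_s": rr_mean},
    )


def expected_cohort_size(hr_bpm: float, n_subjects: int, n_sessions: int, retained_minutes: float) -> int:
    """Expected one-beat sample count: heart rate x subjects x sessions x minutes."""
    if min(hr_bpm, n_subjects, n_sessions, retained_minutes) <= 0:
        raise ValueError("all arguments must be positive")
    return int(round(hr_bpm * n_subjects * n_sessions * retained_minutes))


def generate_cohort(cfg: CohortConfig) -> list[ECGRecord]:
    """Generate the paired two-class cohort described by ``cfg``.

    For every subject-session a subject-level morphology (amplitude scale,
    P width, heart rate) is drawn once and rendered as both a class-0 and a
    class-1 record, so class contrasts are within-subject.  All randomness
    derives from ``cfg.seed`` via spawned seed sequences.
    """
    root = np.random.SeedSequence(cfg.seed)
    records: list[ECGRecord] = []
    for subj, subj_ss in enumerate(root.spawn(cfg.n_subjects)):
        subj_rng = np.random.default_rng(subj_ss)
        # subject draws truncated at +/- 2 SD: keeps every subject inside a
        # physiologically plausible resting range
        z = np.clip(subj_rng.normal(size=3), -2.0, 2.0)
        amp_scale = 1.0 + cfg.subject_amp_cv * z[0]
        p_width = cfg.morphology.waves["P"].width_ms + cfg.subject_pwidth_sd_ms * z[1]
        hr = cfg.mean_hr_bpm + cfg.hr_sd_bpm * z[2]
        waves = {
            name: replace(wp, amplitude_mV=wp.amplitude_mV * amp_scale)
            for name, wp in cfg.morphology.waves.items()
        }
        waves["P"] = replace(waves["P"], width_ms=p_width)
        morph = BeatMorphology(waves=waves, p_width_jitter_ms=cfg.morphology.p_width_jitter_ms)
        for session in range(cfg.sessions_per_subject):
            seeds = subj_rng.integers(0, 2**31 - 1, size=2)
            for label, s in ((0, seeds[0]), (1, seeds[1])):
                rec = synthesize_record(cfg, label, int(s), morphology=morph, mean_hr_bpm=hr)
                rec.meta.update(subject=subj, session=session)
                records.append(rec)
    return records
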