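# Methods

This note documents the models, estimators and numerical choices behind
`ecgddd`, in the order the pipeline runs them.

## Synthetic ECG cohorts

**Beat model.** A heartbeat is a sum of five Gaussian bumps, one per wave.
Defaults (amplitude mV / center ms from R / sigma ms): P 0.15 / −170 / 25,
Q −0.10 / −40 / 9, R 1.10 / 0 / 11, S −0.22 / 40 / 9, T 0.30 / +280 / 45 —
a textbook lead-II-like shape at a 71 bpm resting rate. Gaussians were
chosen because every quantity the pipeline later estimates (peak values,
10%-height widths) has a closed form, so the delineator can be tested
against exact ground truth. The sampling rate defaults to 360 Hz.

**Class contrast.** The drunk class applies fractional shifts to the same
subject's morphology: P amplitude −11.21%, R +19.54%, S +8.14%, mean R-R
−8.43%, Pmax +9.07%, Pd +23.77%. Amplitude and R-R shifts are direct
multiplications. Pmax and Pd are *population* order statistics — a single
beat has neither — so they are injected through the per-beat P-width
distribution: per beat, sigma_P ~ N(mu, s) (truncated at ±3 SD), and a
beat's 10%-height duration is k·sigma with k = 2√(2 ln 10) ≈ 4.292. Over a
window of n beats, E[Pmax] = k(mu + c_n s) and E[Pd] = 2 k c_n s, where
c_n = E[max of n standard normals] (computed by quadrature; c_10 ≈ 1.539).
Both identities are linear in (mu, s), so the drunk (mu′, s′) that shifts
E[Pmax] by +9.07% and E[Pd] by +23.77% is solved exactly
(`apply_drunk_shift`). The calibration window defaults to the feature
window, n = 10. Defaults mu = 25 ms, s = 3 ms give Pmax ≈ 127 ms and
Pd ≈ 40 ms, inside the healthy adult range.

**Population structure.** Each subject draws (truncated at ±2 SD) an
amplitude scale (CV 0.25), a P-width offset (SD 2.5 ms) and a heart rate
(SD 8 bpm) — realistic between-subject variability for resting adults, and
the reason the classification task is non-trivial: with much smaller
variability every kernel classifier saturates at 100% accuracy and the
kernel comparison is uninformative. The same subject morphology is rendered
as one normal and one drunk record per session (a paired sober/intoxicated
protocol); per-beat R-R intervals are Gaussian (SD 30 ms, truncated ±3 SD).

**Noise.** Additive and class-independent: 0.05 mV baseline wander at
0.3 Hz, white noise SD 0.02 mV, optional powerline component (off by
default). All class differences are morphological by construction.

**What the generator does not emulate.** Autonomic heart-rate variability
(R-R intervals are iid, not correlated), motion/electrode artifacts,
non-Gaussian wave shapes (notched P waves, biphasic T), ectopic beats, and
any pharmacokinetics of alcohol. Passing tests therefore demonstrate that
the pipeline recovers known morphological contrasts under stationary
additive noise — not performance on ambulatory clinical data.

## Preprocessing (QRS detection)

The classic Pan-Tompkins sequence: DC removal and max-abs normalization; a
zero-phase 2nd-order Butterworth bandpass 5–15 Hz (the QRS energy band);
the five-point derivative y(n) = fs/8 · [−x(n−2) − 2x(n−1) + 2x(n+1) +
x(n+2)]; squaring; and a 150 ms trailing moving-window mean. Candidate
peaks of the integrated signal are classified against running signal/noise
peak estimates with threshold = noise + 0.25 (signal − noise), a 200 ms
refractory period, and a searchback at half threshold when the gap since
the last beat exceeds 1.66× the running median R-R. Accepted triggers are
shifted left by half the integration window (undoing the trailing-window
delay) and refined to the raw-trace maximum within ±50 ms, so amplitude
features are read off an undistorted signal. All thresholds are
ratio-based: detection is invariant to overall amplitude scaling.

Beats are segregated at R-R midpoints; the first 30 s of each record are
discarded (measurement settling); a beat whose R-R to either neighbor
deviates more than 40% from the record median is dropped as corrupted.
Detection is scored by greedy one-to-one matching at ±50 ms (about half a
QRS duration).

## Delineation

Baseline wander is removed with a zero-phase 0.67 Hz high-pass. Peaks are
located on a copy smoothed with an 8 ms Gaussian (so white noise does not
pick the argmax) in windows anchored on R: Q = min in [R−80, R) ms, S = min
in (R, R+80] ms, P = max in [R−250, R−60] ms, T = largest-magnitude
extremum in [R+100, R+400] ms, clipped to the beat. A P argmax on the
window edge is another wave's slope and flags the beat invalid. Q/R/S
amplitudes are read as the vertex of a least-squares parabola over ±2
samples around the raw-trace extremum (exact for smooth peaks, unbiased
under noise, where the raw value at an argmax sample is max-biased), and
all amplitudes are referenced to the per-beat isoelectric level — the
physiologic definition; referencing the record mean would inject a
class-dependent offset because mean beat area over R-R differs between
classes.

**P duration.** Onset and offset are the crossings at 10% of the P peak
height above baseline. By default they are evaluated on a least-squares
Gaussian-plus-constant fit of the P region (duration k·sigma_fit with
k = 2√(2 ln 10)); the direct sample-by-sample crossing of the smoothed
trace (with sub-sample interpolation) is available as
`method="crossing"` and is the fallback when the fit fails. The fit pools
every sample of the wave and empirically reaches the Cramér–Rao bound for
the width (≈ 1.3 ms in sigma at the default SNR), roughly halving the
noise of direct thresholding. The fit window reaches 85 ms right of the
peak (further runs into the QRS) and adaptively 90–200 ms left — clear of
the preceding T wave, whose position follows from the prior R-R interval.
A fit whose RMS residual exceeds 1.5× the estimated white-noise level is
rejected (the signature of P-on-T overlap at high heart rates), flagging
the beat invalid rather than mismeasuring it. Both duration criteria are
relative to the peak and hence amplitude-scale invariant.

## Features

Per window of W = 10 consecutive valid beats (stride configurable):
mean/variance of P, R, S amplitudes (population variance, divisor W),
mean/variance of the W−1 R-R intervals, and Pmax / Pd over the window's P
durations. A single heartbeat cannot carry a variance or a dispersion, so
the window is the sampling unit. Windows never span gaps of rejected
beats — a gap would masquerade as a long R-R interval.

**Dispersion debiasing.** Each fitted duration carries a known noise
variance (from the fit covariance). Pmax and Pd are order statistics and
are inflated by measurement noise, asymmetrically when the two classes
have different SNR (the drunk P wave is 11% smaller and wider). Deviations
from the window mean are therefore shrunk per beat by
√(s²_true / (s²_true + v_i)) — the classical disattenuation correction,
applied per beat because max/min preferentially select the noisiest
measurements. Two refinements make the correction accurate. First,
s²_true (the variance of the underlying durations) is estimated once per
record from all of its valid beats, var(observed) − mean(v_i) floored at
zero: per-beat jitter is a record-level property and the ~100-beat
estimate is far less noisy than a 10-beat window one. Second, the
analytic v_i from the least-squares covariance is optimistic at low SNR
(parameter bounds and nonlinearity fatten the error tails), so each
record's v_i are rescaled by a parametric bootstrap: 200 synthetic P
windows at the record's median fitted amplitude and width plus its
measured white-noise level are refit and the empirical error variance
replaces the analytic one. With both, the window statistics estimate the
dispersion of the *underlying* durations.

**Paired window balancing.** In cohort assembly the two records of a
subject-session contribute equally many windows (the larger side is evenly
thinned). Faster drunk hearts produce more windows and marginal subjects
lose more drunk beats to validity checks; unequal counts weight subjects
differently in the two class means and bias the recovered contrasts.

Datasets are class-balanced by seeded subsampling of the majority class and
z-scored with training-fold statistics only.

## Kernels and SVM

Prime kernels operate on the full standardized vector; weighted composites
apply the same family per coordinate, K_c(x,y) = Σ_p c_p K_p(x_p, y_p),
with c_p = |r_p| / Σ|r_q| from the point-biserial correlation of feature p
with the label (constant features get zero; all-zero correlations fall
back to uniform with a warning). A conic combination of kernels is a
kernel, so every weighted Gram matrix is positive semidefinite (tested on
thousands of random matrices). The RBF kernel is exp(−γ‖x−y‖²) with
default γ = 1/(2σ²), σ = 1 on standardized features, applied to the scalar
difference in the per-feature form.

The dual is solved by SMO over a precomputed Gram matrix (mandatory — the
composite kernel is custom): maximal-violating-pair selection with a
second-order gain rule, an occasional first-order step to avoid late-phase
zigzag between near-bound multipliers, periodic exact gradient refresh,
and convergence when the violating-pair gap falls below 1e−7 (KKT
residuals in tests are required below 1e−5; the dual objective matches an
independent SLSQP quadratic-programming oracle to 1e−4 on all small
instances). The bias is the mean of b_s − Σ α_i b_i K_is over margin
vectors, else the feasibility-interval midpoint. Ties f(x) = 0 classify as
normal — deterministic and conservative for an alerting system.

**Box bound C.** The source formulation is hard-margin; overlapping real
windows need a soft margin. The default is C = 10 for all eight
classifiers: prime Gram entries scale with the feature count (~10 on
standardized data) while the weight-normalized composite's entries are of
order 1, so C = 1 under-fits the composite and the weighted-vs-prime
comparison would measure regularization mismatch rather than the
weighting. C = ∞ recovers the hard-margin problem exactly.

## Evaluation

10-fold cross-validation. Folds are class-stratified; when subject groups
are available, whole subjects are assigned to folds (largest-first greedy
balancing after a seeded shuffle) so overlapping windows of one recording
never straddle the train/validation boundary — with sliding windows,
non-grouped folds leak heavily. Balancing, standardization and correlation
weights are fit on training rows only, per fold. Acc, Se, Sp are averaged
unweighted over folds (sizes differ by at most one group). The comparison
table evaluates all 4 families × {prime, weighted} under identical folds.

The default benchmark for the weighting comparison is 12 subjects/class,
1-minute records, stride 5, seeds 1–5 — small enough to run in about a
minute while keeping ≥ 12 groups for 10 folds.

## Degenerate inputs and numerical conventions

Constant signals: flagged degenerate (normalization), zero weight
(correlation), unit scale (standardization). Empty duration lists raise.
Undefined metrics (empty denominator) are NaN and named in the report.
Records shorter than 5 s are rejected for adaptive detection. All
randomness flows from explicit integer seeds (numpy Generator /
SeedSequence spawning per subject); identical configuration reproduces
bit-identical records, datasets and reports.

## Known limitations

- The delineator's Gaussian P model matches the generator's wave shape; on
  real ECG the fit residual check will reject atypical (e.g. bifid) P
  waves rather than measure them, and the crossing method should be used
  for sensitivity analyses.
- P-on-T merging at heart rates above ~95 bpm invalidates beats by design;
  cohorts with tachycardic subjects lose coverage.
- Correlation weighting captures only marginal linear association;
  jointly-informative but marginally-uncorrelated features are
  down-weighted.
- The kernel weights are fixed from correlations, not optimized jointly
  with the dual variables.
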