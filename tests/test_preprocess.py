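"""Pan-Tompkins chain: filters, adaptive R detection, beat segregation."""

import numpy as np
import pytest

from ecgddd.preprocess import (
    bandpass_filter,
    derivative_filter,
    detect_r_peaks,
    discard_initial,
    match_beats,
    moving_window_integrate,
    remove_dc_and_normalize,
    segment_beats,
    square,
)
from ecgddd.simulate import ECGRecord


class TestStages:
    def test_dc_removal_examples(self):
        out = remove_dc_and_normalize(np.array([0.0, 2.0, 4.0]))
        assert np.allclose(out.values, [-1, 0, 1])
        out2 = remove_dc_and_normalize(np.array([-1.0, 0.0, 1.0]))
        assert np.allclose(out2.values, [-1, 0, 1])

    def test_constant_input_flagged_degenerate(self):
        out = remove_dc_and_normalize(np.full(10, 5.0))
        assert out.degenerate and np.allclose(out.values, 0.0)

    def test_normalized_output_contract(self, noisy_record):
        out = remove_dc_and_normalize(noisy_record.voltage)
        assert abs(out.values.mean()) < 1e-9
        assert np.max(np.abs(out.values)) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "freq,low,high", [(10.0, 0.9, 1.0), (0.0, 0.0, 1e-3), (50.0, 0.0, 0.1), (1.0, 0.0, 0.1), (40.0, 0.0, 0.15)]
    )
    def test_bandpass_probe_tones(self, freq, low, high):
        fs = 360.0
        t = np.arange(int(20 * fs)) / fs
        x = np.ones_like(t) if freq == 0 else np.sin(2 * np.pi * freq * t)
        y = bandpass_filter(x, fs).values
        mid = slice(int(5 * fs), int(15 * fs))
        ratio = np.max(np.abs(y[mid]))
        assert low <= ratio <= high + 1e-9

    def test_bandpass_rejects_low_sampling_rate(self):
        with pytest.raises(ValueError):
            bandpass_filter(np.zeros(100), fs=25.0)

    def test_derivative_of_constant_is_zero(self):
        out = derivative_filter(np.full(20, 3.0), fs=1.0)
        assert np.allclose(out.values, 0.0)

    def test_derivative_of_unit_ramp(self):
        out = derivative_filter(np.arange(20.0), fs=1.0)
        assert np.allclose(out.values[2:-2], 1.0)

    def test_derivative_linearity_and_length_check(self):
        x = np.sin(np.linspace(0, 5, 50))
        assert np.allclose(derivative_filter(-x, 10.0).values, -derivative_filter(x, 10.0).values)
        with pytest.raises(ValueError):
            derivative_filter(np.zeros(4), 1.0)

    def test_square_examples(self):
        assert np.allclose(square(np.array([-2.0, 3.0])).values, [4, 9])
        x = np.random.default_rng(0).normal(size=100)
        assert np.all(square(x).values >= 0)
        assert np.allclose(square(-x).values, square(x).values)

    def test_moving_window_trailing_means(self):
        fs = 1000.0  # W = round(2ms * 1000/1000) = 2
        out = moving_window_integrate(np.array([0.0, 1.0, 2.0, 3.0]), fs, window_ms=2.0)
        assert np.allclose(out.values, [0.0, 0.5, 1.5, 2.5])

    def test_moving_window_impulse_and_constant(self):
        fs = 360.0
        w = round(150 * fs / 1000)
        imp = np.zeros(200)
        imp[50] = 1.0
        out = moving_window_integrate(imp, fs).values
        assert np.allclose(out[50 : 50 + w], 1.0 / w)
        assert np.allclose(out[50 + w :], 0.0)
        const = moving_window_integrate(np.full(100, 2.5), fs).values
        assert const[-1] == pytest.approx(2.5)


class TestDetection:
    def test_flat_record_yields_no_peaks(self):
        rec = ECGRecord(360.0, np.zeros(int(10 * 360)))
        with pytest.warns(UserWarning):
            assert detect_r_peaks(rec).size == 0

    def test_noiseless_record_perfect_detection(self, noiseless_record):
        det = detect_r_peaks(noiseless_record) / noiseless_record.sampling_rate
        m, nt, nd = match_beats(noiseless_record.beat_times, det)
        assert m == nt == nd  # 100% sensitivity and positive predictivity

    def test_noisy_record_detection_above_99pct(self, noisy_record):
        det = detect_r_peaks(noisy_record) / noisy_record.sampling_rate
        m, nt, nd = match_beats(noisy_record.beat_times, det)
        assert m / nt >= 0.99 and m / nd >= 0.99

    def test_detection_invariant_to_amplitude_scaling(self, noisy_record):
        det1 = detect_r_peaks(noisy_record)
        scaled = ECGRecord(noisy_record.sampling_rate, noisy_record.voltage * 10.0)
        det2 = detect_r_peaks(scaled)
        assert np.array_equal(det1, det2)

    def test_short_record_rejected(self):
        with pytest.raises(ValueError):
            detect_r_peaks(ECGRecord(360.0, np.zeros(360)))


class TestSegmentation:
    def test_midpoint_rule(self):
        rec = ECGRecord(360.0, np.zeros(700))
        segs = segment_beats(rec, np.array([100, 300, 500]))
        assert (segs[1].start, segs[1].end, segs[1].r_index) == (200, 400, 300)

    def test_segments_tile_without_overlap(self, noiseless_record):
        r = (noiseless_record.beat_times * noiseless_record.sampling_rate).astype(int)
        segs = segment_beats(noiseless_record, r)
        assert len(segs) == len(r)
        for a, b in zip(segs[:-1], segs[1:]):
            assert a.end == b.start

    def test_too_few_peaks_rejected(self, noiseless_record):
        with pytest.raises(ValueError):
            segment_beats(noiseless_record, np.array([100]))


class TestDiscardInitial:
    def test_trims_samples_and_shifts_annotations(self, noisy_record):
        out = discard_initial(noisy_record, 30.0)
        assert out.duration_s == pytest.approx(noisy_record.duration_s - 30.0)
        orig = noisy_record.beat_times[noisy_record.beat_times >= 30.0]
        assert np.allclose(out.beat_times, orig - 30.0, atol=1e-9)

    def test_zero_seconds_is_identity(self, noisy_record):
        assert discard_initial(noisy_record, 0.0) is noisy_record
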