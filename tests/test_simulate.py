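"""Synthetic cohort generator: beat templates, class shifts, records, cohorts."""

import numpy as np
import pytest
from dataclasses import replace

from ecgddd.simulate import (
    BeatMorphology,
    CohortConfig,
    DrunkDeltas,
    MorphologyError,
    NoiseConfig,
    WaveParams,
    apply_drunk_shift,
    default_morphology,
    expected_cohort_size,
    expected_max_gaussian,
    generate_cohort,
    synthesize_beat,
    synthesize_record,
    GAUSSIAN_10PCT_WIDTH,
)


class TestSynthesizeBeat:
    def test_zero_amplitudes_give_zero_segment(self, morphology):
        waves = {n: replace(w, amplitude_mV=0.0) for n, w in morphology.waves.items()}
        waves["R"] = replace(waves["R"], amplitude_mV=1e-12)  # keep dominance invariant
        m = BeatMorphology(waves=waves)
        seg = synthesize_beat(m, fs=360.0)
        assert np.allclose(seg, 0.0, atol=1e-11)

    @staticmethod
    def _separated():
        # bumps far apart relative to their widths: cross-talk < 1e-9 mV
        return BeatMorphology(
            waves={
                "P": WaveParams(0.15, -200.0, 8.0),
                "Q": WaveParams(-0.10, -60.0, 5.0),
                "R": WaveParams(1.10, 0.0, 6.0),
                "S": WaveParams(-0.22, 60.0, 5.0),
                "T": WaveParams(0.30, 250.0, 10.0),
            }
        )

    def test_value_at_r_center_matches_closed_form(self, morphology):
        fs = 360.0
        i_r = -round(-350.0 * fs / 1000.0)  # R at offset 0 on the span grid
        seg = synthesize_beat(morphology, fs)
        expected = sum(
            w.amplitude_mV * np.exp(-0.5 * (w.center_ms / w.width_ms) ** 2)
            for w in morphology.waves.values()
        )
        assert seg[i_r] == pytest.approx(expected, abs=1e-12)
        # with well-separated bumps the R sample carries the R amplitude alone
        sep = synthesize_beat(self._separated(), fs)
        assert sep[i_r] == pytest.approx(1.10, abs=1e-6)

    def test_template_is_linear_in_r_amplitude(self):
        base = self._separated()
        doubled = BeatMorphology(
            waves={**base.waves, "R": replace(base.waves["R"], amplitude_mV=2.2)}
        )
        assert synthesize_beat(doubled, 360.0).max() == pytest.approx(
            2 * synthesize_beat(base, 360.0).max(), rel=1e-6
        )

    def test_nonpositive_width_rejected(self, morphology):
        with pytest.raises(MorphologyError):
            BeatMorphology(waves={**morphology.waves, "P": replace(morphology.waves["P"], width_ms=0.0)})


class TestDrunkShift:
    def test_r_amplitude_scales_by_table_delta(self, morphology):
        shifted = apply_drunk_shift(morphology, DrunkDeltas())
        assert shifted.waves["R"].amplitude_mV == pytest.approx(1.10 * 1.1954, rel=1e-9)
        assert shifted.waves["P"].amplitude_mV == pytest.approx(0.15 * (1 - 0.1121), rel=1e-9)
        assert shifted.waves["S"].amplitude_mV == pytest.approx(-0.22 * 1.0814, rel=1e-9)

    def test_zero_deltas_are_identity(self, morphology):
        zero = DrunkDeltas(0, 0, 0, 0, 0, 0)
        out = apply_drunk_shift(morphology, zero)
        assert out == morphology

    def test_inverse_deltas_recover_amplitudes(self, morphology):
        d = DrunkDeltas()
        inv = DrunkDeltas(
            *[-x / (1 + x) for x in (d.p_amp, d.r_amp, d.s_amp, d.rr, d.pmax, d.pd)]
        )
        back = apply_drunk_shift(apply_drunk_shift(morphology, d), inv)
        for w in "PRS":
            assert back.waves[w].amplitude_mV == pytest.approx(morphology.waves[w].amplitude_mV, abs=1e-9)

    def test_population_pmax_pd_shift_by_design(self, morphology):
        """The P-width recalibration moves the window-level order statistics by
        exactly the requested fractions under the linear order-statistic model."""
        n = 10
        c = expected_max_gaussian(n)
        k = GAUSSIAN_10PCT_WIDTH
        d = DrunkDeltas()
        out = apply_drunk_shift(morphology, d, window_beats=n)
        mu0, s0 = morphology.waves["P"].width_ms, morphology.p_width_jitter_ms
        mu1, s1 = out.waves["P"].width_ms, out.p_width_jitter_ms
        pmax0, pmax1 = k * (mu0 + c * s0), k * (mu1 + c * s1)
        pd0, pd1 = k * 2 * c * s0, k * 2 * c * s1
        assert pmax1 / pmax0 == pytest.approx(1 + d.pmax, rel=1e-9)
        assert pd1 / pd0 == pytest.approx(1 + d.pd, rel=1e-9)


class TestSynthesizeRecord:
    def test_two_minute_record_has_expected_beat_count(self):
        cfg = CohortConfig(n_subjects=1, record_minutes=2.0, seed=0)
        rec = synthesize_record(cfg, 0, seed=99)
        assert abs(len(rec.beat_times) - 142) <= 15

    def test_noise_off_record_equals_clean_templates(self, noiseless_cfg, noiseless_record):
        # far from any beat the trace is numerically zero
        t = noiseless_record.time_s
        mask = np.all(np.abs(t[:, None] - noiseless_record.beat_times[None, :]) > 0.55, axis=1)
        assert np.allclose(noiseless_record.voltage[mask], 0.0, atol=1e-6)

    def test_same_seed_is_bit_identical(self, noiseless_cfg):
        a = synthesize_record(noiseless_cfg, 1, seed=7)
        b = synthesize_record(noiseless_cfg, 1, seed=7)
        assert np.array_equal(a.voltage, b.voltage)
        assert np.array_equal(a.beat_times, b.beat_times)

    def test_annotations_sit_on_local_maxima(self, noiseless_record):
        v = noiseless_record.voltage
        for bt in noiseless_record.beat_times:
            i = int(round(bt * noiseless_record.sampling_rate))
            lo, hi = max(0, i - 1), min(len(v), i + 2)
            assert v[i] >= np.max(v[lo:hi]) - 1e-9


class TestCohort:
    def test_sample_count_arithmetic(self):
        assert expected_cohort_size(71, 50, 3, 1.5) == 15975
        assert expected_cohort_size(60, 1, 1, 1) == 60
        assert expected_cohort_size(71, 50, 3, 2.0) == 21300

    def test_nonpositive_arguments_rejected(self):
        with pytest.raises(ValueError):
            expected_cohort_size(0, 50, 3, 1.5)

    def test_record_counts_and_labels(self):
        cfg = CohortConfig(n_subjects=2, sessions_per_subject=1, record_minutes=1.0, seed=3)
        recs = generate_cohort(cfg)
        assert len(recs) == 4
        assert sorted(r.class_label for r in recs) == [0, 0, 1, 1]
        assert all(r.class_label in (0, 1) for r in recs)

    def test_paired_r_amplitude_effect_size(self):
        """Ground-truth template R amplitudes differ by the injected delta
        across >= 50 record pairs (within-subject pairing makes it exact)."""
        cfg = CohortConfig(n_subjects=50, record_minutes=1.0, seed=21)
        recs = generate_cohort(cfg)
        r0 = np.mean([r.meta["morphology"].waves["R"].amplitude_mV for r in recs if r.class_label == 0])
        r1 = np.mean([r.meta["morphology"].waves["R"].amplitude_mV for r in recs if r.class_label == 1])
        assert 100 * (r1 - r0) / r0 == pytest.approx(19.54, abs=1.0)

    def test_cohort_determinism(self):
        cfg = CohortConfig(n_subjects=2, record_minutes=1.0, seed=8)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.voltage, rb.voltage)
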