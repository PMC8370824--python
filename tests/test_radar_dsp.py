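"""Demodulation chain: range FFT, phase, mutation repair, bands, rates."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

import vitalwave as vw
from vitalwave.radar_dsp import (
    PhaseSignal,
    detect_corrupt_frames,
    repair_profile,
)
from vitalwave.synth import RadarCube, RadarParams

FS = 20.0


def dominant_freq(x, fs):
    x = x - np.mean(x)
    spec = np.abs(np.fft.rfft(x, 16 * len(x)))
    return np.fft.rfftfreq(16 * len(x), 1 / fs)[np.argmax(spec)]


class TestRangeFftAndPhase:
    def test_zero_cube_gives_zero_profile(self):
        p = RadarParams()
        cube = RadarCube(np.zeros((p.n_fast, 10), complex), p, 0.3)
        assert np.all(vw.range_fft(cube) == 0)

    def test_empty_cube_rejected(self):
        p = RadarParams()
        cube = RadarCube(np.zeros((p.n_fast, 0), complex), p, 0.3)
        with pytest.raises(ValueError):
            vw.range_fft(cube)

    def test_static_target_constant_phase(self):
        flat = vw.DisplacementTrace(np.zeros(100), FS)
        phase = vw.extract_phase(vw.range_fft(vw.simulate_if_cube(flat, base_range_m=0.30)), FS)
        assert np.std(phase.samples) < 1e-6

    def test_auto_bin_selection_matches_target(self):
        flat = vw.DisplacementTrace(np.zeros(100), FS)
        phase = vw.extract_phase(vw.range_fft(vw.simulate_if_cube(flat, base_range_m=0.45)), FS)
        assert phase.source_range_bin == round(0.45 / 0.0375)

    def test_bin_out_of_range_rejected(self):
        flat = vw.DisplacementTrace(np.zeros(100), FS)
        profile = vw.range_fft(vw.simulate_if_cube(flat, base_range_m=0.30))
        with pytest.raises(ValueError):
            vw.extract_phase(profile, FS, range_bin=999)

    def test_first_difference_preserves_length(self):
        x = np.sin(2 * np.pi * 0.25 * np.arange(600) / FS)
        cube = vw.simulate_if_cube(vw.DisplacementTrace(x, FS), base_range_m=0.3)
        ph = vw.extract_phase(vw.range_fft(cube), FS, first_difference=True)
        assert len(ph.samples) == 600

    def test_phase_unwrapped_no_jump_exceeds_pi(self):
        trace = vw.generate_pattern(vw.PatternSpec.default("normal"))
        ph = vw.extract_phase(vw.range_fft(vw.simulate_if_cube(trace, base_range_m=0.3)), FS)
        assert np.max(np.abs(np.diff(ph.samples))) <= np.pi


class TestMutations:
    def test_clean_sinusoid_unflagged(self):
        x = np.sin(2 * np.pi * 0.25 * np.arange(1200) / FS)
        assert vw.detect_mutations(x) == []

    def test_injected_spike_found(self):
        x = np.sin(2 * np.pi * 0.25 * np.arange(100) / FS)
        x[15] += 10 * np.max(np.abs(x))
        assert vw.detect_mutations(x) == [15]

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            vw.detect_mutations([1.0, 2.0, 3.0])

    def test_count_grows_with_dropout_rate(self, periodic_spec):
        # frame loss is detected on the range bin's magnitude series
        trace = vw.generate_pattern(periodic_spec)
        totals = []
        for rate in (0.0, 0.005, 0.01):
            n = 0
            for seed in range(20):
                cube = vw.simulate_if_cube(trace, base_range_m=0.3, dropout_rate=rate, seed=seed)
                profile = vw.range_fft(cube)
                found = detect_corrupt_frames(profile, 8)
                assert found == cube.dropped_frames
                n += len(found)
            totals.append(n)
        assert totals[0] == 0 and totals[0] < totals[1] < totals[2]

    def test_repair_examples(self):
        np.testing.assert_allclose(
            vw.repair_mutations([1, 2, 50, 3, 4], [2]), [1, 2, 2.5, 3, 4]
        )
        np.testing.assert_allclose(vw.repair_mutations([50, 2, 3], [0]), [2, 2, 3])
        np.testing.assert_allclose(vw.repair_mutations([1, 2, 3], []), [1, 2, 3])

    def test_repair_all_flagged_rejected(self):
        with pytest.raises(ValueError):
            vw.repair_mutations([1, 2, 3], [0, 1, 2])

    @given(st.integers(0, 2**31 - 1))
    def test_repair_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=50)
        flags = sorted(rng.choice(50, size=5, replace=False).tolist())
        once = vw.repair_mutations(x, flags)
        twice = vw.repair_mutations(once, flags)
        np.testing.assert_allclose(once, twice)

    def test_repair_profile_restores_phase(self, periodic_spec):
        trace = vw.generate_pattern(periodic_spec)
        cube = vw.simulate_if_cube(trace, base_range_m=0.3, dropout_rate=0.01, seed=4)
        profile = vw.range_fft(cube)
        fixed = repair_profile(profile, 8, detect_corrupt_frames(profile, 8))
        phase = vw.extract_phase(fixed, FS, range_bin=8)
        clean = vw.extract_phase(
            vw.range_fft(vw.simulate_if_cube(trace, base_range_m=0.3)), FS, range_bin=8
        )
        assert np.max(np.abs(phase.samples - clean.samples)) < 0.5


class TestBandSeparation:
    def test_two_tone_separation(self):
        t = np.arange(1200) / FS
        x = np.sin(2 * np.pi * 0.25 * t) + 0.3 * np.sin(2 * np.pi * 1.2 * t)
        vs = vw.bandpass_separate(x, FS)
        assert dominant_freq(vs.respiration, FS) == pytest.approx(0.25, abs=0.02)
        assert dominant_freq(vs.heart, FS) == pytest.approx(1.2, abs=0.02)

    def test_out_of_band_tone_attenuated(self):
        t = np.arange(2400) / FS
        x = np.sin(2 * np.pi * 0.05 * t)
        vs = vw.bandpass_separate(x, FS)
        for ch in (vs.respiration, vs.heart):
            assert np.max(np.abs(ch)) < 0.1  # >= 20 dB down

    def test_zero_in_zero_out_and_length(self):
        vs = vw.bandpass_separate(np.zeros(500), FS)
        assert np.allclose(vs.respiration, 0) and np.allclose(vs.heart, 0)
        assert len(vs.respiration) == len(vs.heart) == 500

    def test_linearity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=800)
        a = vw.bandpass_separate(3.0 * x, FS)
        b = vw.bandpass_separate(x, FS)
        np.testing.assert_allclose(a.respiration, 3.0 * b.respiration, atol=1e-9)

    def test_sampling_rate_below_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            vw.bandpass_separate(np.zeros(100), 6.0)


class TestRateEstimation:
    def test_known_respiration_frequency(self):
        t = np.arange(1200) / FS
        rate, conf = vw.estimate_rate(np.sin(2 * np.pi * 0.333 * t), FS, (0.1, 0.6))
        assert rate == pytest.approx(20.0, abs=1.0)
        assert 0 < conf <= 1

    def test_known_heart_frequency(self):
        t = np.arange(1200) / FS
        rate, conf = vw.estimate_rate(np.sin(2 * np.pi * 1.15 * t), FS, (0.8, 4.0))
        assert rate == pytest.approx(69.0, abs=2.0)
        assert 0 < conf <= 1

    def test_zero_signal_zero_confidence(self):
        assert vw.estimate_rate(np.zeros(1200), FS, (0.1, 0.6)) == (0.0, 0.0)

    def test_each_method_alone_recovers_tone(self):
        t = np.arange(1200) / FS
        x = np.sin(2 * np.pi * 0.25 * t)
        for method in ("fft", "autocorrelation", "peak_interval"):
            rate, conf = vw.estimate_rate(x, FS, (0.1, 0.6), methods=(method,))
            assert rate == pytest.approx(15.0, abs=1.0), method

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            vw.estimate_rate(np.zeros(60), FS, (0.1, 0.6))


class TestErrorArithmetic:
    @pytest.mark.parametrize(
        "measured,reference,expected",
        [(19, 20, 5.00), (16, 15, 6.67), (67, 69, 2.90), (12, 12, 0.0)],
    )
    def test_percent_error(self, measured, reference, expected):
        assert vw.rate_error(measured, reference) == expected

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            vw.rate_error(10, 0)

    def test_column_mean(self):
        assert vw.column_mean([5]) == 5
        with pytest.raises(ValueError):
            vw.column_mean([])


def test_end_to_end_rate_recovery_smoke():
    """One full simulate -> demodulate -> estimate pass at known frequencies."""
    spec = vw.PatternSpec(
        pattern=vw.Pattern.NORMAL, duration_s=60.0, breath_amplitude_mm=4.0,
        cycle_period_s=4.0, phase_schedule=(("breathe", 60.0),),
    )
    trace = vw.add_noise(
        vw.add_heartbeat(vw.generate_pattern(spec), 1.2, 0.3, seed=0), 0.05, seed=1
    )
    vs, _ = vw.process_cube(vw.simulate_if_cube(trace, base_range_m=0.3))
    assert vs.resp_rate_bpm == pytest.approx(15.0, abs=1.0)
    assert vs.heart_rate_bpm == pytest.approx(72.0, abs=2.0)
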