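"""Synthetic trace and IF-cube generator behaviour."""
import numpy as np
import pytest
from scipy.signal import find_peaks

import vitalwave as vw
from vitalwave.synth import Pattern, PatternSpec

FS = 20.0


def dominant_freq(x, fs, f_floor=0.0):
    """Dominant FFT frequency; ``f_floor`` excludes record-length envelope drift."""
    x = x - np.mean(x)
    spec = np.abs(np.fft.rfft(x, 16 * len(x)))
    freqs = np.fft.rfftfreq(16 * len(x), 1 / fs)
    mask = freqs >= f_floor
    return freqs[mask][np.argmax(spec[mask])]


class TestGeneratePattern:
    def test_tachypnea_has_thirty_cycles(self, tachypnea_trace):
        # 2 s cycles over 60 s -> 30 raised-cosine crests
        assert len(tachypnea_trace.samples) == 1200
        assert len(find_peaks(tachypnea_trace.samples)[0]) == 30

    def test_apnea_protocol_truth_interval(self, apnea_protocol_trace):
        assert apnea_protocol_trace.truth_apnea_intervals == [(400, 800)]

    def test_zero_amplitude_gives_all_zero(self):
        spec = PatternSpec.default("normal", breath_amplitude_mm=0.0)
        trace = vw.generate_pattern(spec)
        assert np.all(trace.samples == 0)

    @pytest.mark.parametrize("pattern", list(vw.PATTERN_LABELS))
    def test_breathing_band_occupancy(self, pattern):
        # apnea-bearing patterns put envelope power below 0.08 Hz (the
        # record-scale on/off gating); the breathing component itself must
        # still dominate inside 0.1-0.6 Hz
        trace = vw.generate_pattern(PatternSpec.default(pattern))
        f = dominant_freq(trace.samples, FS, f_floor=0.08)
        assert 0.1 <= f <= 0.6

    @pytest.mark.parametrize("pattern", ["biot", "cheyne_stokes", "apnea_protocol"])
    def test_apnea_truth_samples_are_zero(self, pattern):
        trace = vw.generate_pattern(PatternSpec.default(pattern))
        for start, stop in trace.truth_apnea_intervals:
            assert np.all(trace.samples[start:stop] == 0)

    @pytest.mark.parametrize(
        "pattern,period,expected_cycles",
        [("tachypnea", 2.0, 30), ("bradypnea", 8.0, 7), ("normal", 3.3, 18)],
    )
    def test_complete_cycle_count_is_floor(self, pattern, period, expected_cycles):
        trace = vw.generate_pattern(PatternSpec.default(pattern))
        # a complete cycle has fallen back below half amplitude; the
        # truncated partial cycle at the record end has not
        amp = trace.samples.max()
        above = trace.samples > amp / 2
        falls = int(np.sum(above[:-1] & ~above[1:]))
        assert falls == expected_cycles == int(60.0 // period)

    def test_unknown_pattern_rejected(self):
        with pytest.raises(ValueError):
            PatternSpec.default("sighing")

    def test_duration_shorter_than_cycle_rejected(self):
        spec = PatternSpec(
            pattern=Pattern.BRADYPNEA, duration_s=5.0, cycle_period_s=8.0,
            phase_schedule=(("breathe", 5.0),),
        )
        with pytest.raises(ValueError, match="one breathing cycle"):
            vw.generate_pattern(spec)

    def test_low_sampling_rate_rejected(self, periodic_spec):
        with pytest.raises(ValueError, match="sampling_rate"):
            vw.generate_pattern(periodic_spec, sampling_rate=2.0)

    def test_deterministic(self, periodic_spec):
        a = vw.generate_pattern(periodic_spec, seed=7)
        b = vw.generate_pattern(periodic_spec, seed=7)
        np.testing.assert_array_equal(a.samples, b.samples)


class TestHeartbeatAndNoise:
    def test_zero_amplitude_heartbeat_is_identity(self, tachypnea_trace):
        out = vw.add_heartbeat(tachypnea_trace, 1.2, 0.0)
        np.testing.assert_array_equal(out.samples, tachypnea_trace.samples)

    def test_heartbeat_spectral_peak(self):
        flat = vw.DisplacementTrace(np.zeros(1200), FS)
        out = vw.add_heartbeat(flat, 1.2, 0.3)
        assert dominant_freq(out.samples, FS) == pytest.approx(1.2, abs=0.02)
        assert 0.8 <= dominant_freq(out.samples, FS) <= 4.0

    def test_heartbeat_persists_through_apnea(self, apnea_protocol_trace):
        out = vw.add_heartbeat(apnea_protocol_trace, 70 / 60, 0.3)
        seg = out.samples[400:800]
        assert np.sqrt(np.mean(seg**2)) >= 0.2 * 0.3

    def test_out_of_band_heart_rate_warns(self, tachypnea_trace):
        with pytest.warns(UserWarning):
            vw.add_heartbeat(tachypnea_trace, 5.0, 0.3)

    def test_noise_sigma_zero_identity(self, tachypnea_trace):
        out = vw.add_noise(tachypnea_trace, 0.0, seed=1)
        np.testing.assert_array_equal(out.samples, tachypnea_trace.samples)

    def test_noise_standard_deviation(self):
        flat = vw.DisplacementTrace(np.zeros(1200), FS)
        out = vw.add_noise(flat, 0.1, seed=5)
        assert np.std(out.samples) == pytest.approx(0.1, rel=0.1)

    def test_noise_deterministic_and_negative_rejected(self, tachypnea_trace):
        a = vw.add_noise(tachypnea_trace, 0.2, seed=3)
        b = vw.add_noise(tachypnea_trace, 0.2, seed=3)
        np.testing.assert_array_equal(a.samples, b.samples)
        with pytest.raises(ValueError):
            vw.add_noise(tachypnea_trace, -0.1)


class TestIfCube:
    def test_static_target_peaks_in_bin_eight(self, radar_params):
        # d_res = c/(2B) = 0.0375 m, so 0.30 m falls in bin 8
        flat = vw.DisplacementTrace(np.zeros(200), FS)
        cube = vw.simulate_if_cube(flat, radar_params, base_range_m=0.30)
        profile = vw.range_fft(cube)
        assert np.argmax(np.mean(np.abs(profile), axis=1)) == round(
            0.30 / radar_params.range_resolution
        ) == 8

    def test_phase_swing_matches_four_pi_over_lambda(self, radar_params):
        # 1 mm displacement -> 4 pi A / lambda ~ 3.23 rad
        x = 1.0 * np.sin(2 * np.pi * 0.25 * np.arange(1200) / FS)
        cube = vw.simulate_if_cube(vw.DisplacementTrace(x, FS), base_range_m=0.30)
        phase = vw.extract_phase(vw.range_fft(cube), FS)
        swing = (phase.samples.max() - phase.samples.min()) / 2
        expected = 4 * np.pi * 1e-3 / radar_params.wavelength
        assert swing == pytest.approx(expected, rel=0.05)

    def test_no_dropout_means_no_dropped_frames(self, tachypnea_trace):
        cube = vw.simulate_if_cube(tachypnea_trace, dropout_rate=0.0)
        assert cube.dropped_frames == []

    def test_out_of_range_target_rejected(self, tachypnea_trace, radar_params):
        with pytest.raises(ValueError, match="base_range_m"):
            vw.simulate_if_cube(tachypnea_trace, base_range_m=radar_params.max_range + 1)

    def test_fast_time_dimension(self, tachypnea_trace, radar_params):
        cube = vw.simulate_if_cube(tachypnea_trace)
        assert cube.data.shape == (radar_params.n_fast, len(tachypnea_trace.samples))


def test_radar_param_invariants():
    p = vw.RadarParams()
    assert p.range_resolution == pytest.approx(0.0375)
    assert p.speed_resolution == pytest.approx(2 * np.pi / 100)
    with pytest.raises(ValueError):
        vw.RadarParams(bandwidth_b=-1)


def test_random_trace_deterministic_and_annotated():
    a = vw.random_trace("cheyne_stokes", seed=9)
    b = vw.random_trace("cheyne_stokes", seed=9)
    np.testing.assert_array_equal(a.samples, b.samples)
    assert a.truth_pattern is Pattern.CHEYNE_STOKES
    assert a.truth_apnea_intervals  # bracketing apnea recorded
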