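"""Demodulation chain: range FFT, phase extraction, dropout repair, band separation, rates.

The chain mirrors how an FMCW vital-sign radar recovers chest motion:

1. fast-time FFT of each chirp (``range_fft``), bin spacing c/(2B);
2. unwrapped phase of the target's range bin across slow time
   (``extract_phase``), displacement-proportional: phi = 4 pi d / lambda;
3. robust spike (frame-loss "mutation") detection and neighbour-mean
   repair (``detect_mutations`` / ``repair_mutations``);
4. zero-phase Butterworth band separation into respiration (0.1-0.6 Hz)
   and heartbeat (0.8-4.0 Hz) channels (``bandpass_separate``);
5. rate estimation by FFT, autocorrelation and peak-interval methods with
   a confidence-based decision (``estimate_rate``).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .synth import RadarCube, RadarParams, RESPIRATION_BAND, HEARTBEAT_BAND

RATE_METHODS = ("fft", "autocorrelation", "peak_interval")


@dataclass
class PhaseSignal:
    """Unwrapped slow-time phase (rad) of one range bin."""

    samples: np.ndarray
    sampling_rate: float
    source_range_bin: int = -1

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")


@dataclass
class VitalSigns:
    """Band-separated respiration/heart signals with estimated rates."""

    respiration: np.ndarray
    heart: np.ndarray
    sampling_rate: float
    resp_rate_bpm: float | None = None
    resp_confidence: float | None = None
    heart_rate_bpm: float | None = None
    heart_confidence: float | None = None

    def __post_init__(self) -> None:
        self.respiration = np.asarray(self.respiration, dtype=float)
        self.heart = np.asarray(self.heart, dtype=float)
        if len(self.respiration) != len(self.heart):
            raise ValueError("respiration and heart channels must have equal length")


def range_fft(cube: RadarCube) -> np.ndarray:
    """Fast-time FFT per chirp: complex range profile, bins x frames.

    With N_fast = Tc * Fs_fast the bin spacing equals the range resolution
    c/(2B), so a static target at range d peaks in bin round(d / d_res).
    """
    if cube.data.size == 0:
        raise ValueError("empty radar cube")
    n_fast = cube.data.shape[0]
    return np.fft.fft(cube.data, axis=0)[: n_fast // 2 + 1]


def extract_phase(
    profile: np.ndarray,
    sampling_rate: float,
    range_bin: int | str = "auto",
    first_difference: bool = False,
) -> PhaseSignal:
    """Unwrapped phase of the selected range bin across slow time.

    ``range_bin="auto"`` picks the bin with the largest mean magnitude.
    ``first_difference=True`` returns the per-frame phase difference
    (length preserved; the first sample is 0).
    """
    profile = np.asarray(profile)
    if profile.ndim != 2 or profile.size == 0:
        raise ValueError("profile must be a non-empty bins x frames matrix")
    n_bins = profile.shape[0]
    if range_bin == "auto":
        range_bin = int(np.argmax(np.mean(np.abs(profile), axis=1)))
    range_bin = int(range_bin)
    if not (0 <= range_bin < n_bins):
        raise ValueError("range bin out of range")
    phase = np.unwrap(np.angle(profile[range_bin, :]))
    if first_difference:
        phase = np.diff(phase, prepend=phase[0])
    return PhaseSignal(samples=phase, sampling_rate=sampling_rate, source_range_bin=range_bin)


def phase_to_displacement_mm(phase: PhaseSignal | np.ndarray, params: RadarParams | None = None) -> np.ndarray:
    """Convert phase (rad) to chest displacement (mm): d = phi lambda / (4 pi)."""
    params = params or RadarParams()
    x = phase.samples if isinstance(phase, PhaseSignal) else np.asarray(phase, float)
    return x * params.wavelength / (4.0 * np.pi) * 1e3


def detect_mutations(x: np.ndarray, k_mad: float = 6.0) -> list[int]:
    """Flag frame-loss mutation points with a robust median/MAD rule.

    A sample is flagged when its deviation from the median of its (up to)
    four nearest neighbours exceeds ``k_mad`` times the MAD of those
    neighbours.  Smooth physiological signals have MAD of the same order
    as their local slope, so only genuine spikes trip the rule.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 5:
        raise ValueError("signal too short for mutation detection (need >= 5 samples)")
    if k_mad <= 0:
        raise ValueError("k_mad must be > 0")
    floor = 1e-9 * (np.max(np.abs(x)) + 1.0)
    flagged = []
    for i in range(n):
        lo, hi = i - 2, i + 3
        if lo < 0:
            lo, hi = 0, 5
        elif hi > n:
            lo, hi = n - 5, n
        nb = np.concatenate([x[lo:i], x[i + 1 : hi]])
        med = np.median(nb)
        mad = np.median(np.abs(nb - med))
        if abs(x[i] - med) > k_mad * mad + floor:
            flagged.append(i)
    return flagged


def repair_mutations(x: np.ndarray, indices: list[int]) -> np.ndarray:
    """Replace each flagged sample by the mean of its nearest clean neighbours.

    Boundary flags fall back to the single available neighbour; length is
    preserved so downstream truth annotations stay aligned.
    """
    x = np.asarray(x, dtype=float).copy()
    n = len(x)
    bad = set(int(i) for i in indices)
    if any(not (0 <= i < n) for i in bad):
        raise ValueError("mutation index out of range")
    if len(bad) == n:
        raise ValueError("cannot repair a signal whose samples are all flagged")
    orig = x.copy()
    for i in sorted(bad):
        left = next((j for j in range(i - 1, -1, -1) if j not in bad), None)
        right = next((j for j in range(i + 1, n) if j not in bad), None)
        vals = [orig[j] for j in (left, right) if j is not None]
        x[i] = float(np.mean(vals))
    return x


def detect_corrupt_frames(profile: np.ndarray, range_bin: int, k_mad: float = 6.0) -> list[int]:
    """Flag lost/corrupted frames from the range bin's magnitude series.

    A clean frame contributes near-constant magnitude at the target bin;
    a lost frame shows up as an amplitude spike (or collapse).  Detection
    must happen on magnitude *before* phase unwrapping: a corrupted
    frame's phase excursion aliases into a permanent 2 pi unwrap step and
    is invisible as a spike afterwards.
    """
    profile = np.asarray(profile)
    return detect_mutations(np.abs(profile[int(range_bin), :]), k_mad=k_mad)


def repair_profile(profile: np.ndarray, range_bin: int, indices: list[int]) -> np.ndarray:
    """Replace corrupted frames' complex samples at one bin by neighbour means."""
    profile = np.asarray(profile).copy()
    if not indices:
        return profile
    row = profile[int(range_bin), :]
    repaired = repair_mutations(row.real, indices) + 1j * repair_mutations(row.imag, indices)
    profile[int(range_bin), :] = repaired
    return profile


def bandpass_separate(
    phase: PhaseSignal | np.ndarray,
    sampling_rate: float | None = None,
    resp_band: tuple[float, float] = RESPIRATION_BAND,
    heart_band: tuple[float, float] = HEARTBEAT_BAND,
    order: int = 4,
) -> VitalSigns:
    """Split a phase/displacement signal into respiration and heart channels.

    Uses 4th-order Butterworth bandpass filters applied forward and
    backward (zero phase), one per band.
    """
    if isinstance(phase, PhaseSignal):
        x, fs = phase.samples, phase.sampling_rate
    else:
        if sampling_rate is None:
            raise ValueError("sampling_rate required for bare arrays")
        x, fs = np.asarray(phase, dtype=float), float(sampling_rate)
    for lo, hi in (resp_band, heart_band):
        if not (0 < lo < hi):
            raise ValueError("bands must satisfy 0 < lo < hi")
    if fs <= 2 * heart_band[1]:
        raise ValueError("sampling rate below Nyquist for the heart band")
    resp = _sos_bandpass(x, fs, resp_band, order)
    heart = _sos_bandpass(x, fs, heart_band, order)
    return VitalSigns(respiration=resp, heart=heart, sampling_rate=fs)


def _sos_bandpass(x: np.ndarray, fs: float, band: tuple[float, float], order: int) -> np.ndarray:
    sos = sps.butter(order, band, btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def _fft_estimate(x, fs, band):
    n = len(x)
    n_fft = int(2 ** np.ceil(np.log2(8 * n)))
    win = np.hanning(n)
    spec = np.abs(np.fft.rfft((x - x.mean()) * win, n_fft)) ** 2
    freqs = np.fft.rfftfreq(n_fft, 1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not mask.any() or spec[mask].sum() <= 0:
        return 0.0, 0.0
    in_band = spec[mask]
    f_in = freqs[mask]
    k = int(np.argmax(in_band))
    # confidence: spectral mass within one natural resolution bin of the
    # peak, as a fraction of the total in-band mass
    halfwidth = fs / n
    local = in_band[np.abs(f_in - f_in[k]) <= halfwidth].sum()
    conf = float(np.clip(local / in_band.sum(), 0.0, 1.0))
    return 60.0 * f_in[k], conf


def _autocorr_estimate(x, fs, band):
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom <= 0:
        return 0.0, 0.0
    acf = np.correlate(x, x, mode="full")[len(x) - 1 :] / denom
    lag_lo = max(1, int(np.floor(fs / band[1])))
    lag_hi = min(len(acf) - 1, int(np.ceil(fs / band[0])))
    if lag_hi <= lag_lo:
        return 0.0, 0.0
    seg = acf[lag_lo : lag_hi + 1]
    peaks, _ = sps.find_peaks(seg)
    if len(peaks) == 0:
        return 0.0, 0.0
    best = peaks[np.argmax(seg[peaks])]
    lag = lag_lo + best
    conf = float(np.clip(seg[best], 0.0, 1.0))
    return 60.0 * fs / lag, conf


def _peak_interval_estimate(x, fs, band):
    x = x - x.mean()
    amp = np.max(np.abs(x))
    if amp <= 0:
        return 0.0, 0.0
    min_dist = max(1, int(0.5 * fs / band[1]))
    peaks, _ = sps.find_peaks(x, distance=min_dist, prominence=0.3 * amp)
    if len(peaks) < 3:
        return 0.0, 0.0
    intervals = np.diff(peaks) / fs
    mean_iv = float(np.mean(intervals))
    rate_hz = 1.0 / mean_iv
    if not (band[0] <= rate_hz <= band[1]):
        return 0.0, 0.0
    cv = float(np.std(intervals) / mean_iv)
    return 60.0 * rate_hz, float(np.clip(1.0 - cv, 0.0, 1.0))


_ESTIMATORS = {
    "fft": _fft_estimate,
    "autocorrelation": _autocorr_estimate,
    "peak_interval": _peak_interval_estimate,
}


def estimate_rate(
    x: np.ndarray,
    sampling_rate: float,
    band: tuple[float, float],
    methods: tuple[str, ...] = RATE_METHODS,
) -> tuple[float, float]:
    """Estimate the dominant rate (per minute) in ``band`` with a confidence.

    Each requested method (spectral peak, autocorrelation, peak interval)
    produces a band-restricted estimate and a confidence in [0, 1]; the
    estimate of the highest-confidence method is returned.  A flat or
    out-of-band signal yields ``(0.0, 0.0)``, signalling a damaged segment.
    """
    x = np.asarray(x, dtype=float)
    lo, hi = band
    if not (0 < lo < hi):
        raise ValueError("band must satisfy 0 < lo < hi")
    if len(x) / sampling_rate < 2.0 / lo:
        raise ValueError("signal shorter than two cycles of the band's low edge")
    unknown = set(methods) - set(_ESTIMATORS)
    if unknown:
        raise ValueError(f"unknown rate methods: {sorted(unknown)}")
    if not np.any(x != x[0] if len(x) else False):
        return 0.0, 0.0
    best_rate, best_conf = 0.0, 0.0
    for m in methods:
        rate, conf = _ESTIMATORS[m](x, sampling_rate, band)
        if conf > best_conf:
            best_rate, best_conf = rate, conf
    return float(best_rate), float(best_conf)


def rate_error(measured: float, reference: float) -> float:
    """Percent error of a per-minute rate against a contact reference.

    100 |measured - reference| / reference, rounded to two decimals.
    """
    if reference <= 0:
        raise ValueError("reference rate must be > 0")
    return round(100.0 * abs(measured - reference) / reference, 2)


def column_mean(values) -> float:
    """Arithmetic mean of a non-empty list of counts."""
    values = list(values)
    if not values:
        raise ValueError("empty value list")
    return float(np.mean(values))


def process_cube(
    cube: RadarCube,
    repair: bool = True,
    first_difference: bool = False,
    resp_band: tuple[float, float] = RESPIRATION_BAND,
    heart_band: tuple[float, float] = HEARTBEAT_BAND,
) -> tuple[VitalSigns, PhaseSignal]:
    """Full chain: range FFT -> phase -> (repair) -> band separation -> rates.

    Returns the completed :class:`VitalSigns` (rates and confidences
    filled) and the repaired phase signal it was derived from.
    """
    profile = range_fft(cube)
    sel = int(np.argmax(np.mean(np.abs(profile), axis=1)))
    if repair:
        bad = detect_corrupt_frames(profile, sel)
        profile = repair_profile(profile, sel, bad)
    phase = extract_phase(profile, cube.params.slow_rate, range_bin=sel,
                          first_difference=first_difference)
    if repair:
        residual = detect_mutations(phase.samples)
        if residual:
            phase = PhaseSignal(
                repair_mutations(phase.samples, residual), phase.sampling_rate, sel
            )
    vs = bandpass_separate(phase, resp_band=resp_band, heart_band=heart_band)
    vs.resp_rate_bpm, vs.resp_confidence = estimate_rate(vs.respiration, vs.sampling_rate, resp_band)
    vs.heart_rate_bpm, vs.heart_confidence = estimate_rate(vs.heart, vs.sampling_rate, heart_band)
    return vs, phase
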