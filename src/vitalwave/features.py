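"""Respiratory-pattern features: VPD peaks, short-term energy, instantaneous frequency.

Three feature families describe one minute of respiration signal:

* **Valley-to-peak-difference (VPD) peak finding** — after three-point
  forward-backward smoothing, all local extrema are located and peaks are
  iteratively screened: a peak whose rise over its reference valley,
  VPD(k) = P(k) - V(k), falls below 0.7x the local three-term VPD mean is
  deleted as noise-induced.  Iteration stops when the peak count is stable
  between consecutive passes.  Valleys are never deleted, so the valley
  count stays at or above the peak count; the count difference
  (valleys - peaks) is itself a feature.
* **Normalized short-term energy** — the signal is scaled by its maximum
  absolute value and affinely mapped onto [-1, 1], then the energy of
  non-overlapping 4 s rectangular windows (N = 80 samples at 20 Hz) is
  summarised by its mean and standard deviation.  Breathing patterns with
  apnea phases (Biot, Cheyne-Stokes) show much larger energy spread.
* **Instantaneous frequency** — the Hilbert analytic signal's phase is
  differentiated to an instantaneous frequency in Hz (negative excursions
  clipped to 0).  Its mean separates fast from slow breathing; its minimum
  is ~0 exactly for patterns with apnea plateaus.

The 8-vector [n_peaks, n_valleys, diff, ste_mean, ste_std, if_mean,
if_std, if_min] feeds the pattern classifier.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

FEATURE_NAMES = (
    "n_peaks",
    "n_valleys",
    "diff",
    "ste_mean",
    "ste_std",
    "if_mean",
    "if_std",
    "if_min",
)


@dataclass
class PeakSet:
    """Surviving peaks, all detected valleys, and the VPD series."""

    peak_positions: np.ndarray
    peak_values: np.ndarray
    valley_positions: np.ndarray
    valley_values: np.ndarray
    vpd_series: np.ndarray
    n_iterations: int = 0
    peak_count_history: tuple = ()

    @property
    def n_peaks(self) -> int:
        return len(self.peak_positions)

    @property
    def n_valleys(self) -> int:
        return len(self.valley_positions)


@dataclass
class InstFreq:
    """Analytic amplitude/phase and instantaneous-frequency summaries (Hz)."""

    amplitude: np.ndarray
    phase: np.ndarray
    inst_freq_hz: np.ndarray
    mean: float
    std: float
    min: float


@dataclass(frozen=True)
class FeatureVector:
    """The eight pattern features with an optional class label (1-5)."""

    n_peaks: int
    n_valleys: int
    diff: int
    ste_mean: float
    ste_std: float
    if_mean: float
    if_std: float
    if_min: float
    label: int | None = None

    def __post_init__(self) -> None:
        if self.diff != self.n_valleys - self.n_peaks:
            raise ValueError("diff must equal n_valleys - n_peaks")

    def as_array(self) -> np.ndarray:
        return np.array(
            [getattr(self, name) for name in FEATURE_NAMES], dtype=float
        )


def smooth_forward_backward(x: np.ndarray) -> np.ndarray:
    """Three-point moving average applied forward and backward (zero phase).

    Edges use shrunken windows so the length is preserved.  The symmetric
    kernel has no phase shift; the backward pass doubles the smoothing.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("signal too short to smooth (need >= 3 samples)")
    return _box3(_box3(x))


def _box3(x: np.ndarray) -> np.ndarray:
    s = np.convolve(x, np.ones(3), mode="same")
    counts = np.convolve(np.ones_like(x), np.ones(3), mode="same")
    return s / counts


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Local maxima and minima positions; a lower starting sample counts as a valley."""
    peaks, _ = sps.find_peaks(x)
    valleys, _ = sps.find_peaks(-x)
    # A record that opens on a trough has no interior minimum before its
    # first crest; count the first sample as that trough.
    if len(x) >= 2 and x[0] < x[1] and (len(valleys) == 0 or valleys[0] != 0):
        valleys = np.concatenate([[0], valleys])
    return peaks.astype(int), valleys.astype(int)


def _pair_vpd(x, peak_pos, valley_pos):
    """VPD(k) = P(k) - V(k) with V(k) the deepest valley since the previous peak.

    Pairing against the deepest intervening valley measures the true rise
    of each breath; a shallow noise dip on a crest never becomes a peak's
    reference valley.
    """
    vpd = np.empty(len(peak_pos))
    prev = -1
    for k, p in enumerate(peak_pos):
        mask = (valley_pos > prev) & (valley_pos < p)
        cand = valley_pos[mask] if mask.any() else valley_pos[valley_pos < p]
        vpd[k] = x[p] - np.min(x[cand])
        prev = p
    return vpd


def vpd_peak_finding(x: np.ndarray, ratio: float = 0.7) -> PeakSet:
    """Iterative valley-to-peak-difference peak screening.

    Steps: (a) smooth; (b) locate all extrema; (c) discard peaks before
    the first valley so the series starts at a valley; (d) compute the VPD
    series and delete peaks with VPD(k) < ratio * mean(VPD(k-1..k+1))
    (edge terms replicated); (e) repeat until the peak count is unchanged
    between consecutive iterations.  Valleys are retained throughout.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 5:
        raise ValueError("signal too short for VPD peak finding (need >= 5 samples)")
    xs = smooth_forward_backward(x)
    peaks, valleys = _local_extrema(xs)
    if len(peaks) == 0 or len(valleys) == 0:
        return PeakSet(
            np.array([], int), np.array([]), valleys, xs[valleys] if len(valleys) else np.array([]),
            np.array([]), n_iterations=0, peak_count_history=(0,),
        )
    peaks = peaks[peaks > valleys[0]]  # step (c)
    history = [len(peaks)]
    n_iter = 0
    vpd = np.array([])
    while len(peaks) > 0:
        n_iter += 1
        vpd = _pair_vpd(xs, peaks, valleys)
        padded = np.concatenate([[vpd[0]], vpd, [vpd[-1]]])
        local_mean = (padded[:-2] + padded[1:-1] + padded[2:]) / 3.0
        keep = vpd >= ratio * local_mean
        if keep.all():
            break
        peaks = peaks[keep]
        history.append(len(peaks))
    if len(peaks) > 0:
        vpd = _pair_vpd(xs, peaks, valleys)
    return PeakSet(
        peak_positions=peaks,
        peak_values=xs[peaks],
        valley_positions=valleys,
        valley_values=xs[valleys],
        vpd_series=vpd,
        n_iterations=n_iter,
        peak_count_history=tuple(history),
    )


def naive_findpeaks(x: np.ndarray) -> PeakSet:
    """All strict local extrema, no smoothing, no screening (baseline)."""
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("signal too short (need >= 3 samples)")
    peaks, _ = sps.find_peaks(x)
    valleys, _ = sps.find_peaks(-x)
    return PeakSet(
        peak_positions=peaks.astype(int),
        peak_values=x[peaks],
        valley_positions=valleys.astype(int),
        valley_values=x[valleys],
        vpd_series=np.array([]),
        n_iterations=0,
        peak_count_history=(len(peaks),),
    )


def normalize(x: np.ndarray) -> np.ndarray:
    """Two-step normalization onto exactly [-1, 1].

    Divide by the maximum absolute value, then map affinely so the minimum
    is -1 and the maximum is +1.  Constant signals have zero range and are
    rejected.
    """
    x = np.asarray(x, dtype=float)
    peak = np.max(np.abs(x))
    if peak == 0 or np.ptp(x) == 0:
        raise ValueError("cannot normalize a constant signal")
    x = x / peak
    return -1.0 + (x - x.min()) / (x.max() - x.min()) * 2.0


def short_term_energy(xn: np.ndarray, window: int = 80, hop: int | None = None) -> np.ndarray:
    """En = sum xn^2 over rectangular windows (default 4 s = 80 samples at 20 Hz).

    Windows are non-overlapping by default (hop = window); the trailing
    partial window is dropped.
    """
    xn = np.asarray(xn, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > len(xn):
        raise ValueError("window longer than signal")
    hop = window if hop is None else hop
    if hop < 1:
        raise ValueError("hop must be >= 1")
    starts = np.arange(0, len(xn) - window + 1, hop)
    return np.array([float(np.sum(xn[s : s + window] ** 2)) for s in starts])


def instantaneous_frequency(
    x: np.ndarray, sampling_rate: float, interior: float = 0.95
) -> InstFreq:
    """Hilbert-transform instantaneous frequency in Hz.

    The analytic signal z = x + i H[x] gives amplitude a(t) = |z| and
    unwrapped phase theta(t); the instantaneous frequency is the phase
    derivative (central differences) divided by 2 pi, clipped below at 0.
    Summaries (mean/std/min) are taken over the interior ``interior``
    fraction of samples to exclude transform edge distortion.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 16:
        raise ValueError("signal too short for instantaneous frequency (need >= 16)")
    if not np.any(x != 0):
        raise ValueError("all-zero signal has no instantaneous frequency")
    x = x - x.mean()
    z = sps.hilbert(x)
    amp = np.abs(z)
    theta = np.unwrap(np.angle(z))
    omega = np.gradient(theta) * sampling_rate / (2.0 * np.pi)
    omega = np.clip(omega, 0.0, None)
    margin = int(round(len(x) * (1.0 - interior) / 2.0))
    core = omega[margin : len(x) - margin] if margin > 0 else omega
    return InstFreq(
        amplitude=amp,
        phase=theta,
        inst_freq_hz=omega,
        mean=float(np.mean(core)),
        std=float(np.std(core)),
        min=float(np.min(core)),
    )


def extract_features(
    x: np.ndarray,
    sampling_rate: float = 20.0,
    label: int | None = None,
    ste_window_s: float = 4.0,
) -> FeatureVector:
    """Assemble the 8-dimensional pattern descriptor of one respiration record.

    Feature order: [n_peaks, n_valleys, diff, ste_mean, ste_std, if_mean,
    if_std, if_min] with diff = n_valleys - n_peaks.
    """
    x = np.asarray(x, dtype=float)
    ps = vpd_peak_finding(x)
    xn = normalize(x)
    en = short_term_energy(xn, window=int(round(ste_window_s * sampling_rate)))
    iff = instantaneous_frequency(x, sampling_rate)
    return FeatureVector(
        n_peaks=ps.n_peaks,
        n_valleys=ps.n_valleys,
        diff=ps.n_valleys - ps.n_peaks,
        ste_mean=float(np.mean(en)),
        ste_std=float(np.std(en)),
        if_mean=iff.mean,
        if_std=iff.std,
        if_min=iff.min,
        label=label,
    )
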