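"""Apnea judgment from windowed energy intensity and an adaptive threshold.

A rectangular window segments the respiration (or heart) signal; each
segment's energy intensity is E(i) = sum of squared samples.  The
threshold D(n) is half a running reference energy:

* n = 1: half the first segment's energy;
* 2 <= n < 5: half the mean of all segments observed so far;
* n >= 5: half the mean of the first five segments (the initial
  normal-breathing reference).

Apnea is declared for segments whose energy falls strictly below the
threshold (output ``1``); ties and higher energies output ``0``.  A
``trailing`` threshold mode replaces the fixed five-segment reference by
the trailing five segments including the current one; it tracks slow
amplitude drift but collapses to D = 0 during sustained apnea, so the
anchored mode is the default.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class ApneaInterval:
    """Half-open apnea interval [start, stop) in segment (or sample) units."""

    start: int
    stop: int

    def __post_init__(self) -> None:
        if self.stop <= self.start:
            raise ValueError("interval must satisfy start < stop")

    def __len__(self) -> int:
        return self.stop - self.start


@dataclass
class EnergyJudgment:
    """Per-segment energies, thresholds and binary apnea output."""

    energies_e: np.ndarray
    thresholds_d: np.ndarray
    binary_out: np.ndarray
    segment_window: int
    segment_hop: int

    def __post_init__(self) -> None:
        self.energies_e = np.asarray(self.energies_e, dtype=float)
        self.thresholds_d = np.asarray(self.thresholds_d, dtype=float)
        self.binary_out = np.asarray(self.binary_out, dtype=int)
        if not (len(self.energies_e) == len(self.thresholds_d) == len(self.binary_out)):
            raise ValueError("energies, thresholds and output must have equal length")
        if np.any(self.energies_e < 0):
            raise ValueError("energies must be non-negative")


def segment_energy(x: np.ndarray, window: int, hop: int) -> np.ndarray:
    """Energy intensity E(i) = sum x^2 over each rectangular window.

    Windows start every ``hop`` samples; the trailing partial window is
    dropped.
    """
    x = np.asarray(x, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if not (1 <= hop <= window):
        raise ValueError("hop must satisfy 1 <= hop <= window")
    if window > len(x):
        raise ValueError("window longer than signal")
    starts = np.arange(0, len(x) - window + 1, hop)
    return np.array([float(np.sum(x[s : s + window] ** 2)) for s in starts])


def adaptive_threshold(energies: np.ndarray, mode: str = "anchored") -> np.ndarray:
    """Per-segment threshold D(n) = 50% of a reference energy.

    ``anchored`` (default): reference = mean of the first min(n, 5)
    segment energies, so the threshold locks onto the initial
    normal-breathing level.  ``trailing``: for n >= 5 the reference is the
    mean of the trailing five segments including the current one.
    """
    e = np.asarray(energies, dtype=float)
    if len(e) == 0:
        raise ValueError("empty energy sequence")
    if np.any(e < 0):
        raise ValueError("energies must be non-negative")
    if mode not in ("anchored", "trailing"):
        raise ValueError("mode must be 'anchored' or 'trailing'")
    d = np.empty_like(e)
    for n in range(1, len(e) + 1):  # 1-based segment index
        if n < 5 or mode == "anchored":
            ref = float(np.mean(e[: min(n, 5)]))
        else:
            ref = float(np.mean(e[n - 5 : n]))
        d[n - 1] = 0.5 * ref
    return d


def judge(energies: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Binary apnea output: 1 where E(i) < D(i), else 0 (ties are 'not lower')."""
    e = np.asarray(energies, dtype=float)
    d = np.asarray(thresholds, dtype=float)
    if len(e) != len(d):
        raise ValueError("energies and thresholds must have equal length")
    return (e < d).astype(int)


def extract_intervals(binary: np.ndarray, min_len: int = 3) -> list[ApneaInterval]:
    """Maximal runs of 1s with length >= ``min_len`` as half-open intervals."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    b = np.asarray(binary, dtype=int)
    intervals: list[ApneaInterval] = []
    start = None
    for i, v in enumerate(b):
        if v and start is None:
            start = i
        elif not v and start is not None:
            if i - start >= min_len:
                intervals.append(ApneaInterval(start, i))
            start = None
    if start is not None and len(b) - start >= min_len:
        intervals.append(ApneaInterval(start, len(b)))
    return intervals


def detection_accuracy(detected, actual) -> float:
    """Overlap of detected with actual apnea, as a percent of the actual length.

    ``100 * |detected & actual| / |actual|`` with interval length
    ``stop - start``; reported to one decimal.  Disjoint intervals give 0.
    """
    d = detected if isinstance(detected, ApneaInterval) else ApneaInterval(*detected)
    a = actual if isinstance(actual, ApneaInterval) else ApneaInterval(*actual)
    overlap = max(0, min(d.stop, a.stop) - max(d.start, a.start))
    return round(100.0 * overlap / len(a), 1)


@dataclass
class JointJudgment:
    """Combined apnea verdict with a heart-confirmation mask."""

    binary: np.ndarray
    heart_confirmed: np.ndarray


def joint_judgment(resp_binary: np.ndarray, heart_binary: np.ndarray) -> JointJudgment:
    """Combine respiration and heart verdicts.

    The respiration channel dominates (its judgment accuracy is higher):
    the combined output is 1 exactly where respiration says 1, and a
    segment is heart-confirmed where both channels agree on apnea.  If the
    two sequences differ in length the shorter one is resampled by nearest
    segment.
    """
    r = np.asarray(resp_binary, dtype=int)
    h = np.asarray(heart_binary, dtype=int)
    if len(r) == 0 and len(h) == 0:
        raise ValueError("both judgment sequences are empty")
    if len(r) != len(h):
        if len(r) < len(h):
            r = _resample_nearest(r, len(h))
        else:
            h = _resample_nearest(h, len(r))
    return JointJudgment(binary=r.copy(), heart_confirmed=(r & h).astype(int))


def _resample_nearest(b: np.ndarray, n: int) -> np.ndarray:
    idx = np.clip(np.round(np.linspace(0, len(b) - 1, n)).astype(int), 0, len(b) - 1)
    return b[idx]


def apnea_judgment(
    x: np.ndarray,
    window: int = 80,
    hop: int = 5,
    mode: str = "anchored",
    min_len: int = 3,
) -> tuple[EnergyJudgment, list[ApneaInterval]]:
    """Windowed energy -> adaptive threshold -> binary output -> intervals.

    Defaults (window 80 samples = 4 s at 20 Hz, hop 5 samples) give
    ~0.25 s judgment granularity (~225 points over 60 s) while each
    window spans at least one breath cycle, so the energy of normal
    breathing does not dip at the zero crossings within a cycle.
    """
    e = segment_energy(x, window, hop)
    d = adaptive_threshold(e, mode=mode)
    b = judge(e, d)
    ej = EnergyJudgment(e, d, b, window, hop)
    return ej, extract_intervals(b, min_len=min_len)


def samples_to_segments(interval: tuple[int, int], window: int, hop: int) -> ApneaInterval:
    """Map a sample-unit truth interval to the segments fully inside it.

    Segment i covers samples [i*hop, i*hop + window); the returned
    half-open segment interval contains exactly the segments whose windows
    lie entirely within the sample interval.
    """
    start_s, stop_s = interval
    first = int(np.ceil(start_s / hop))
    last = (stop_s - window) // hop  # last fully-contained segment
    if last < first:
        raise ValueError("interval shorter than one segment window")
    return ApneaInterval(first, last + 1)
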