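"""Synthetic chest-motion traces and simplified FMCW intermediate-frequency cubes.

The generators in this module stand in for a 77 GHz frequency-modulated
continuous-wave (FMCW) radar pointed at a breathing subject.  Chest-wall
displacement is modelled as a raised-cosine cycle train (one smooth
peak/valley pair per breath, amplitude 1-12 mm, 0.1-0.6 Hz) optionally
superposed with a sinusoidal heartbeat component (0.8-4.0 Hz, 0.1-0.5 mm)
and additive Gaussian sensor noise.  Five clinical breathing patterns plus
a normal/apnea/normal protocol are encoded as phase schedules:

==================  ============================================================
normal              steady breathing, default period 3.3 s (~18 breaths/min)
biot                30 s apnea, then 30 s of strong 4 s cycles
tachypnea           2 s cycles for the whole record (>20 breaths/min)
bradypnea           8 s cycles for the whole record (<10 breaths/min)
cheyne_stokes       apnea / 20 s crescendo / 20 s decrescendo / apnea
apnea_protocol      20 s normal, 20 s apnea, 20 s normal
==================  ============================================================

A :func:`simulate_if_cube` routine turns a displacement trace into a
fast-time x slow-time complex IF data cube (one chirp per frame) so the
whole demodulation chain can be exercised without hardware.
"""
from __future__ import annotations

import dataclasses
import enum
import warnings
from dataclasses import dataclass, field

import numpy as np

SPEED_OF_LIGHT = 3.0e8  # m/s, radar convention (makes d_res = c/2B exactly 0.0375 m at B = 4 GHz)

#: body-surface vibration bands (Hz) for respiration and heartbeat
RESPIRATION_BAND = (0.1, 0.6)
HEARTBEAT_BAND = (0.8, 4.0)
HEARTBEAT_AMPLITUDE_MM = (0.1, 0.5)


class Pattern(str, enum.Enum):
    """Respiratory pattern labels (class indices 1-5 follow this order)."""

    NORMAL = "normal"
    BIOT = "biot"
    TACHYPNEA = "tachypnea"
    BRADYPNEA = "bradypnea"
    CHEYNE_STOKES = "cheyne_stokes"
    APNEA_PROTOCOL = "apnea_protocol"


#: integer class labels used by the classifier (the protocol trace is unlabeled)
PATTERN_LABELS = {
    Pattern.NORMAL: 1,
    Pattern.BIOT: 2,
    Pattern.TACHYPNEA: 3,
    Pattern.BRADYPNEA: 4,
    Pattern.CHEYNE_STOKES: 5,
}


@dataclass(frozen=True)
class RadarParams:
    """Linear-FM chirp parameters of the radar front end.

    Defaults follow a 77 GHz automotive-band sensor configured for
    vital-sign sensing: 4 GHz sweep bandwidth, 100 chirps per frame,
    50 us chirp, 20 frames/s slow-time rate and a 2 MHz ADC.
    """

    bandwidth_b: float = 4e9
    n_chirps: int = 100
    chirp_duration: float = 50e-6
    start_freq: float = 77e9
    slow_rate: float = 20.0
    fast_rate: float = 2e6
    c: float = SPEED_OF_LIGHT

    def __post_init__(self) -> None:
        for name in ("bandwidth_b", "chirp_duration", "start_freq", "slow_rate", "fast_rate", "c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"RadarParams.{name} must be strictly positive")
        if self.n_chirps < 1:
            raise ValueError("RadarParams.n_chirps must be >= 1")

    @property
    def range_resolution(self) -> float:
        """Range-bin spacing d_res = c / (2 B) in metres."""
        return self.c / (2.0 * self.bandwidth_b)

    @property
    def speed_resolution(self) -> float:
        """Angular speed resolution 2 pi / N (rad) of the Doppler axis."""
        return 2.0 * np.pi / self.n_chirps

    @property
    def wavelength(self) -> float:
        return self.c / self.start_freq

    @property
    def chirp_slope(self) -> float:
        """Frequency sweep slope S = B / Tc in Hz/s."""
        return self.bandwidth_b / self.chirp_duration

    @property
    def n_fast(self) -> int:
        """ADC samples per chirp."""
        return round(self.chirp_duration * self.fast_rate)

    @property
    def max_range(self) -> float:
        """Maximum unambiguous range of the (real-sampled) beat spectrum."""
        return self.range_resolution * (self.n_fast / 2)


@dataclass(frozen=True)
class PatternSpec:
    """A breathing protocol: pattern label, amplitude, cycle period and phase schedule.

    ``phase_schedule`` is an ordered list of ``(kind, duration_s)`` segments
    with ``kind`` one of ``breathe``, ``apnea``, ``crescendo``,
    ``decrescendo``.
    """

    pattern: Pattern
    duration_s: float = 60.0
    breath_amplitude_mm: float = 6.0
    cycle_period_s: float = 3.3
    phase_schedule: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if self.breath_amplitude_mm < 0:
            raise ValueError("breath_amplitude_mm must be >= 0")
        if self.breath_amplitude_mm > 12:
            warnings.warn("breath amplitude outside the 1-12 mm chest-wall range", stacklevel=2)
        if self.cycle_period_s <= 0:
            raise ValueError("cycle_period_s must be > 0")
        total = sum(d for _, d in self.phase_schedule)
        if self.phase_schedule and abs(total - self.duration_s) > 1e-6:
            raise ValueError("phase_schedule durations must sum to duration_s")
        for kind, dur in self.phase_schedule:
            if kind not in ("breathe", "apnea", "crescendo", "decrescendo"):
                raise ValueError(f"unknown segment kind {kind!r}")
            if dur <= 0:
                raise ValueError("segment durations must be > 0")

    @classmethod
    def default(
        cls,
        pattern: Pattern | str,
        duration_s: float = 60.0,
        breath_amplitude_mm: float = 6.0,
        cycle_period_s: float | None = None,
    ) -> "PatternSpec":
        """Default protocol for a pattern.

        Periods and schedules encode the standard simulation protocols:
        tachypnea 2 s cycles, bradypnea 8 s cycles, Biot 30 s apnea +
        30 s of 4 s cycles, Cheyne-Stokes apnea-crescendo-decrescendo-apnea,
        apnea protocol 20/20/20 s.
        """
        pattern = Pattern(pattern)
        periods = {
            Pattern.NORMAL: 3.3,
            Pattern.BIOT: 4.0,
            Pattern.TACHYPNEA: 2.0,
            Pattern.BRADYPNEA: 8.0,
            Pattern.CHEYNE_STOKES: 3.3,
            Pattern.APNEA_PROTOCOL: 3.3,
        }
        period = cycle_period_s if cycle_period_s is not None else periods[pattern]
        d = duration_s
        if pattern is Pattern.BIOT:
            schedule = (("apnea", d / 2), ("breathe", d / 2))
        elif pattern is Pattern.CHEYNE_STOKES:
            # ~20 s crescendo / ~20 s decrescendo bracketed by apnea; the
            # bracketing apnea absorbs whatever the ramps do not fill.
            ramp = min(20.0, d / 3)
            pad = (d - 2 * ramp) / 2
            schedule = (("apnea", pad), ("crescendo", ramp), ("decrescendo", ramp), ("apnea", pad))
        elif pattern is Pattern.APNEA_PROTOCOL:
            schedule = (("breathe", d / 3), ("apnea", d / 3), ("breathe", d / 3))
        else:
            schedule = (("breathe", d),)
        return cls(
            pattern=pattern,
            duration_s=d,
            breath_amplitude_mm=breath_amplitude_mm,
            cycle_period_s=period,
            phase_schedule=schedule,
        )


@dataclass
class DisplacementTrace:
    """Uniformly sampled chest displacement in millimetres with ground truth."""

    samples: np.ndarray
    sampling_rate: float
    truth_pattern: Pattern | None = None
    truth_apnea_intervals: list = field(default_factory=list)
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        n = len(self.samples)
        prev_stop = 0
        for start, stop in self.truth_apnea_intervals:
            if not (0 <= start < stop <= n):
                raise ValueError("apnea interval outside trace")
            if start < prev_stop:
                raise ValueError("apnea intervals must be sorted and non-overlapping")
            prev_stop = stop

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sampling_rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sampling_rate

    def replace_samples(self, samples: np.ndarray) -> "DisplacementTrace":
        return dataclasses.replace(self, samples=np.asarray(samples, dtype=float))


@dataclass
class RadarCube:
    """Complex IF samples, fast time (rows) x slow time (columns)."""

    data: np.ndarray
    params: RadarParams
    target_base_range_m: float
    dropped_frames: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.ndim != 2:
            raise ValueError("cube data must be 2-D (fast x slow)")
        if self.data.shape[0] != self.params.n_fast:
            raise ValueError("fast-time dimension must equal round(Tc * Fs_fast)")
        n_frames = self.data.shape[1]
        if any(not (0 <= f < n_frames) for f in self.dropped_frames):
            raise ValueError("dropped_frames outside valid slow-time indices")

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]


def _cycle_train(n: int, period_n: int, amplitude: float, envelope: str | None = None) -> np.ndarray:
    """Raised-cosine breath train of ``n`` samples, ``period_n`` samples/cycle.

    The train is continuous: a partial final cycle is truncated at the
    segment end rather than padded with a fake breath hold.  ``envelope``
    applies a per-cycle linear amplitude ramp for crescendo/decrescendo
    segments (the ramp changes at the zero crossings between cycles, so the
    waveform stays continuous).
    """
    idx = np.arange(n)
    base = 0.5 * (1.0 - np.cos(2.0 * np.pi * idx / period_n))
    cycle = idx // period_n
    n_cycles = int(np.ceil(n / period_n))
    if envelope == "crescendo":
        amp = amplitude * (cycle + 1) / n_cycles
    elif envelope == "decrescendo":
        amp = amplitude * (n_cycles - cycle) / n_cycles
    else:
        amp = amplitude
    return amp * base


def generate_pattern(
    spec: PatternSpec, sampling_rate: float = 20.0, seed: int | None = None
) -> DisplacementTrace:
    """Render a noiseless chest-displacement trace from a pattern spec.

    The breathing component is a raised-cosine cycle train at the spec's
    period and amplitude, identically zero during apnea segments.  Ground
    truth (pattern label, apnea sample intervals) is recorded on the trace.
    """
    if not isinstance(spec, PatternSpec):
        raise TypeError("spec must be a PatternSpec")
    if sampling_rate < 4:
        raise ValueError("sampling_rate must be >= 4 Hz")
    if spec.duration_s < spec.cycle_period_s:
        raise ValueError("duration shorter than one breathing cycle")
    schedule = spec.phase_schedule or (("breathe", spec.duration_s),)
    n_total = round(spec.duration_s * sampling_rate)
    period_n = max(2, round(spec.cycle_period_s * sampling_rate))
    samples = np.zeros(n_total)
    apnea_intervals: list[tuple[int, int]] = []
    pos = 0
    for kind, seg_dur in schedule:
        seg_n = min(round(seg_dur * sampling_rate), n_total - pos)
        if seg_n <= 0:
            continue
        if kind == "apnea":
            apnea_intervals.append((pos, pos + seg_n))
        elif kind == "breathe":
            samples[pos : pos + seg_n] = _cycle_train(seg_n, period_n, spec.breath_amplitude_mm)
        else:  # crescendo / decrescendo
            samples[pos : pos + seg_n] = _cycle_train(
                seg_n, period_n, spec.breath_amplitude_mm, envelope=kind
            )
        pos += seg_n
    return DisplacementTrace(
        samples=samples,
        sampling_rate=sampling_rate,
        truth_pattern=spec.pattern,
        truth_apnea_intervals=apnea_intervals,
        rng_seed=seed,
    )


def add_heartbeat(
    trace: DisplacementTrace,
    heart_rate_hz: float = 1.2,
    amplitude_mm: float = 0.3,
    seed: int | None = None,
) -> DisplacementTrace:
    """Superpose a sinusoidal heartbeat component on a trace.

    The heartbeat persists through apnea segments (the heart keeps beating);
    the random seed only sets the initial cardiac phase.
    """
    if amplitude_mm < 0:
        raise ValueError("amplitude_mm must be >= 0")
    if not (HEARTBEAT_BAND[0] <= heart_rate_hz <= HEARTBEAT_BAND[1]):
        warnings.warn("heart rate outside the 0.8-4.0 Hz band", stacklevel=2)
    if not (HEARTBEAT_AMPLITUDE_MM[0] <= amplitude_mm <= HEARTBEAT_AMPLITUDE_MM[1]) and amplitude_mm > 0:
        warnings.warn("heartbeat amplitude outside the 0.1-0.5 mm range", stacklevel=2)
    if amplitude_mm == 0:
        return trace.replace_samples(trace.samples)
    phase0 = 0.0
    if seed is not None:
        phase0 = float(np.random.default_rng(seed).uniform(0, 2 * np.pi))
    hb = amplitude_mm * np.sin(2 * np.pi * heart_rate_hz * trace.time + phase0)
    return trace.replace_samples(trace.samples + hb)


def add_noise(trace: DisplacementTrace, sigma_mm: float, seed: int | None = None) -> DisplacementTrace:
    """Add zero-mean Gaussian sensor noise (mm), deterministic given seed."""
    if sigma_mm < 0:
        raise ValueError("sigma_mm must be >= 0")
    if sigma_mm == 0:
        return trace.replace_samples(trace.samples)
    rng = np.random.default_rng(seed)
    return trace.replace_samples(trace.samples + rng.normal(0.0, sigma_mm, len(trace.samples)))


def inject_spikes(
    trace: DisplacementTrace,
    n_spikes: int = 1,
    seed: int | None = None,
    indices: list[int] | None = None,
    magnitude: float = 10.0,
) -> tuple[DisplacementTrace, list[int]]:
    """Inject frame-loss mutation artifacts: additive spikes of ``magnitude`` x max |sample|.

    Returns the corrupted trace and the sorted spike indices.  Emulates the
    point mutations left by dropped radar frames in the demodulated signal.
    """
    x = trace.samples.copy()
    scale = float(np.max(np.abs(x))) or 1.0
    if indices is None:
        rng = np.random.default_rng(seed)
        indices = sorted(rng.choice(len(x), size=n_spikes, replace=False).tolist())
    else:
        indices = sorted(int(i) for i in indices)
    for i in indices:
        x[i] += magnitude * scale
    return trace.replace_samples(x), indices


def simulate_if_cube(
    trace: DisplacementTrace,
    params: RadarParams | None = None,
    base_range_m: float = 0.30,
    dropout_rate: float = 0.0,
    seed: int | None = None,
) -> RadarCube:
    """Synthesize a simplified IF data cube from a displacement trace.

    One chirp is rendered per slow-time frame as a unit-amplitude complex
    tone whose beat frequency is f_b = 2 S d(t) / c (S = B/Tc) and whose
    phase is phi(t) = 4 pi d(t) / lambda, with d(t) the base range plus the
    chest displacement.  Frame dropouts (Bernoulli ``dropout_rate`` per
    frame) are emulated as corrupted frames: 10x amplitude with the phase
    flipped by pi, the spike artifact a lost frame leaves after demodulation.
    """
    params = params or RadarParams()
    if not (0.0 <= dropout_rate < 1.0):
        raise ValueError("dropout_rate must be in [0, 1)")
    if not (0.0 < base_range_m < params.max_range):
        raise ValueError(
            f"base_range_m must lie within (0, {params.max_range:.3f}) m for these parameters"
        )
    n_frames = len(trace.samples)
    t_fast = np.arange(params.n_fast) / params.fast_rate  # (n_fast,)
    d = base_range_m + trace.samples * 1e-3  # metres, (n_frames,)
    f_beat = 2.0 * params.chirp_slope * d / params.c
    phi = 4.0 * np.pi * d / params.wavelength
    # frames in columns: exp(j(2 pi f_b t + phi))
    data = np.exp(1j * (2.0 * np.pi * t_fast[:, None] * f_beat[None, :] + phi[None, :]))
    dropped: list[int] = []
    if dropout_rate > 0:
        rng = np.random.default_rng(seed)
        dropped = np.flatnonzero(rng.random(n_frames) < dropout_rate).tolist()
        for f in dropped:
            data[:, f] *= -10.0  # 10x amplitude, pi phase flip
    return RadarCube(data=data, params=params, target_base_range_m=base_range_m, dropped_frames=dropped)


def random_trace(
    pattern: Pattern | str,
    seed: int,
    duration_s: float = 60.0,
    sampling_rate: float = 20.0,
    noise_sigma_mm: float = 0.1,
    heartbeat: bool = True,
) -> DisplacementTrace:
    """One physiologically varied trace of a pattern, fully determined by ``seed``.

    Per-trace variation emulates inter-subject spread: breath amplitude
    uniform in 3-9 mm, cycle period jittered +/-10% around the pattern
    default, heart rate uniform in 0.9-1.5 Hz at 0.1-0.5 mm, plus 0.1 mm
    RMS sensor noise.
    """
    pattern = Pattern(pattern)
    rng = np.random.default_rng(seed)
    amp = float(rng.uniform(3.0, 9.0))
    base_period = PatternSpec.default(pattern).cycle_period_s
    period = base_period * float(rng.uniform(0.9, 1.1))
    spec = PatternSpec.default(
        pattern, duration_s=duration_s, breath_amplitude_mm=amp, cycle_period_s=period
    )
    trace = generate_pattern(spec, sampling_rate=sampling_rate, seed=seed)
    if heartbeat:
        hr = float(rng.uniform(0.9, 1.5))
        hamp = float(rng.uniform(0.1, 0.5))
        trace = add_heartbeat(trace, hr, hamp, seed=int(rng.integers(2**31 - 1)))
    if noise_sigma_mm > 0:
        trace = add_noise(trace, noise_sigma_mm, seed=int(rng.integers(2**31 - 1)))
    trace.rng_seed = seed
    return trace
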