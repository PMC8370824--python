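# Methods

## Measurement model

A frequency-modulated continuous-wave (FMCW) radar transmits linear
frequency sweeps (chirps) and mixes the echo with the transmitted chirp;
the resulting intermediate-frequency (IF) tone has beat frequency
`f_b = 2 S d / c` (sweep slope `S = B / Tc`) and phase `φ = 4π d / λ`
(`λ = c / F_c`), both set by the target range `d`.  A breathing subject's
chest wall moves 1–12 mm at 0.1–0.6 Hz, with a superposed heartbeat
component of 0.1–0.5 mm at 0.8–4.0 Hz; the micromotion rides on the phase,
which is what the chain recovers.

Default chirp parameters (`RadarParams`): bandwidth B = 4 GHz, N = 100
chirps/frame, chirp duration Tc = 50 µs, start frequency F_c = 77 GHz,
slow-time frame rate F_s = 20 Hz, ADC rate 2 MHz.  Derived quantities:
range resolution `d_res = c / 2B = 0.0375 m` and angular speed resolution
`Δω = 2π / N`.  The speed of light is taken as the radar convention
3×10⁸ m/s so `d_res` is exactly 3.75 cm.  The simulator renders one chirp
per frame: N only enters through Δω and has no effect on the slow-time
vital-sign chain.

## Synthetic chest motion

No public dataset accompanies this problem, so the generator *is* the
study condition:

* **Waveform.** Each breath is a raised cosine, `A/2 (1 − cos 2πt/T)` —
  smooth, unimodal, one peak/valley pair per cycle, baseline 0 (end of
  exhalation).  The analytic form of a real breath is not prescribed
  anywhere; the raised cosine matches the qualitative morphology of chest
  displacement and makes cycle counts analytically predictable.  Breathing
  segments are continuous cycle trains truncated at the segment boundary:
  a partial final cycle is kept (a subject does not freeze mid-record),
  and the *complete*-cycle count stays `floor(duration / T)`.
* **Protocols.**  normal: T = 3.3 s (≈18 breaths/min, inside the 16–20
  adult range); Biot: 30 s apnea then 30 s of 4 s cycles; tachypnea: 2 s
  cycles (30/min); bradypnea: 8 s cycles (7.5/min); Cheyne–Stokes:
  10 s apnea / 20 s linear crescendo / 20 s linear decrescendo / 10 s
  apnea (the ~20 s ramps quoted for this pattern cannot all be 20 s in a
  60 s record, so the bracketing apnea absorbs the remainder); apnea
  protocol: 20 s normal / 20 s apnea / 20 s normal.  Apnea segments are
  identically zero displacement and are recorded as ground-truth sample
  intervals.
* **Heartbeat and noise.**  A pure sinusoid (default 1.2 Hz, 0.3 mm) that
  persists through apnea, plus white Gaussian sensor noise (default
  σ = 0.1 mm for "realistic" traces).
* **Per-trace variation** (`random_trace`): amplitude uniform 3–9 mm,
  period jitter ±10%, heart rate 0.9–1.5 Hz at 0.1–0.5 mm — a coarse
  model of inter-subject spread.  All draws derive from a single seed.
* **Frame dropouts.**  Real acquisitions lose frames to interface faults;
  the lost frame appears as a point "mutation" in the demodulated signal.
  In the cube, a dropped frame is rendered at 10× amplitude with its phase
  flipped; at the trace level `inject_spikes` adds spikes of 10× the
  signal maximum.

What the generator does **not** emulate: respiratory-rate drift within a
record, body macro-movement, multiple reflectors/multipath, amplitude
asymmetry between inhale and exhale, heart-rate variability, or
colored/1-f sensor noise.  Tests passing on this corpus therefore show
the algorithms are implemented correctly and behave as designed under
idealized physiology, not that they reach any particular accuracy on
human subjects.

## Demodulation

Per-chirp FFT along fast time gives the range profile (bin spacing
`d_res`); the bin with the largest mean magnitude is selected, its phase
is unwrapped across slow time, and displacement follows as
`d = φ λ / 4π`.  Respiration and heart channels are separated with
4th-order Butterworth bandpass filters (0.1–0.6 Hz, 0.8–4.0 Hz) applied
forward and backward (`sosfiltfilt`), so the filters are zero-phase and
transients are suppressed.  Absolute unwrapped phase is the default; a
first-difference mode is available.

**Dropout handling.**  Mutations are flagged by a robust rule: a sample
whose deviation from the median of its four nearest neighbours exceeds
6× their median absolute deviation.  Flagged samples are replaced by the
mean of the nearest clean left/right neighbours (single neighbour at
boundaries; length preserved so truth annotations stay aligned).  In the
cube chain the detection runs on the selected bin's *magnitude* series
before unwrapping: a corrupted frame's phase excursion wraps, and
`np.unwrap` converts it into a permanent ±2π step rather than a spike,
so the phase series alone cannot reveal it afterwards.  The complex bin
sample is repaired first and the phase is unwrapped clean; a residual
phase-domain pass catches anything left.

**Rates.**  Three estimators run per channel — zero-padded
Hann-windowed FFT peak, autocorrelation first-peak, and mean
peak-to-peak interval — each restricted to its band and each with a
confidence in [0, 1] (spectral peak mass fraction, autocorrelation peak
height, 1 − CV of intervals respectively; none of these is prescribed
anywhere, any monotone-in-SNR surrogate serves).  The estimate of the
highest-confidence method is reported; flat or out-of-band signals give
(0, 0), marking a damaged segment.

## Apnea judgment

Segment energy `E(i) = Σ x²` over a rectangular window, default 80
samples (4 s) with hop 5 (0.25 s, ~225 judgment points per minute).  A
4 s window spans at least one breath cycle, so normal-breathing energy
does not dip at within-cycle zero crossings; a 1 s window flickers.
Threshold `D(n)` is half a reference energy: the first segment's energy
at n = 1, the running mean of all segments for n < 5, and the mean of the
*first five* segments thereafter — i.e. the detector locks onto the
initial normal-breathing level.  A trailing-window variant
(`mode="trailing"`, last five segments including the current) is provided
for completeness but collapses to D → 0 during sustained apnea, making a
60-point apnea run undetectable; the anchored form is what reproduces the
expected sustained judgment.  Consequence of anchoring: the record must
*begin* with normal breathing (true for the normal–apnea–normal
protocol); a record that opens with apnea (Biot) has a near-zero
reference and its leading apnea is not detectable by this rule.

Output is 1 where `E < D` (ties are "not lower" → 0).  Runs of 1s
shorter than 3 segments are discarded as flicker.  Detection accuracy of
an interval against truth is `100 · |detected ∩ actual| / |actual|`
with interval length `stop − start`, reported to one decimal.  Joint
judgment lets respiration dominate (its judgment is more reliable) and
uses the heart channel as confirmation: `confirmed = resp AND heart`.

## Pattern features

1. **VPD peak screening.**  Smooth with a three-point moving average
   applied forward and backward; find all local extrema (a record opening
   on a rising slope counts its first sample as the opening trough);
   discard peaks before the first valley; compute the valley-to-peak
   difference `VPD(k) = P(k) − V(k)` and delete every peak with
   `VPD(k) < 0.7 · mean(VPD(k−1), VPD(k), VPD(k+1))` (edge terms
   replicated); iterate until the peak count is stable.  The count is
   non-increasing, so termination is guaranteed.  `V(k)` is the deepest
   valley between the previous surviving peak and peak k — pairing with
   the *nearest* preceding valley instead would let a shallow noise dip
   on a crest become a true peak's reference and delete it.  Valleys are
   never deleted; with noise the valley count therefore exceeds the peak
   count, and the difference `n_valleys − n_peaks` is itself the third
   count feature.
2. **Normalized short-term energy.**  Scale by the maximum absolute
   value, map affinely onto exactly [−1, 1], then sum squares over
   non-overlapping 4 s rectangular windows (N = 80 at 20 Hz).  Mean and
   standard deviation summarise level and spread; apnea-bearing patterns
   have near-zero windows and ramps, hence much larger spread.
3. **Instantaneous frequency.**  Hilbert analytic signal of the demeaned
   respiration channel (no empirical-mode decomposition — the transform
   is applied directly to the band-limited signal); instantaneous
   frequency is the unwrapped-phase derivative (central differences) in
   Hz, clipped below at 0.  Summaries use the interior 95% of samples to
   exclude transform edge distortion.  The minimum is ~0 exactly for
   patterns with apnea plateaus (phase stalls), and the mean orders the
   steady patterns by breathing rate.

Features are extracted from the respiration-band channel
(`featurize_trace`), not the raw trace: band limiting removes most
wide-band noise power, which would otherwise dominate the
instantaneous-frequency derivative.

## Classification

RBF-kernel SVM (C = 1, gamma = 'scale', one-vs-one) and KNN (k = 5,
Euclidean), both behind a train-statistics z-scoring step; kernel and k
were not prescribed, so conventional defaults are used and configurable.
Evaluation: stratified 10-fold CV or a stratified 50/50 holdout;
confusion matrices are rows = true / columns = predicted (declared in
every output header); Cohen's kappa is computed from its closed form
`(p_o − p_e)/(1 − p_e)` with product-of-marginals `p_e`, and is
cross-checked against scikit-learn in the tests.

## Numerical choices and degenerate inputs

* Constant signals: no extrema (empty peak set), rejected by
  normalization and instantaneous frequency (zero range / zero signal).
* Mutation detector uses a tiny absolute floor (10⁻⁹ × signal scale) so
  exactly-constant neighbourhoods do not flag on rounding noise.
* Rate estimation needs at least two cycles of the band's low edge.
* The judgment tie `E == D` outputs 0 (apnea must be *lower*).
* Sample-to-segment truth mapping keeps only segments whose windows lie
  entirely inside the truth interval.
* All random stages accept explicit seeds; the pipeline derives per-stage
  substreams from one run seed via SHA-256 (all below 2³¹).

## Problem sizes

Test-suite defaults: 60 s records at 20 Hz (1200 samples), IF cubes of
100×1200 complex samples, 10–50 seeds for parameter-recovery and
peak-screening suites, 20 seeds per pattern for feature signatures, and a
scaled classification benchmark of 5×160 traces split 50/50 with 10 split
replicates.  These sizes keep the whole suite under a minute while the
stochastic checks still average over enough seeds to be stable.

## Known limitations

* The synthetic corpus separates the five patterns almost perfectly, so
  benchmark accuracies near 100% say nothing about accuracy on real
  subjects; the benchmark is a lower-bound sanity check, not a clinical
  claim.
* The anchored apnea threshold assumes the record opens with breathing.
* Phase unwrapping limits the product (amplitude × frequency): at 20 Hz
  a 12 mm, 0.6 Hz breath approaches the π-per-sample bound and can alias.
* No multi-target or motion-artifact rejection beyond the energy rule.
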