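"""Generate chest-displacement traces for the five breathing patterns.

Each pattern is rendered as a raised-cosine breath train (60 s at 20 Hz)
with its protocol's period and apnea phases, then a heartbeat and sensor
noise are superposed.  The printed numbers are the per-pattern breath
period, the number of complete cycles, and the annotated apnea intervals
in seconds — the ground truth every downstream stage is judged against.
"""
import vitalwave as vw

for pattern in list(vw.PATTERN_LABELS) + [vw.Pattern.APNEA_PROTOCOL]:
    spec = vw.PatternSpec.default(pattern)
    trace = vw.generate_pattern(spec)
    trace = vw.add_noise(vw.add_heartbeat(trace, 1.2, 0.3, seed=0), 0.1, seed=1)
    apnea_s = [
        (start / trace.sampling_rate, stop / trace.sampling_rate)
        for start, stop in trace.truth_apnea_intervals
    ]
    breathing_s = sum(dur for kind, dur in spec.phase_schedule if kind != "apnea")
    print(
        f"{spec.pattern.value:15s} period {spec.cycle_period_s:4.1f} s  "
        f"complete cycles {int(breathing_s // spec.cycle_period_s):2d}  apnea {apnea_s or '-'}"
    )
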