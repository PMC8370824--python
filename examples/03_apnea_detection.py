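"""Detect an apnea episode with the windowed-energy adaptive threshold.

The protocol is 20 s normal breathing, 20 s apnea, 20 s normal breathing.
Segment energies (4 s rectangular window, 0.25 s hop) are compared with a
threshold at half the initial normal-breathing energy; runs of
below-threshold segments become apnea intervals.  The printed accuracy is
the overlap of the detected interval with the ground-truth interval as a
percentage of the truth length.
"""
import vitalwave as vw

trace = vw.random_trace("apnea_protocol", seed=11)
vitals = vw.bandpass_separate(trace.samples, trace.sampling_rate)

judgment, intervals = vw.apnea_judgment(vitals.respiration, window=80, hop=5)
truth = vw.samples_to_segments(trace.truth_apnea_intervals[0], window=80, hop=5)

print(f"judgment points       {len(judgment.energies_e)}")
print(f"truth segments        ({truth.start}, {truth.stop})")
for iv in intervals:
    acc = vw.detection_accuracy(iv, truth)
    print(f"detected segments     ({iv.start}, {iv.stop})  accuracy {acc:.1f}%")
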