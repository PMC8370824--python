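"""Extract the 8-dimensional pattern descriptor from each breathing pattern.

For one seeded trace per pattern the respiration band is isolated and the
three feature families are computed: VPD-screened peak/valley counts and
their difference, normalized short-term energy mean/std (4 s windows),
and Hilbert instantaneous-frequency mean/std/min.  Note the signatures:
tachypnea's frequency mean is the highest, bradypnea's the lowest, and
only the apnea-bearing patterns (Biot, Cheyne-Stokes) reach an
instantaneous-frequency minimum of 0.
"""
import vitalwave as vw

header = f"{'pattern':15s}" + "".join(f"{n:>10s}" for n in vw.FEATURE_NAMES)
print(header)
for pattern in vw.PATTERN_LABELS:
    fv = vw.featurize_trace(vw.random_trace(pattern, seed=3))
    row = f"{pattern.value:15s}"
    for v in fv.as_array():
        row += f"{v:10.2f}"
    print(row)
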