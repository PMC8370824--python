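import numpy as np
import pytest
from hypothesis import settings

import vitalwave as vw

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")

FS = 20.0


@pytest.fixture(scope="session")
def radar_params():
    return vw.RadarParams()


@pytest.fixture(scope="session")
def tachypnea_trace():
    return vw.generate_pattern(vw.PatternSpec.default("tachypnea"), sampling_rate=FS)


@pytest.fixture(scope="session")
def apnea_protocol_trace():
    return vw.generate_pattern(vw.PatternSpec.default("apnea_protocol"), sampling_rate=FS)


@pytest.fixture(scope="session")
def periodic_spec():
    """Pure 4 s-cycle breathing (15 cycles in 60 s), no apnea phases."""
    return vw.PatternSpec(
        pattern=vw.Pattern.NORMAL,
        duration_s=60.0,
        breath_amplitude_mm=6.0,
        cycle_period_s=4.0,
        phase_schedule=(("breathe", 60.0),),
    )


@pytest.fixture(scope="session")
def pattern_features():
    """20 seeded feature vectors per pattern from the standard protocols."""
    out = {}
    for pattern in vw.PATTERN_LABELS:
        rows = [
            vw.featurize_trace(vw.random_trace(pattern, seed=1000 + s)).as_array()
            for s in range(20)
        ]
        out[pattern] = np.array(rows)
    return out
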