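import numpy as np
import pytest

import eskin_lpm as el
from eskin_lpm.synthetic import SessionScript, default_profiles


@pytest.fixture(scope="session")
def flexion_script() -> SessionScript:
    return SessionScript(profiles=[default_profiles()[el.Movement.FLEXION]])


@pytest.fixture(scope="session")
def flexion_session(flexion_script) -> el.SyntheticSession:
    """15-repetition flexion session under default study conditions."""
    return el.generate_session(flexion_script, seed=42)


@pytest.fixture(scope="session")
def flexion_aligned(flexion_session) -> el.AlignedPair:
    return el.preprocess_session(
        flexion_session.eskin_streams, flexion_session.angle_stream
    )


def noiseless_session(movement: el.Movement, *, reps_per_set=5, n_sets=3,
                      seed=3, **kwargs) -> el.SyntheticSession:
    """Idealised session: no noise, no drift, no quantisation, no lead."""
    script = SessionScript(
        profiles=[default_profiles()[movement]], reps_per_set=reps_per_set, n_sets=n_sets
    )
    sensor = el.StrainSensorParams(r0=1400.0, drift_per_rep=0.0)
    defaults = dict(
        noise_sd_adu=0.0,
        angle_noise_sd_deg=0.0,
        onset_lead_s=0.0,
        quantize=False,
        angle_rate_hz=15.0,
    )
    defaults.update(kwargs)
    return el.generate_session(script, sensor=sensor, seed=seed, **defaults)
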