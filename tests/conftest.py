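import numpy as np
import pytest

import semgpipe as sp


@pytest.fixture(scope="session")
def protocol():
    return sp.build_protocol({})


@pytest.fixture(scope="session")
def signatures():
    return sp.default_signatures()


@pytest.fixture(scope="session")
def participant_recordings(protocol, signatures):
    """One full simulated participant: 6 actions x 5 sessions."""
    return sp.simulate_participant(protocol, signatures, "P01", 42)


@pytest.fixture(scope="session")
def participant_segments(protocol, participant_recordings):
    return [seg for rec in participant_recordings
            for seg in sp.segment_recording(rec, protocol)]


@pytest.fixture(scope="session")
def participant_table(participant_segments):
    """300-row, 12-feature labelled table for one simulated participant."""
    return sp.build_feature_table(participant_segments)


def brute_force_features(v):
    """Independent plain-loop implementation of the six channel features."""
    v = [abs(float(x)) for x in v]
    n = len(v)
    mean = sum(v) / n
    vmax = v[0]
    vmin = v[0]
    for x in v:
        if x > vmax:
            vmax = x
        if x < vmin:
            vmin = x
    ss = sum((x - mean) ** 2 for x in v)
    sd = (ss / (n - 1)) ** 0.5 if n > 1 else 0.0
    m2 = ss / n
    m3 = sum((x - mean) ** 3 for x in v) / n
    m4 = sum((x - mean) ** 4 for x in v) / n
    if m2 == 0:
        skew = kurt = 0.0
    else:
        skew = m3 / m2 ** 1.5
        kurt = m4 / m2 ** 2
    return {"v_mean": mean, "v_max": vmax, "v_min": vmin, "v_sd": sd,
            "skew": skew, "kurt": kurt}


def make_segment(med, lat, fs=1111.0, action="HO", rep=0):
    """Build an EnvelopeSegment directly from sample arrays."""
    return sp.EnvelopeSegment(
        medial_env_uV=np.asarray(med, dtype=float),
        lateral_env_uV=np.asarray(lat, dtype=float),
        sampling_rate_hz=fs, action=action, participant_id="T",
        session_id="s0", rep_index=rep, center_time_s=1.0)
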