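import numpy as np
import pytest

import cervitrack as ct


@pytest.fixture(scope="session")
def rig_flexion():
    """Noise-free 34 deg flexion rig trial (stream + ground truth)."""
    return ct.simulate_rig_trial(
        ct.RigTrialSpec(plane="flexion_extension", angle_deg=34.0)
    )


@pytest.fixture(scope="session")
def clean_session():
    """Noise-free default six-movement protocol session."""
    cfg = ct.default_protocol(seed=0, noise_sd_deg=0.0)
    return ct.simulate_protocol(cfg)


@pytest.fixture(scope="session")
def clean_analysis(clean_session):
    stream, gt = clean_session
    return ct.analyze_stream(stream), gt


@pytest.fixture()
def constant_stream():
    """Two seconds of a fixed non-identity orientation at 60 Hz."""
    q = ct.compose_from_angles(ct.AnatomicalAngles(5.0, -3.0, 10.0))
    t = np.arange(120) / 60.0
    quat = np.tile([q.w, q.x, q.y, q.z], (120, 1))
    return ct.PoseStream(t=t, quat_wxyz=quat, nominal_rate=60.0)
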