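import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from extrande import InputTrajectory, TwoStageParams, build_two_stage_model


@pytest.fixture
def two_stage_net():
    """Small two-stage fixture: ks=2, kdm=3, kdp=0.5 (per hour)."""
    return build_two_stage_model(TwoStageParams(ks=2.0, kdm=3.0, kdp=0.5))


@pytest.fixture
def step_traj():
    """Three-point step trajectory: values (1, 3, 2) on grid (0, 1, 2)."""
    return InputTrajectory(np.array([0.0, 1.0, 2.0]), np.array([1.0, 3.0, 2.0]))
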