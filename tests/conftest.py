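import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def dh_table():
    from limbmanip.arm_kinematics import default_dh_table

    return default_dh_table()


@pytest.fixture
def random_pose_factory(rng):
    """Poses with a clearly bent elbow (away from the extended-arm
    singularity) unless full=True asks for the whole joint range."""
    from limbmanip.arm_kinematics import ArmPose

    def make(full: bool = False):
        q = rng.uniform(-1.3, 1.3, size=6)
        if not full:
            q[3] = rng.uniform(0.3, 2.4)
        return ArmPose.from_array(q)

    return make
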