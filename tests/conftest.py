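import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def profiles():
    from windbat.species import default_profiles

    return default_profiles()


@pytest.fixture(scope="session")
def study_rig():
    from windbat.stereo import StereoRig

    return StereoRig.facing()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
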