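import pytest
from hypothesis import HealthCheck, settings

from probcoherence import build_battery, uniform_world

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def battery_t1():
    return build_battery("T1", seed=1)


@pytest.fixture(scope="session")
def battery_t2():
    return build_battery("T2", seed=2)


@pytest.fixture(scope="session")
def world_t1_uniform():
    return uniform_world("T1")
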