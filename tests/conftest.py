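import pytest
from hypothesis import HealthCheck, settings

from redoxkin import ThresholdPolicy, builtin_registry

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    return builtin_registry()


@pytest.fixture(scope="session")
def policy():
    return ThresholdPolicy()
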