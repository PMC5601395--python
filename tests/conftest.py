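import pytest
from hypothesis import HealthCheck, settings

from atheroqsp import AtheroParams, PKPDParams, default_params
from atheroqsp.params import EngineSettings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def athero() -> AtheroParams:
    return default_params()[0]


@pytest.fixture(scope="session")
def pkpd() -> PKPDParams:
    return default_params()[1]


@pytest.fixture(scope="session")
def fast_settings() -> EngineSettings:
    """Looser tolerances for tests that only need qualitative trajectories."""
    return EngineSettings(rtol=1e-6, atol=1e-9)
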