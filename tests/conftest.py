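import pytest
from hypothesis import HealthCheck, settings

import selexa as sx

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def design():
    return sx.aurora_design()


@pytest.fixture(scope="session")
def fixture_config():
    return sx.aurora_fixture_config()


@pytest.fixture(scope="session")
def pair_model():
    """Fixture fitness model planting only the four base-pair constraints."""
    return sx.aurora_fitness_model(include_conserved=False)


@pytest.fixture(scope="session")
def full_model():
    """Fixture fitness model with pairs plus conserved blocks."""
    return sx.aurora_fitness_model()
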