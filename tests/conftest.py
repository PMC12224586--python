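import pytest
from hypothesis import HealthCheck, settings

from pmslt.engine import prepare_inputs
from pmslt.exposure import default_scenarios
from pmslt.synthetic import generate_inputs

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def synthetic_inputs():
    """The default synthetic input bundle (seed 1)."""
    return generate_inputs(seed=1)


@pytest.fixture(scope="session")
def model_inputs(synthetic_inputs):
    """Preprocessed 1-year model inputs for the default bundle."""
    return prepare_inputs(synthetic_inputs)


@pytest.fixture(scope="session")
def scenario_map():
    """The ten shipped scenarios keyed by id."""
    return {s.id: s for s in default_scenarios()}
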