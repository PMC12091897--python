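import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def weak_dc_params():
    """The weak-DC baseline stimulus used throughout the sensitivity study."""
    from prfield import ModelParams
    return ModelParams(Is=0.0, Id=1.0)


@pytest.fixture(scope="session")
def fixture_traces():
    from prfield import make_fixture_traces
    return make_fixture_traces()


@pytest.fixture(scope="session")
def default_trace(weak_dc_params):
    """One full-length simulation of the baseline bursting configuration."""
    from prfield import FieldConfig, simulate
    return simulate(weak_dc_params, FieldConfig(0.0))


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
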