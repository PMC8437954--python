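import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20210913)


@pytest.fixture(scope="session")
def default_elastic():
    from dynhelix.elastic import FilamentElasticParams

    return FilamentElasticParams()


@pytest.fixture(scope="session")
def default_membrane():
    from dynhelix.membrane import MembraneParams

    return MembraneParams()
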