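import numpy as np
import pytest

from promix.photo import AllocationParams, PHOTOPHYS_PRESETS, diel_irradiance_factors
from promix.synth import SyntheticSpec, make_environment


@pytest.fixture(scope="session")
def alloc():
    return AllocationParams()


@pytest.fixture(scope="session")
def hl_params():
    return PHOTOPHYS_PRESETS["HL"]


@pytest.fixture(scope="session")
def ll_params():
    return PHOTOPHYS_PRESETS["LL"]


@pytest.fixture(scope="session")
def diel():
    """Subtropical mid-summer diel cycle used throughout the fixtures."""
    return diel_irradiance_factors(22.75, 190)


@pytest.fixture(scope="session")
def synth_spec():
    return SyntheticSpec(seed=11)


@pytest.fixture(scope="session")
def synth_env(synth_spec):
    return make_environment(synth_spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
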