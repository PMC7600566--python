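import pytest

from selpbpk.engine import CompoundModelSet
from selpbpk.populations import mean_individual, population_presets


@pytest.fixture(scope="session")
def model():
    return CompoundModelSet()


@pytest.fixture(scope="session")
def presets():
    return population_presets()


@pytest.fixture(scope="session")
def healthy_subject(presets):
    return mean_individual(presets["healthy"])
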