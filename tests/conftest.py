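import pytest

from chemocal import ToyModelSpec, make_toy_model
from chemocal import datasets


@pytest.fixture(scope="session")
def toy_spec():
    return ToyModelSpec()


@pytest.fixture()
def toy_model(toy_spec):
    return make_toy_model(toy_spec)


@pytest.fixture(scope="session")
def glycerol_rates():
    return datasets.load_rates("glycerol")


@pytest.fixture(scope="session")
def methanol_rates():
    return datasets.load_rates("methanol")


@pytest.fixture(scope="session")
def glycerol_biomass():
    return datasets.biomass_constants("glycerol")


@pytest.fixture(scope="session")
def methanol_biomass():
    return datasets.biomass_constants("methanol")
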