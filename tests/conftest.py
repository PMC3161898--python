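import pytest

from petrirec.assembly import build_catalog
from petrirec.fixtures import phosphate_regulon, toy_example, water_net
from petrirec.timeseries import compile_state_matrix


@pytest.fixture(scope="session")
def water():
    return water_net()


@pytest.fixture(scope="session")
def toy():
    return toy_example()


@pytest.fixture(scope="session")
def toy_sm(toy):
    return compile_state_matrix(toy.experiments, components=toy.expected["components"])


@pytest.fixture(scope="session")
def toy_catalog(toy_sm):
    return build_catalog(toy_sm)


@pytest.fixture(scope="session")
def phosphate():
    return phosphate_regulon()


@pytest.fixture(scope="session")
def phosphate_sm(phosphate):
    return compile_state_matrix(
        phosphate.experiments, components=phosphate.expected["components"]
    )


@pytest.fixture(scope="session")
def phosphate_catalog(phosphate_sm):
    return build_catalog(phosphate_sm)
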