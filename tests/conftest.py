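import pytest

from pedispine.config import default_config
from pedispine.vertebra import build_vertebra
from pedispine.disc import build_disc
from pedispine.spine import assemble_spine


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def vertebra_l3():
    """Default L3 vertebra per age group (built once per session)."""
    return {g: build_vertebra(g, "L3") for g in range(1, 6)}


@pytest.fixture(scope="session")
def newborn_vertebra(vertebra_l3):
    return vertebra_l3[1]


@pytest.fixture(scope="session")
def newborn_disc():
    return build_disc(1, "L3/4")


@pytest.fixture(scope="session")
def newborn_spine():
    return assemble_spine(1)


@pytest.fixture(scope="session")
def preadolescent_spine():
    return assemble_spine(5)
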