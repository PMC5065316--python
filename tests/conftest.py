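import numpy as np
import pytest

from npckinetics.config import RunConfig
from npckinetics.growth import PRINTED_GROWTH
from npckinetics.maturation import densities_from_samples
from npckinetics.table_io import load_table1_fixture


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def core_densities(table1):
    """Inner/outer-core density time courses (19.2-116 min)."""
    return densities_from_samples(table1)


@pytest.fixture(scope="session")
def config():
    return RunConfig()


@pytest.fixture(scope="session")
def growth_params():
    return PRINTED_GROWTH
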