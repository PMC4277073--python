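import pytest

from bioisru import bioreactor_catalog as brc
from bioisru import mission_resources as mr
from bioisru import stoichiometry as st


@pytest.fixture(scope="session")
def catalog():
    return brc.load_catalog()


@pytest.fixture(scope="session")
def waste_streams():
    return mr.load_waste_streams()


@pytest.fixture(scope="session")
def inventories():
    return mr.load_environment_inventories()


@pytest.fixture(scope="session")
def reactions():
    return st.load_reactions()
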