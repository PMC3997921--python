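import pytest

from fragnet.chem_io import parse_structure
from fragnet.fingerprints import KeyLibrary
from fragnet.fixtures import default_oracle, make_toy_library

NITRONAPHTHALENE = "O=[N+]([O-])c1cccc2ccccc12"
AMINONITROBENZOIC = "Nc1cccc([N+](=O)[O-])c1C(=O)O"  # 2-amino-6-nitrobenzoic acid


@pytest.fixture(scope="session")
def key_library():
    return KeyLibrary.default()


@pytest.fixture(scope="session")
def oracle():
    return default_oracle()


@pytest.fixture(scope="session")
def toy_library():
    return make_toy_library(n=40, seed=1)


@pytest.fixture
def benzene():
    return parse_structure("c1ccccc1", "benzene")


@pytest.fixture
def nitronaphthalene():
    return parse_structure(NITRONAPHTHALENE, "1-nitronaphthalene")


@pytest.fixture
def aminonitrobenzoic():
    return parse_structure(AMINONITROBENZOIC, "2-amino-6-nitrobenzoic acid")
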