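import pytest

from rnamotifs.folding import NussinovEngine, ViennaEngine
from rnamotifs.structure_core import enumerate_structures


@pytest.fixture(scope="session")
def nussinov():
    return NussinovEngine()


@pytest.fixture(scope="session")
def vienna():
    return ViennaEngine()


@pytest.fixture(scope="session")
def enumeration_to_14():
    """Every valid dot-bracket (min hairpin 3) for each length 1..14."""
    return [db for L in range(1, 15) for db in enumerate_structures(L)]
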