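import sys
from pathlib import Path

import pytest

from bdmseed import IncompatibilityModel

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable


@pytest.fixture(scope="session")
def m1p3():
    """The model favoured by the segregation data: one maternal, three
    paternal loci."""
    return IncompatibilityModel(n_maternal_loci=1, n_paternal_loci=3)


@pytest.fixture(scope="session")
def m1p2():
    """The competing model with two paternal loci."""
    return IncompatibilityModel(n_maternal_loci=1, n_paternal_loci=2)


@pytest.fixture(scope="session")
def m1p1():
    return IncompatibilityModel(n_maternal_loci=1, n_paternal_loci=1)
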