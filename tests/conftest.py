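import pytest

from mitodui.data import solenaia_fixture_pair
from mitodui.genome import GeneFeature, MitoGenome


@pytest.fixture(scope="session")
def fixture_pair():
    """The packaged synthetic F-like/M-like genome pair."""
    return solenaia_fixture_pair()


@pytest.fixture(scope="session")
def f_genome(fixture_pair):
    return fixture_pair[0]


@pytest.fixture(scope="session")
def m_genome(fixture_pair):
    return fixture_pair[1]


def toy_genome(length=100, features=(), identifier="toy", seq=None):
    if seq is None:
        # deterministic filler with all four bases present
        seq = ("ACGT" * (length // 4 + 1))[:length]
    return MitoGenome(identifier, seq, list(features))


@pytest.fixture
def two_gene_circle():
    """100 bp circle with genes at [0,40) and [50,90)."""
    return toy_genome(100, [
        GeneFeature("g1", "PCG", 0, 40, 1),
        GeneFeature("g2", "PCG", 50, 90, 1),
    ])
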