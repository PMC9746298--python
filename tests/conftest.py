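import pytest

from rgptyper.fixtures import FixtureSpec, generate_locus
from rgptyper.scheme_db import load_scheme

ALL_GENOTYPES = ("1", "2", "2A", "3", "4", "5", "6", "7")


@pytest.fixture(scope="session")
def scheme():
    return load_scheme()


@pytest.fixture(scope="session")
def fixture_map(scheme):
    """One seed-1 fixture genome per genotype (shared across tests)."""
    return {
        g: generate_locus(FixtureSpec(genotype=g, seed=1), scheme=scheme)
        for g in ALL_GENOTYPES
    }
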