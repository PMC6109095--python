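import numpy as np
import pytest

from navvar.enumeration import enumerate_missense
from navvar.synthetic import synthetic_reference
from navvar.topology import ProteinTopology, Region


@pytest.fixture(scope="session")
def topology():
    return ProteinTopology.default()


@pytest.fixture(scope="session")
def toy_cds():
    """Small stop-free CDS (30 codons), fixed seed."""
    return synthetic_reference(length=30, seed=11)


@pytest.fixture(scope="session")
def toy_census(toy_cds):
    return enumerate_missense(toy_cds)


@pytest.fixture(scope="session")
def full_census():
    """Census of a synthetic full-length (2016 codon) reference."""
    return enumerate_missense(synthetic_reference(2016))


def make_two_region_topology():
    """Minimal valid-enough toy: two termini tiling 1..40 (only the fields
    the density/tally code touches are meaningful)."""
    return ProteinTopology(40, [
        Region("N", "terminus", 0, 0, 1, 10, "cytoplasmic"),
        Region("C", "terminus", 0, 0, 11, 40, "cytoplasmic"),
    ])


@pytest.fixture
def two_region_topology():
    return make_two_region_topology()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
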