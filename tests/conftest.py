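import pytest

from retrojoin.align import GenomeIndex
from retrojoin.classify import reference_index
from retrojoin.refs import build_reference_set


@pytest.fixture(scope="session")
def refset():
    return build_reference_set(1)


@pytest.fixture(scope="session")
def ref_index(refset):
    """Seeded index over every alignment reference."""
    return reference_index(refset)


@pytest.fixture(scope="session")
def genome_index(refset):
    """Seeded index over the genome only (PolyA-seq alignment)."""
    return GenomeIndex(refset.genome)
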