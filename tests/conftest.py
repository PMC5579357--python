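import numpy as np
import pytest

from phyloprof import PhyloProfile, SpeciesCatalog, SpeciesTree

CODES4 = ("Aaaa", "Bbbb", "Cccc", "Dddd")


@pytest.fixture
def catalog4() -> SpeciesCatalog:
    return SpeciesCatalog(CODES4)


@pytest.fixture
def tree4() -> SpeciesTree:
    return SpeciesTree.from_newick("((Aaaa,Bbbb),(Cccc,Dddd));")


@pytest.fixture
def profile_factory():
    """Build a single-copy profile from a 0/1 vector (default 4-species catalog)."""

    def make(name: str, presence, codes=CODES4) -> PhyloProfile:
        return PhyloProfile.from_presence(name, codes, np.asarray(presence))

    return make
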