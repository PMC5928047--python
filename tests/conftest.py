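import pytest

from genecontent import SpeciesTree


@pytest.fixture
def tree4() -> SpeciesTree:
    """((A,B)M,(C,D)O)R — the minimal two-clade fixture."""
    return SpeciesTree.from_newick("((A,B)M,(C,D)O)R;")


@pytest.fixture
def tree5() -> SpeciesTree:
    """(((A,B)M,(C,D)O)P,E)R — two clades plus an outgroup leaf."""
    return SpeciesTree.from_newick("(((A,B)M,(C,D)O)P,E)R;")


@pytest.fixture
def caterpillar6() -> SpeciesTree:
    return SpeciesTree.from_newick("(((((A,B)N4,C)N3,D)N2,E)N1,F)R;")


@pytest.fixture
def balanced6() -> SpeciesTree:
    return SpeciesTree.from_newick("(((A,B)I1,(C,D)I2)I5,(E,F)I6)R;")
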