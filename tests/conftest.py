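import numpy as np
import pytest

from phyloselect.alignments import CodonAlignment, ProteinAlignment
from phyloselect.simulate import mammal_tree
from phyloselect.trees import PhyloTree


@pytest.fixture(scope="session")
def quartet_trees():
    t1 = PhyloTree.from_newick("((A:0.1,B:0.1):0.05,(C:0.1,D:0.1):0.05);")
    t2 = PhyloTree.from_newick("((A:0.1,C:0.1):0.05,(B:0.1,D:0.1):0.05);")
    return t1, t2


@pytest.fixture(scope="session")
def mammal12():
    return mammal_tree()


@pytest.fixture(scope="session")
def taxa8():
    return ["Human", "Chimp", "Macaque", "Mouse", "Rat", "Dog", "Cow",
            "Opossum"]


@pytest.fixture
def tiny_protein():
    return ProteinAlignment(["t1", "t2", "t3"], ["MAR", "MAK", "M-R"])


@pytest.fixture
def tiny_codon():
    return CodonAlignment(
        ["t1", "t2", "t3"],
        ["ATGGCTCGT", "ATGGCTAAA", "ATG---CGT"])
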