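import io

import numpy as np
import pytest

from parevol import synthetic_data as syn
from parevol.core_io import read_timed_tree

BALANCED_8 = (
    "(((a_2000:0.3,b_2000:0.3):0.15,(c_2000:0.3,d_2000:0.3):0.15):0.075,"
    "((e_2000:0.3,f_2000:0.3):0.15,(g_2000:0.3,h_2000:0.3):0.15):0.475);"
)


@pytest.fixture(scope="session")
def balanced_codon_tree():
    """8-taxon tree with branch lengths in substitutions/codon; the long
    internal branch above (e,f,g,h) serves as the selection foreground."""
    return read_timed_tree(io.StringIO(BALANCED_8))


@pytest.fixture(scope="session")
def foreground_branch(balanced_codon_tree):
    from parevol._phylo import IndexedTree

    itree = IndexedTree.from_timed_tree(balanced_codon_tree)
    return itree, {itree.mrca(["e_2000", "f_2000", "g_2000", "h_2000"])}


@pytest.fixture(scope="session")
def het_tree():
    """Heterochronous 20-tip coalescent time tree."""
    return syn.simulate_timed_tree(n_taxa=20, seed=11, sampling_window=100,
                                   pop_size=40)


def make_tree(n_taxa=12, seed=0, isochronous=True, pop_size=30):
    return syn.simulate_timed_tree(n_taxa=n_taxa, seed=seed,
                                   isochronous=isochronous, pop_size=pop_size)
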