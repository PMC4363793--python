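import numpy as np
import pytest

from ontopart.matrix_io import CharacterMatrix
from ontopart.ontology import PartitionScheme
from ontopart.synthetic_data import scarabaeinae_graph
from ontopart.trees import PhyloTree


@pytest.fixture(scope="session")
def scarab_graph():
    return scarabaeinae_graph()


@pytest.fixture
def three_taxon_tree():
    return PhyloTree.from_newick("((A:0.1,B:0.2):0.15,C:0.3);")


@pytest.fixture
def abcd_matrix():
    """4-taxon matrix: one clean character, one conflicting."""
    return CharacterMatrix(
        taxa=["A", "B", "C", "D"],
        data=[
            [frozenset({0}), frozenset({0})],
            [frozenset({0}), frozenset({1})],
            [frozenset({1}), frozenset({0})],
            [frozenset({1}), frozenset({1})],
        ],
    )


def single_block_scheme(matrix) -> PartitionScheme:
    return PartitionScheme(id="1", blocks=(("all", frozenset(matrix.char_ids)),))


def random_binary_matrix(n_taxa, n_char, seed, n_states=2):
    rng = np.random.default_rng(seed)
    taxa = [f"t{i}" for i in range(n_taxa)]
    data = [
        [frozenset({int(rng.integers(n_states))}) for _ in range(n_char)]
        for _ in taxa
    ]
    return CharacterMatrix(taxa=taxa, data=data)
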