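"""Fitch scoring, implied weights, search, statistics, instability."""

import itertools

import numpy as np
import pytest

from ontopart.errors import OntopartError
from ontopart.matrix_io import CharacterMatrix
from ontopart.parsimony import (
    ParsimonyConfig,
    all_unrooted_topologies,
    exhaustive_search,
    fitch_length,
    heuristic_search,
    implied_weights_score,
    instability_profile,
    leaf_stability,
    tree_stats,
)
from ontopart.trees import PhyloTree

from conftest import random_binary_matrix


# -- independent oracle: minimize over all internal labelings -------------


def brute_force_length(tree, matrix):
    internals = [n for n in tree.postorder() if not n.is_leaf]
    total = 0
    for j in range(matrix.n_char):
        cell_of = dict(zip(matrix.taxa, matrix.column(j)))
        best = None
        leaf_choices = {
            t: sorted(c) if c is not None else [0, 1, 2]
            for t, c in cell_of.items()
        }
        for assignment in itertools.product([0, 1, 2], repeat=len(internals)):
            labels = {id(n): s for n, s in zip(internals, assignment)}
            for leaves in itertools.product(
                *(leaf_choices[t] for t in matrix.taxa)
            ):
                leaf_labels = dict(zip(matrix.taxa, leaves))
                changes = 0
                for node in tree.postorder():
                    if node.parent is None:
                        continue
                    a = (
                        leaf_labels[node.taxon]
                        if node.is_leaf
                        else labels[id(node)]
                    )
                    b = labels[id(node.parent)]
                    changes += a != b
                if best is None or changes < best:
                    best = changes
        total += best
    return total


def test_constant_character_costs_zero():
    tree = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
    m = CharacterMatrix(taxa=list("ABCD"), data=[[frozenset({1})]] * 4)
    assert fitch_length(tree, m)[0] == 0


def test_informative_character_on_two_topologies():
    m = CharacterMatrix(
        taxa=list("ABCD"),
        data=[[frozenset({0})], [frozenset({0})], [frozenset({1})], [frozenset({1})]],
    )
    t_ab = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
    t_ac = PhyloTree.from_newick("((A:1,C:1):1,(B:1,D:1):1);")
    assert fitch_length(t_ab, m)[0] == 1
    assert fitch_length(t_ac, m)[0] == 2


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_fitch_matches_exhaustive_labelings(seed):
    rng = np.random.default_rng(seed)
    taxa = list("ABCDE")
    tree = next(
        itertools.islice(all_unrooted_topologies(taxa), int(rng.integers(15)), None)
    )
    m = random_binary_matrix(5, 4, seed=seed + 100, n_states=3)
    m = CharacterMatrix(taxa=taxa, data=m.data)
    assert fitch_length(tree, m)[0] == brute_force_length(tree, m)


def test_fitch_with_missing_and_polymorphic():
    tree = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
    m = CharacterMatrix(
        taxa=list("ABCD"),
        data=[[frozenset({0})], [None], [frozenset({0, 1})], [frozenset({1})]],
    )
    assert fitch_length(tree, m)[0] == brute_force_length(tree, m)


def test_implied_weights_basics():
    tree = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
    clean = CharacterMatrix(
        taxa=list("ABCD"),
        data=[[frozenset({0})], [frozenset({0})], [frozenset({1})], [frozenset({1})]],
    )
    assert implied_weights_score(tree, clean, 10.0) == 0.0
    conflict = CharacterMatrix(
        taxa=list("ABCD"),
        data=[[frozenset({0})], [frozenset({1})], [frozenset({0})], [frozenset({1})]],
    )
    # one extra step, k=1 -> es/(es+k) = 0.5
    assert implied_weights_score(tree, conflict, 1.0) == pytest.approx(0.5)
    ks = [1, 10, 30, 100]
    scores = [implied_weights_score(tree, conflict, k) for k in ks]
    assert all(a > b for a, b in zip(scores, scores[1:]))
    assert scores[-1] < 0.01  # F(k -> inf) -> 0


def test_implied_ranking_approaches_equal_weights_for_large_k():
    m = random_binary_matrix(6, 15, seed=5)
    trees = list(all_unrooted_topologies(m.taxa))[:25]
    lengths = [fitch_length(t, m)[0] for t in trees]
    fits = [implied_weights_score(t, m, 1000.0) for t in trees]
    # strictly shorter tree -> strictly better fit (ranking agrees up to ties)
    for (la, fa), (lb, fb) in itertools.combinations(zip(lengths, fits), 2):
        if la < lb:
            assert fa < fb
        elif la > lb:
            assert fa > fb


def test_search_recovers_perfect_signal():
    # characters exactly mirror the clades of ((A,B),(C,D),E)
    cols = [{"A", "B"}, {"C", "D"}, {"A", "B"}, {"C", "D"}]
    taxa = list("ABCDE")
    data = [
        [frozenset({1 if t in c else 0}) for c in cols] for t in taxa
    ]
    m = CharacterMatrix(taxa=taxa, data=data)
    res = heuristic_search(m, ParsimonyConfig(n_replicates=3, seed=0))
    truth = PhyloTree.from_newick("(((A:1,B:1):1,(C:1,D:1):1):1,E:1);")
    assert res.stats.ci == 1.0
    assert truth.topology_key() in {t.topology_key() for t in res.trees}


@pytest.mark.parametrize("seed", [0, 7])
def test_search_matches_exhaustive_on_seven_taxa(seed):
    m = random_binary_matrix(7, 12, seed=seed)
    best, _ = exhaustive_search(m)
    res = heuristic_search(m, ParsimonyConfig(n_replicates=6, seed=seed))
    assert res.score == best


def test_search_invariant_to_character_and_taxon_order():
    m = random_binary_matrix(7, 10, seed=3)
    base = heuristic_search(m, ParsimonyConfig(n_replicates=5, seed=1)).score
    shuffled_chars = CharacterMatrix(
        taxa=m.taxa,
        data=[list(reversed(row)) for row in m.data],
        char_ids=list(reversed(m.char_ids)),
    )
    order = list(reversed(range(m.n_taxa)))
    shuffled_taxa = CharacterMatrix(
        taxa=[m.taxa[i] for i in order],
        data=[m.data[i] for i in order],
    )
    assert heuristic_search(shuffled_chars, ParsimonyConfig(n_replicates=5, seed=1)).score == base
    assert heuristic_search(shuffled_taxa, ParsimonyConfig(n_replicates=5, seed=1)).score == base


def test_tree_stats_hand_computed(abcd_matrix):
    # char1 clean on AB|CD (1 step), char2 conflicts (2 steps)
    tree = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
    stats = tree_stats(tree, abcd_matrix)
    assert stats.length == 3
    assert stats.ci == pytest.approx(2 / 3)   # m=2, L=3
    assert stats.ri == pytest.approx(0.5)     # g=4: (4-3)/(4-2)
    assert stats.per_character == (1, 2)


def test_homoplasy_free_stats():
    cols = [{"A", "B"}, {"C", "D"}]
    data = [[frozenset({1 if t in c else 0}) for c in cols] for t in "ABCD"]
    m = CharacterMatrix(taxa=list("ABCD"), data=data)
    tree = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
    stats = tree_stats(tree, m)
    assert stats.ci == 1.0 and stats.ri == 1.0


def test_ci_weakly_decreases_with_added_homoplasy(abcd_matrix):
    tree = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
    base = tree_stats(tree, abcd_matrix).ci
    more = CharacterMatrix(
        taxa=abcd_matrix.taxa,
        data=[row + [row[1]] for row in abcd_matrix.data],
    )
    assert tree_stats(tree, more).ci <= base


def test_number_of_unrooted_topologies():
    assert len(list(all_unrooted_topologies(list("ABCDE")))) == 15
    keys = {t.topology_key() for t in all_unrooted_topologies(list("ABCDEF"))}
    assert len(keys) == 105


# -- instability ----------------------------------------------------------


def _rogue_fixture():
    """Two optimal placements of leaf R driven by two conflicting
    characters; all other characters fit both trees equally."""
    taxa = sorted(["A", "B", "C", "D", "E", "F", "G", "R"])
    t1 = PhyloTree.from_newick(
        "(((((A:1,B:1):1,R:1):1,(C:1,D:1):1):1,(E:1,F:1):1):1,G:1);"
    )
    t2 = PhyloTree.from_newick(
        "((((A:1,B:1):1,((C:1,D:1):1,R:1):1):1,(E:1,F:1):1):1,G:1);"
    )

    def col(ones):
        return [frozenset({1 if t in ones else 0}) for t in taxa]

    cols = [
        col({"A", "B", "R"}),   # pulls R toward the AB clade
        col({"C", "D", "R"}),   # pulls R toward the CD clade
        col({"A", "B"}),
        col({"A", "B"}),
        col({"C", "D"}),
        col({"C", "D"}),
        col({"E", "F"}),
        col({"E", "F"}),
    ]
    data = [[c[i] for c in cols] for i in range(len(taxa))]
    return CharacterMatrix(taxa=taxa, data=data), t1, t2


def test_identical_trees_have_no_instability():
    m, t1, _ = _rogue_fixture()
    profile = instability_profile(m, [t1, t1.copy()])
    assert profile.unstable_leaves == []
    assert profile.character_frequencies == {}


def test_single_tree_raises():
    m, t1, _ = _rogue_fixture()
    with pytest.raises(OntopartError):
        instability_profile(m, [t1])


def test_rogue_leaf_and_supporting_characters():
    m, t1, t2 = _rogue_fixture()
    stab = leaf_stability([t1, t2])
    assert min(stab, key=stab.get) == "R"
    profile = instability_profile(m, [t1, t2])
    assert profile.unstable_leaves and profile.unstable_leaves[0][0] == "R"
    assert profile.character_frequencies == {1: 1, 2: 1}


def test_pruning_rogue_improves_consensus_resolution():
    from ontopart.mcmc import consensus_tree
    from ontopart.parsimony import _restrict_tree

    m, t1, t2 = _rogue_fixture()
    n = len(t1.taxa)
    before = len(consensus_tree([t1, t2], mode="strict").bipartitions())
    taxa = [t for t in t1.taxa if t != "R"]
    after = len(
        consensus_tree(
            [_restrict_tree(t1, taxa), _restrict_tree(t2, taxa)], mode="strict"
        ).bipartitions()
    )
    # resolution relative to a fully resolved unrooted tree (n-3 splits)
    assert after / (n - 4) > before / (n - 3)
    assert after == n - 4  # fully resolved once the rogue is gone
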