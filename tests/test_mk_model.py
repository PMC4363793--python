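"""Mk transition probabilities, pruning, and the Mkv correction."""

import itertools
import math

import numpy as np
import pytest

from ontopart.errors import AscertainmentError
from ontopart.matrix_io import CharacterMatrix
from ontopart.mk_model import (
    MkParameters,
    character_log_likelihood,
    dataset_log_likelihood,
    discrete_gamma_rates,
    transition_matrix,
)
from ontopart.model_space import LinkageSpec
from ontopart.ontology import PartitionScheme
from ontopart.trees import PhyloTree

from conftest import single_block_scheme


# -- independent oracle: exhaustive sum over internal-node states ---------


def brute_force_likelihood(tree, leaf_states, k, rates):
    """Sum over all internal state assignments, averaged over rate
    categories, uniform root frequencies."""

    def clade(node, state, r):
        if node.is_leaf:
            return 1.0 if leaf_states[node.taxon] == state else 0.0
        total = 1.0
        for child in node.children:
            s = 0.0
            P = transition_matrix(k, float(child.length) * r)
            for cs in range(k):
                s += P[state, cs] * clade(child, cs, r)
            total *= s
        return total

    out = 0.0
    for r in rates:
        out += sum(clade(tree.root, s, r) / k for s in range(k)) / len(rates)
    return out


# -- transition matrix ----------------------------------------------------


def test_zero_length_is_identity():
    assert np.allclose(transition_matrix(2, 0.0), np.eye(2))
    assert np.allclose(transition_matrix(3, 0.0), np.eye(3))


def test_long_branch_reaches_stationarity():
    P = transition_matrix(3, 100.0)
    assert np.allclose(P, 1.0 / 3, atol=1e-12)


def test_closed_form_value():
    assert transition_matrix(2, 0.5)[0, 0] == pytest.approx(
        0.5 + 0.5 * math.exp(-1.0), abs=1e-9
    )


@pytest.mark.parametrize("k", [2, 3])
@pytest.mark.parametrize("t", [0.0, 0.01, 0.3, 1.7, 10.0])
def test_rows_sum_to_one(k, t):
    assert np.allclose(transition_matrix(k, t).sum(axis=1), 1.0, atol=1e-12)


@pytest.mark.parametrize("k", [2, 3])
def test_chapman_kolmogorov(k):
    for t1, t2 in [(0.1, 0.2), (0.5, 1.3), (0.05, 0.05)]:
        left = transition_matrix(k, t1) @ transition_matrix(k, t2)
        assert np.allclose(left, transition_matrix(k, t1 + t2), atol=1e-10)


def test_negative_length_rejected():
    with pytest.raises(ValueError):
        transition_matrix(2, -0.1)


def test_discrete_gamma_mean_one():
    for shape in (0.2, 0.5, 1.0, 5.0):
        rates = discrete_gamma_rates(shape, 4)
        assert rates.mean() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(rates) > 0)


# -- pruning vs oracle ----------------------------------------------------


NEWICKS = [
    "((A:0.1,B:0.2):0.15,C:0.3);",
    "(((A:0.05,B:0.4):0.1,C:0.2):0.12,(D:0.3,E:0.07):0.2);",
]


@pytest.mark.parametrize("newick", NEWICKS)
@pytest.mark.parametrize("k", [2, 3])
@pytest.mark.parametrize("shape", [None, 0.5])
def test_pruning_equals_exhaustive_summation(newick, k, shape):
    tree = PhyloTree.from_newick(newick)
    rng = np.random.default_rng(hash((newick, k)) % 2**31)
    params = MkParameters(gamma_shape=shape)
    rates = (
        [1.0] if shape is None else list(discrete_gamma_rates(shape, 4))
    )
    for _ in range(5):
        states = {t: int(rng.integers(k)) for t in tree.taxa}
        char = {t: frozenset({s}) for t, s in states.items()}
        got = character_log_likelihood(tree, char, params, k=k)
        want = math.log(brute_force_likelihood(tree, states, k, rates))
        assert got == pytest.approx(want, abs=1e-9)


def test_zero_length_identical_states_gives_one_over_k():
    tree = PhyloTree.from_newick("(A:0.0,B:0.0);")
    char = {"A": frozenset({0}), "B": frozenset({0})}
    assert character_log_likelihood(tree, char, MkParameters(), k=2) == pytest.approx(
        math.log(0.5), abs=1e-9
    )


def test_state_relabelling_symmetry(three_taxon_tree):
    params = MkParameters(gamma_shape=0.7)
    char = {"A": frozenset({0}), "B": frozenset({1}), "C": frozenset({0})}
    flipped = {t: frozenset({1 - next(iter(c))}) for t, c in char.items()}
    a = character_log_likelihood(three_taxon_tree, char, params, k=2)
    b = character_log_likelihood(three_taxon_tree, flipped, params, k=2)
    assert a == pytest.approx(b, abs=1e-12)


def test_missing_cells_contribute_ones(three_taxon_tree):
    full_unknown = {"A": None, "B": None, "C": None}
    got = character_log_likelihood(three_taxon_tree, full_unknown, MkParameters(), k=2)
    assert got == pytest.approx(0.0, abs=1e-9)  # total probability 1


# -- Mkv correction -------------------------------------------------------


def _pattern_matrix(taxa, pattern):
    return CharacterMatrix(
        taxa=list(taxa), data=[[frozenset({s})] for s in pattern]
    )


@pytest.mark.parametrize("newick", [
    "((A:0.1,B:0.2):0.15,C:0.3);",
    "((A:0.15,B:0.2):0.1,(C:0.3,D:0.05):0.2);",
])
def test_variable_pattern_probabilities_sum_to_one(newick):
    tree = PhyloTree.from_newick(newick)
    taxa = sorted(tree.taxa)
    total = 0.0
    for pattern in itertools.product(range(2), repeat=len(taxa)):
        if len(set(pattern)) == 1:
            continue
        m = _pattern_matrix(taxa, pattern)
        ll = dataset_log_likelihood(
            tree, m, single_block_scheme(m), LinkageSpec(), MkParameters()
        )
        total += math.exp(ll)
    assert total == pytest.approx(1.0, abs=1e-9)


def test_variable_pattern_probabilities_sum_to_one_three_states():
    """Same normalization at a fixed k=3, reconstructed from the
    uncorrected per-character likelihood and the constant-pattern mass
    (the matrix path infers k per character, so 2-state patterns there
    use k=2 by design)."""
    tree = PhyloTree.from_newick("((A:0.1,B:0.2):0.15,C:0.3);")
    taxa = sorted(tree.taxa)
    params = MkParameters()
    p_const = sum(
        math.exp(
            character_log_likelihood(
                tree, {t: frozenset({s}) for t in taxa}, params, k=3
            )
        )
        for s in range(3)
    )
    total = 0.0
    for pattern in itertools.product(range(3), repeat=3):
        if len(set(pattern)) == 1:
            continue
        char = {t: frozenset({s}) for t, s in zip(taxa, pattern)}
        ll = character_log_likelihood(tree, char, params, k=3)
        total += math.exp(ll - math.log1p(-p_const))
    assert total == pytest.approx(1.0, abs=1e-9)


def test_zero_tree_variable_character_is_impossible():
    tree = PhyloTree.from_newick("((A:0.0,B:0.0):0.0,C:0.0);")
    m = _pattern_matrix(["A", "B", "C"], (0, 0, 1))
    ll = dataset_log_likelihood(
        tree, m, single_block_scheme(m), LinkageSpec(), MkParameters()
    )
    assert ll < -1e6


def test_constant_character_rejected(three_taxon_tree):
    m = _pattern_matrix(["A", "B", "C"], (1, 1, 1))
    with pytest.raises(AscertainmentError):
        dataset_log_likelihood(
            three_taxon_tree, m, single_block_scheme(m), LinkageSpec(), MkParameters()
        )


def test_identical_partitions_equal_unpartitioned(three_taxon_tree):
    m = CharacterMatrix(
        taxa=["A", "B", "C"],
        data=[
            [frozenset({0}), frozenset({0})],
            [frozenset({0}), frozenset({0})],
            [frozenset({1}), frozenset({1})],
        ],
    )
    split = PartitionScheme(
        id="2", blocks=(("p1", frozenset({1})), ("p2", frozenset({2})))
    )
    partitioned = dataset_log_likelihood(
        three_taxon_tree, m, split,
        LinkageSpec(rate_multiplier="unlinked"),
        MkParameters(rate_multipliers=(1.0, 1.0)),
    )
    merged = dataset_log_likelihood(
        three_taxon_tree, m, single_block_scheme(m), LinkageSpec(), MkParameters()
    )
    assert partitioned == pytest.approx(merged, abs=1e-9)


def test_rerooting_invariance():
    tree = PhyloTree.from_newick(
        "(((A:0.05,B:0.4):0.1,C:0.2):0.12,(D:0.3,E:0.07):0.2);"
    )
    m = _pattern_matrix(sorted(tree.taxa), (0, 1, 0, 1, 1))
    args = (m, single_block_scheme(m), LinkageSpec(rates="shared_gamma"),
            MkParameters(gamma_shape=0.6))
    base = dataset_log_likelihood(tree, *args)
    for taxon in ("A", "D"):
        rerooted = dataset_log_likelihood(tree.rerooted_at(taxon), *args)
        assert rerooted == pytest.approx(base, abs=1e-9)


def test_likelihood_continuous_in_branch_length(three_taxon_tree):
    m = _pattern_matrix(["A", "B", "C"], (0, 0, 1))
    scheme = single_block_scheme(m)

    def at(eps):
        t = three_taxon_tree.copy()
        t.edges()[0].length += eps
        return dataset_log_likelihood(t, m, scheme, LinkageSpec(), MkParameters())

    assert abs(at(1e-7) - at(0.0)) < 1e-4


def test_unlinked_branch_lengths_scale_partitions_independently(three_taxon_tree):
    m = CharacterMatrix(
        taxa=["A", "B", "C"],
        data=[
            [frozenset({0}), frozenset({0})],
            [frozenset({1}), frozenset({0})],
            [frozenset({1}), frozenset({1})],
        ],
    )
    split = PartitionScheme(
        id="2", blocks=(("p1", frozenset({1})), ("p2", frozenset({2})))
    )
    tree = three_taxon_tree.copy()
    for e in tree.edges():
        e.length = np.array([float(e.length), float(e.length)])
    linked_value = dataset_log_likelihood(
        three_taxon_tree, m, split, LinkageSpec(), MkParameters()
    )
    unlinked_value = dataset_log_likelihood(
        tree, m, split, LinkageSpec(brlens="unlinked"), MkParameters()
    )
    assert unlinked_value == pytest.approx(linked_value, abs=1e-9)
    # scaling only partition 2's lengths changes only its characters
    tree2 = tree.copy()
    for e in tree2.edges():
        e.length = e.length.copy()
        e.length[1] *= 3.0
    changed = dataset_log_likelihood(
        tree2, m, split, LinkageSpec(brlens="unlinked"), MkParameters(),
        per_character=True,
    )[1]
    base = dataset_log_likelihood(
        tree, m, split, LinkageSpec(brlens="unlinked"), MkParameters(),
        per_character=True,
    )[1]
    assert changed[0] == pytest.approx(base[0], abs=1e-12)
    assert changed[1] != pytest.approx(base[1], abs=1e-9)
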