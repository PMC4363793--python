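"""Sampler correctness, convergence diagnostics, consensus summaries."""

import math

import numpy as np
import pytest
from scipy import integrate

from ontopart.errors import OntopartError
from ontopart.matrix_io import CharacterMatrix
from ontopart.mcmc import (
    McmcConfig,
    PhyloPosterior,
    average_split_sd,
    consensus_tree,
    discard_burn_in,
    run_mcmc,
)
from ontopart.model_space import LinkageSpec
from ontopart.synthetic_data import SimulationSpec, simulate_matrix, simulate_tree
from ontopart.trees import PhyloTree

from conftest import single_block_scheme


@pytest.fixture(scope="module")
def small_dataset():
    spec = SimulationSpec(n_taxa=6, partition_sizes=(50,), seed=5)
    tree = simulate_tree(spec)
    matrix, _ = simulate_matrix(tree, spec)
    return tree, matrix


def test_same_seed_reproduces_sample_stream(small_dataset):
    _, matrix = small_dataset
    scheme = single_block_scheme(matrix)
    cfg = McmcConfig(n_generations=300, sample_interval=10, seed=42)
    a = run_mcmc(matrix, scheme, LinkageSpec(), cfg)
    b = run_mcmc(matrix, scheme, LinkageSpec(), cfg)
    assert [s.newick for s in a[0]] == [s.newick for s in b[0]]
    assert [s.log_likelihood for s in a[1]] == [s.log_likelihood for s in b[1]]


def test_sample_count_and_bookkeeping(small_dataset):
    _, matrix = small_dataset
    scheme = single_block_scheme(matrix)
    cfg = McmcConfig(n_generations=400, sample_interval=20, seed=1,
                     sample_topology=True)
    runs = run_mcmc(matrix, scheme, LinkageSpec(rates="shared_gamma"), cfg)
    assert all(len(r) == 21 for r in runs)
    posterior = PhyloPosterior(matrix, scheme, LinkageSpec(rates="shared_gamma"), cfg)
    for sample in runs[0][::7]:
        state = type("S", (), {})()
        state.tree = sample.tree
        state.shapes = np.asarray(sample.gamma_shapes)
        state.multipliers = None
        assert posterior.log_likelihood(state) == pytest.approx(
            sample.log_likelihood, abs=1e-9
        )
        assert posterior.log_prior(state) == pytest.approx(
            sample.log_prior, abs=1e-9
        )


def test_prior_only_sampling_recovers_branch_prior_mean(small_dataset):
    _, matrix = small_dataset
    scheme = single_block_scheme(matrix)
    cfg = McmcConfig(n_generations=6000, sample_interval=20, n_runs=2,
                     seed=9, prior_only=True)
    runs = run_mcmc(matrix, scheme, LinkageSpec(), cfg)
    lengths = [
        float(e.length)
        for r in runs
        for s in discard_burn_in(r)
        for e in s.tree.edges()
    ]
    assert np.mean(lengths) == pytest.approx(0.1, abs=0.02)


def test_three_taxon_branch_posterior_matches_quadrature():
    """Posterior mean of a terminal branch vs direct numeric integration
    for a single variable character on the (only) 3-taxon topology.

    Under the reversible Mk chain the rooted likelihood equals the
    unrooted star likelihood with leaf edges (ta, tb, u) where u sums
    the internal and C edges, so the 4-D posterior collapses to 3-D:
    ta, tb carry Exponential(10) priors and u a Gamma(2, 10) prior.
    """

    def p_same(t):
        return 0.5 + 0.5 * math.exp(-2 * t)

    def p_diff(t):
        return 0.5 - 0.5 * math.exp(-2 * t)

    def corrected(ta, tb, u):
        # pattern (A,B,C) = (0,0,1), star center marginalized
        lik = 0.5 * (
            p_same(ta) * p_same(tb) * p_diff(u)
            + p_diff(ta) * p_diff(tb) * p_same(u)
        )
        const = (
            p_same(ta) * p_same(tb) * p_same(u)
            + p_diff(ta) * p_diff(tb) * p_diff(u)
        )
        return lik / (1.0 - const)

    rate = 10.0

    def weight(ta, tb, u):
        prior = math.exp(-rate * (ta + tb + u)) * u  # Gamma(2) kernel on u
        return prior * corrected(ta, tb, u)

    hi = 1.5
    z, _ = integrate.tplquad(weight, 0, hi, 0, hi, 0, hi, epsabs=1e-10)
    za, _ = integrate.tplquad(
        lambda ta, tb, u: ta * weight(ta, tb, u), 0, hi, 0, hi, 0, hi,
        epsabs=1e-10,
    )
    oracle = za / z

    matrix = CharacterMatrix(
        taxa=["A", "B", "C"],
        data=[[frozenset({0})], [frozenset({0})], [frozenset({1})]],
    )
    start = PhyloTree.from_newick("((A:0.1,B:0.1):0.15,C:0.1);")
    cfg = McmcConfig(n_generations=40000, sample_interval=20, n_runs=2,
                     seed=3, start_tree=start, sample_topology=False)
    runs = run_mcmc(matrix, single_block_scheme(matrix), LinkageSpec(), cfg)
    means = []
    for r in runs:
        vals = [
            float(next(n for n in s.tree.postorder() if n.taxon == "A").length)
            for s in discard_burn_in(r)
        ]
        means.append(np.mean(vals))
    assert np.mean(means) == pytest.approx(oracle, abs=0.015)


def test_consensus_recovers_strong_signal():
    spec = SimulationSpec(n_taxa=8, partition_sizes=(200,), seed=13)
    tree = simulate_tree(spec)
    matrix, _ = simulate_matrix(tree, spec)
    cfg = McmcConfig(n_generations=4000, sample_interval=20, n_runs=2, seed=7)
    runs = run_mcmc(matrix, single_block_scheme(matrix), LinkageSpec(), cfg)
    pooled = [s for r in runs for s in discard_burn_in(r)]
    cons = consensus_tree(pooled, mode="majority")
    truth = tree.bipartitions()
    recovered = truth & cons.bipartitions()
    assert len(recovered) >= 0.9 * len(truth)


# -- ASDSF ----------------------------------------------------------------


def test_asdsf_identical_runs_zero(small_dataset):
    tree, _ = small_dataset
    run = [tree.copy() for _ in range(10)]
    asdsf, converged = average_split_sd([run, [t.copy() for t in run]])
    assert asdsf == 0.0 and converged


def test_asdsf_fully_conflicting_runs():
    t1 = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
    t2 = PhyloTree.from_newick("((A:1,C:1):1,(B:1,D:1):1);")
    asdsf, converged = average_split_sd([[t1, t1.copy()], [t2, t2.copy()]])
    assert asdsf == pytest.approx(math.sqrt(0.5), abs=1e-9)
    assert not converged


def test_asdsf_threshold_is_inclusive():
    # frequencies engineered so the mean split SD is just under 0.01
    t1 = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
    t2 = PhyloTree.from_newick("((A:1,C:1):1,(B:1,D:1):1);")
    run_a = [t1.copy() for _ in range(100)]
    run_b = [t1.copy() for _ in range(99)] + [t2.copy()]
    asdsf, converged = average_split_sd([run_a, run_b])
    # split AB|CD: freqs (1.0, 0.99); split AC|BD: (0, 0.01) below min_freq
    assert asdsf == pytest.approx(0.01 / math.sqrt(2), abs=1e-9)
    assert converged


def test_asdsf_requires_common_taxa(small_dataset):
    tree, _ = small_dataset
    other = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
    with pytest.raises(OntopartError):
        average_split_sd([[tree], [other]])


def test_asdsf_needs_two_runs(small_dataset):
    tree, _ = small_dataset
    with pytest.raises(OntopartError):
        average_split_sd([[tree]])


# -- consensus ------------------------------------------------------------


def test_consensus_of_identical_trees(small_dataset):
    tree, _ = small_dataset
    cons = consensus_tree([tree.copy() for _ in range(5)], mode="majority")
    assert cons.bipartitions() == tree.bipartitions()
    supports = [
        n.support for n in cons.postorder() if n.support is not None
    ]
    assert supports and all(s == 1.0 for s in supports)


def test_majority_support_two_thirds():
    t1 = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
    t2 = PhyloTree.from_newick("((A:1,C:1):1,(B:1,D:1):1);")
    cons = consensus_tree([t1, t1.copy(), t2], mode="majority", threshold=0.5)
    split = frozenset({"C", "D"})
    node = next(
        n for n in cons.postorder()
        if n.support is not None
    )
    assert split in cons.bipartitions()
    assert node.support == pytest.approx(2 / 3)


def test_strict_splits_subset_of_majority(small_dataset):
    _, matrix = small_dataset
    cfg = McmcConfig(n_generations=600, sample_interval=10, seed=21)
    runs = run_mcmc(matrix, single_block_scheme(matrix), LinkageSpec(), cfg)
    pooled = [s for r in runs for s in discard_burn_in(r)]
    strict = consensus_tree(pooled, mode="strict").bipartitions()
    majority = consensus_tree(pooled, mode="majority").bipartitions()
    assert strict <= majority
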