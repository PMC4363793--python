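"""Posterior sampling of topology and Mkv model parameters.

Metropolis–Hastings over tree topology (NNI, plus an optional SPR move
with a uniform edge-split proposal), branch lengths (scale proposals),
gamma shapes (log-scale random walks) and partition rate multipliers
(mass-transfer moves on the weighted simplex).  Priors follow common
morphological-analysis defaults: Exponential(10) branch lengths,
Exponential(1) gamma shapes, a flat Dirichlet on the weighted
multipliers, uniform topology.

Two (or more) independent runs are the unit of analysis: convergence is
diagnosed by the average standard deviation of split frequencies
(ASDSF) between runs, with the conventional 0.01-or-lower rule, and
summarised by consensus trees whose split supports are posterior
probabilities.  Proposal tuning constants are fixed (no adaptation), so
a seed fully determines the sample stream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from ontopart.errors import OntopartError
from ontopart.mk_model import MkParameters, MkvLikelihood
from ontopart.trees import Node, PhyloTree, tree_from_splits


@dataclass
class McmcConfig:
    n_generations: int = 2000
    sample_interval: int = 10
    n_runs: int = 2
    burn_in_fraction: float = 0.25
    seed: int = 0
    branch_prior_rate: float = 10.0
    shape_prior_rate: float = 1.0
    n_gamma_categories: int = 4
    prior_only: bool = False
    sample_topology: bool = True
    start_tree: object = None  # PhyloTree; None = random start
    # fixed proposal tuning (no adaptation; determinism given seed)
    brlen_lambda: float = 1.4
    shape_step: float = 2.0
    multiplier_delta: float = 0.15
    nni_weight: float = 0.3
    spr_weight: float = 0.1
    heating_temperature: float | None = None  # e.g. 0.2; None = single chain
    n_chains: int = 1

    def __post_init__(self):
        if not 0 <= self.burn_in_fraction < 1:
            raise ValueError("burn_in_fraction must be in [0,1)")
        if self.n_generations % self.sample_interval:
            raise ValueError("sample_interval must divide n_generations")
        for name in ("brlen_lambda", "shape_step", "multiplier_delta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PosteriorSample:
    generation: int
    tree: PhyloTree
    newick: str
    gamma_shapes: tuple | None
    multipliers: tuple | None
    log_likelihood: float
    log_prior: float


@dataclass
class _State:
    tree: PhyloTree
    shapes: np.ndarray | None
    multipliers: np.ndarray | None
    log_likelihood: float = 0.0
    log_prior: float = 0.0


class PhyloPosterior:
    """Posterior context: likelihood, prior and proposal kernel for one
    (matrix, scheme, linkage) model."""

    def __init__(self, matrix, scheme, linkage, config: McmcConfig):
        self.matrix = matrix
        self.scheme = scheme
        self.linkage = linkage
        self.config = config
        self.likelihood = (
            None if config.prior_only else MkvLikelihood(matrix, scheme, linkage)
        )
        self.n_partitions = scheme.n_partitions
        self.n_brlen_sets = (
            self.n_partitions if linkage.brlens == "unlinked" else 1
        )
        self.n_shapes = (
            0
            if linkage.rates == "equal"
            else (1 if linkage.rates == "shared_gamma" else self.n_partitions)
        )
        self.has_multipliers = linkage.rate_multiplier != "absent"
        sizes = np.asarray([len(c) for _, c in scheme.blocks], float)
        self.weights = sizes / sizes.sum()

    # -- state ----------------------------------------------------------
    def init_state(self, rng) -> _State:
        if self.config.start_tree is not None:
            tree = self.config.start_tree.copy()
        else:
            tree = _random_tree(sorted(self.matrix.taxa), rng,
                                self.config.branch_prior_rate)
        if self.n_brlen_sets > 1:
            for e in tree.edges():
                e.length = np.full(self.n_brlen_sets, float(e.length))
        shapes = np.ones(self.n_shapes) if self.n_shapes else None
        multipliers = (
            np.ones(self.n_partitions) if self.has_multipliers else None
        )
        state = _State(tree=tree, shapes=shapes, multipliers=multipliers)
        state.log_likelihood = self.log_likelihood(state)
        state.log_prior = self.log_prior(state)
        return state

    def params_of(self, state: _State) -> MkParameters:
        if self.n_shapes == 0:
            shape = None
        elif self.n_shapes == 1:
            shape = float(state.shapes[0])
        else:
            shape = state.shapes
        return MkParameters(
            gamma_shape=shape,
            n_gamma_categories=self.config.n_gamma_categories,
            rate_multipliers=state.multipliers,
        )

    def log_likelihood(self, state: _State) -> float:
        if self.likelihood is None:
            return 0.0
        return self.likelihood.log_likelihood(state.tree, self.params_of(state))

    def log_prior(self, state: _State) -> float:
        rate = self.config.branch_prior_rate
        lp = 0.0
        for e in state.tree.edges():
            t = e.length
            if isinstance(t, np.ndarray):
                lp += float(np.sum(np.log(rate) - rate * t))
            else:
                lp += math.log(rate) - rate * float(t)
        if state.shapes is not None:
            srate = self.config.shape_prior_rate
            lp += float(np.sum(np.log(srate) - srate * state.shapes))
        # multipliers: flat Dirichlet on the weighted simplex -> constant
        return lp

    # -- proposals ------------------------------------------------------
    def _move_table(self):
        cfg = self.config
        moves = [("brlen", 0.5)]
        topology_on = cfg.sample_topology and self.matrix.n_taxa >= 4
        if topology_on:
            moves.append(("nni", cfg.nni_weight))
            if cfg.spr_weight > 0:
                moves.append(("spr", cfg.spr_weight))
        # with the topology fixed, spend the freed proposal mass on the
        # continuous parameters (better effective sample sizes)
        param_w = 0.15 if topology_on else 0.25
        if self.n_shapes:
            moves.append(("shape", param_w))
        if self.has_multipliers:
            moves.append(("mult", param_w))
        names, w = zip(*moves)
        w = np.asarray(w, float)
        return names, w / w.sum()

    def propose(self, state: _State, rng):
        names, probs = self._move_table()
        move = names[rng.choice(len(names), p=probs)]
        if move == "brlen":
            return self._propose_brlen(state, rng)
        if move == "nni":
            return self._propose_nni(state, rng)
        if move == "spr":
            return self._propose_spr(state, rng)
        if move == "shape":
            return self._propose_shape(state, rng)
        return self._propose_mult(state, rng)

    def _propose_brlen(self, state, rng):
        tree = state.tree.copy()
        edges = tree.edges()
        e = edges[rng.integers(len(edges))]
        lam = self.config.brlen_lambda
        factor = math.exp(lam * (rng.random() - 0.5))
        if isinstance(e.length, np.ndarray):
            p = int(rng.integers(len(e.length)))
            e.length = e.length.copy()
            e.length[p] *= factor
        else:
            e.length = float(e.length) * factor
        return replace(state, tree=tree), math.log(factor)

    def _propose_nni(self, state, rng):
        tree = state.tree.copy()
        internals = [
            n for n in tree.postorder()
            if not n.is_leaf and n.parent is not None
        ]
        if not internals:
            return replace(state, tree=tree), 0.0
        v = internals[rng.integers(len(internals))]
        u = v.parent
        c = v.children[rng.integers(len(v.children))]
        siblings = [s for s in u.children if s is not v]
        s = siblings[rng.integers(len(siblings))]
        # exchange subtrees c and s (lengths ride along)
        v.children[v.children.index(c)] = s
        u.children[u.children.index(s)] = c
        c.parent, s.parent = u, v
        return replace(state, tree=tree), 0.0

    def _spr_pairs(self, tree):
        nodes = list(tree.postorder())
        pairs = []
        for pi, p in enumerate(nodes):
            if p.parent is None:
                continue
            if p.parent.parent is None and len(p.parent.children) == 2:
                # pruning a root child would drop an edge dimension
                continue
            sub = set()
            stack = [p]
            while stack:
                n = stack.pop()
                sub.add(id(n))
                stack.extend(n.children)
            for gi, g in enumerate(nodes):
                if gi == pi or g.parent is None:
                    continue
                if id(g) in sub or g is p.parent:
                    continue
                if len(p.parent.children) == 2 and p.parent is g.parent:
                    # sibling graft: topology no-op
                    continue
                pairs.append((pi, gi))
        return nodes, pairs

    def _propose_spr(self, state, rng):
        nodes, pairs = self._spr_pairs(state.tree)
        if not pairs:
            return replace(state, tree=state.tree.copy()), 0.0
        n_fwd = len(pairs)
        pi, gi = pairs[rng.integers(n_fwd)]
        tree = state.tree.copy()
        tn = list(tree.postorder())
        p, g = tn[pi], tn[gi]
        parent = p.parent
        parent.children.remove(p)
        p.parent = None
        # parent is never a 2-child root here (excluded in _spr_pairs),
        # so suppressing it merges two edge lengths into one
        only = parent.children[0]
        gp = parent.parent
        only.length = only.length + parent.length
        merged_len = only.length
        only.parent = gp
        gp.children[gp.children.index(parent)] = only
        if g.parent is None:
            return replace(state, tree=state.tree.copy()), 0.0
        split_len = g.length
        u = rng.random()
        gparent = g.parent
        mid = Node(length=g.length * (1 - u))
        g.length = g.length * u
        gparent.children[gparent.children.index(g)] = mid
        mid.parent = gparent
        mid.add(g)
        mid.add(p)
        root = mid
        while root.parent is not None:
            root = root.parent
        new_tree = PhyloTree(root)
        _, rev_pairs = self._spr_pairs(new_tree)
        n_rev = max(len(rev_pairs), 1)

        def total(x):
            return float(np.sum(x)) if isinstance(x, np.ndarray) else float(x)

        t_split = total(split_len)   # edge split by the forward move
        t_merged = total(merged_len)  # edge the reverse move would split
        # split-merge Jacobian: |J| = t_split / t_merged
        hastings = math.log(n_fwd) - math.log(n_rev)
        if t_split > 0 and t_merged > 0:
            hastings += math.log(t_split) - math.log(t_merged)
        return replace(state, tree=new_tree), hastings

    def _propose_shape(self, state, rng):
        shapes = state.shapes.copy()
        i = int(rng.integers(len(shapes)))
        if rng.random() < 0.5:
            # independence draw from the Exponential prior: the prior
            # ratio cancels against the proposal, leaving the likelihood
            # ratio — mixes well where the likelihood is flat in the shape
            srate = self.config.shape_prior_rate
            new = float(rng.exponential(1.0 / srate))
            log_h = srate * (new - shapes[i])
            shapes[i] = new
            return replace(state, shapes=shapes), log_h
        factor = math.exp(self.config.shape_step * (rng.random() - 0.5))
        shapes[i] *= factor
        return replace(state, shapes=shapes), math.log(factor)

    def _propose_mult(self, state, rng):
        m = state.multipliers.copy()
        w = self.weights
        x = w * m
        i, j = rng.choice(len(m), size=2, replace=False)
        delta = (rng.random() - 0.5) * 2 * self.config.multiplier_delta
        x = x.copy()
        x[i] += delta
        x[j] -= delta
        if x[i] <= 0 or x[j] <= 0:
            return None  # out of support; caller counts a rejection
        m2 = x / w
        return replace(state, multipliers=m2), 0.0


def _random_tree(taxa, rng, branch_rate) -> PhyloTree:
    root = Node()
    root.add(Node(taxon=taxa[0], length=float(rng.exponential(1 / branch_rate))))
    root.add(Node(taxon=taxa[1], length=float(rng.exponential(1 / branch_rate))))
    tree = PhyloTree(root)
    for label in taxa[2:]:
        edges = tree.edges()
        target = edges[rng.integers(len(edges))]
        parent = target.parent
        mid = Node(length=target.length / 2)
        target.length = target.length / 2
        parent.children[parent.children.index(target)] = mid
        mid.parent = parent
        mid.add(target)
        mid.add(Node(taxon=label, length=float(rng.exponential(1 / branch_rate))))
        tree = PhyloTree(root)
    return tree


def _run_chain(posterior: PhyloPosterior, rng, n_generations, sample_interval,
               beta: float = 1.0, init_state: _State | None = None,
               record: bool = True):
    """One MH chain targeting prior x likelihood^beta.  Returns
    (samples, final_state, acceptance_rate)."""
    state = posterior.init_state(rng) if init_state is None else init_state
    samples = []
    accepted = proposed = 0
    if record:
        samples.append(_record(state, 0))
    for gen in range(1, n_generations + 1):
        prop = posterior.propose(state, rng)
        proposed += 1
        if prop is not None:
            new_state, log_hastings = prop
            new_state.log_likelihood = posterior.log_likelihood(new_state)
            new_state.log_prior = posterior.log_prior(new_state)
            log_alpha = (
                beta * (new_state.log_likelihood - state.log_likelihood)
                + (new_state.log_prior - state.log_prior)
                + log_hastings
            )
            if log_alpha >= 0 or rng.random() < math.exp(max(log_alpha, -700)):
                state = new_state
                accepted += 1
        if record and gen % sample_interval == 0:
            samples.append(_record(state, gen))
    return samples, state, accepted / max(proposed, 1)


def _record(state: _State, gen: int) -> PosteriorSample:
    tree = state.tree.copy()
    return PosteriorSample(
        generation=gen,
        tree=tree,
        newick=tree.to_newick(),
        gamma_shapes=tuple(state.shapes) if state.shapes is not None else None,
        multipliers=(
            tuple(state.multipliers) if state.multipliers is not None else None
        ),
        log_likelihood=state.log_likelihood,
        log_prior=state.log_prior,
    )


def run_mcmc(matrix, scheme, linkage, config: McmcConfig):
    """Independent-run posterior sampling; returns one sample list per
    run (``config.n_runs``), each of length n_generations/interval + 1.

    With ``config.heating_temperature`` set and ``n_chains > 1``, each
    run is a Metropolis-coupled ensemble: chain ``i`` targets
    ``posterior^(1/(1 + T i))`` and adjacent chains propose swaps; only
    the cold chain is recorded.
    """
    posterior = PhyloPosterior(matrix, scheme, linkage, config)
    runs = []
    for r in range(config.n_runs):
        rng = np.random.default_rng((config.seed, r))
        if config.heating_temperature and config.n_chains > 1:
            runs.append(_run_mc3(posterior, rng, config))
        else:
            samples, _, _ = _run_chain(
                posterior, rng, config.n_generations, config.sample_interval
            )
            runs.append(samples)
    return runs


def _run_mc3(posterior, rng, config):
    T = config.heating_temperature
    powers = [1.0 / (1.0 + T * i) for i in range(config.n_chains)]
    states = [posterior.init_state(rng) for _ in powers]
    samples = [_record(states[0], 0)]
    for gen in range(1, config.n_generations + 1):
        for i, beta in enumerate(powers):
            prop = posterior.propose(states[i], rng)
            if prop is None:
                continue
            new_state, log_h = prop
            new_state.log_likelihood = posterior.log_likelihood(new_state)
            new_state.log_prior = posterior.log_prior(new_state)
            log_alpha = (
                beta * (new_state.log_likelihood - states[i].log_likelihood)
                + (new_state.log_prior - states[i].log_prior)
                + log_h
            )
            if log_alpha >= 0 or rng.random() < math.exp(max(log_alpha, -700)):
                states[i] = new_state
        i = int(rng.integers(len(powers) - 1))
        d = (powers[i] - powers[i + 1]) * (
            states[i + 1].log_likelihood - states[i].log_likelihood
        )
        if d >= 0 or rng.random() < math.exp(max(d, -700)):
            states[i], states[i + 1] = states[i + 1], states[i]
        if gen % config.sample_interval == 0:
            samples.append(_record(states[0], gen))
    return samples


# ---------------------------------------------------------------------------
# Diagnostics and summaries


def _trees_of(run):
    return [s.tree if isinstance(s, PosteriorSample) else s for s in run]


def discard_burn_in(run, burn_in_fraction: float = 0.25):
    n = len(run)
    return run[int(math.floor(n * burn_in_fraction)):]


def split_frequencies(trees) -> dict:
    counts: dict = {}
    for tree in trees:
        for split in tree.bipartitions():
            counts[split] = counts.get(split, 0) + 1
    n = len(trees)
    return {s: c / n for s, c in counts.items()}


def average_split_sd(runs, min_freq: float = 0.10):
    """ASDSF across >= 2 runs of trees (burn-in already removed).

    Splits whose frequency reaches ``min_freq`` in at least one run
    enter the average; each contributes the sample standard deviation of
    its per-run frequencies.  Returns ``(asdsf, converged)`` with the
    0.01-or-lower convergence rule.
    """
    if len(runs) < 2:
        raise OntopartError("ASDSF needs at least two runs")
    tree_runs = [_trees_of(r) for r in runs]
    taxa = set(tree_runs[0][0].taxa)
    for tr in tree_runs:
        for t in tr:
            if set(t.taxa) != taxa:
                raise OntopartError("runs sample trees over different taxon sets")
    freqs = [split_frequencies(tr) for tr in tree_runs]
    eligible = set()
    for f in freqs:
        eligible |= {s for s, v in f.items() if v >= min_freq}
    if not eligible:
        return 0.0, True
    sds = []
    for s in eligible:
        values = np.array([f.get(s, 0.0) for f in freqs])
        sds.append(float(np.std(values, ddof=1)))
    asdsf = float(np.mean(sds))
    return asdsf, asdsf <= 0.01


def consensus_tree(samples, mode: str = "majority", threshold: float = 0.5) -> PhyloTree:
    """Consensus of a tree sample with per-split support.

    ``majority`` keeps splits with frequency strictly above
    ``threshold`` (supports are posterior probabilities when the sample
    is an MCMC run); ``strict`` keeps splits present in every tree.
    """
    trees = _trees_of(samples)
    if not trees:
        raise OntopartError("empty tree sample")
    freqs = split_frequencies(trees)
    if mode == "strict":
        kept = {s: 1.0 for s, f in freqs.items() if f >= 1.0 - 1e-12}
    elif mode == "majority":
        kept = {s: f for s, f in freqs.items() if f > threshold}
    else:
        raise ValueError("mode must be 'strict' or 'majority'")
    return tree_from_splits(sorted(trees[0].taxa), kept)
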