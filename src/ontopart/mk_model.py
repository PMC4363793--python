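"""Partitioned Mk/Mkv likelihood for discrete morphological characters.

The Mk model is the k-state generalisation of Jukes–Cantor: all states
equally frequent, all exchanges at the same rate.  Its transition
probabilities have the closed form

    P_same(t) = 1/k + (k-1)/k * exp(-k t / (k-1))
    P_diff(t) = 1/k -   1/k   * exp(-k t / (k-1))

with ``t`` in expected changes per character.  The Mkv variant corrects
for the ascertainment bias of morphological matrices that score only
variable characters by conditioning each character's likelihood on being
variable: lnL_i - ln(1 - sum_s Pr(all taxa in state s)).

Among-character rate variation uses Yang's discrete gamma (equal
probability categories represented by their means); among-partition rate
variation uses per-partition multipliers m_p constrained to weighted
mean one (weights = partition sizes), and optionally per-partition
branch-length vectors when branch lengths are unlinked.

Likelihoods are computed by Felsenstein pruning, vectorised over the
characters of a partition, with per-node scaling against underflow.
Missing cells (and polymorphic cells, which the likelihood treats as
missing) contribute a vector of ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from ontopart.errors import AscertainmentError, OntopartError
from ontopart.model_space import LinkageSpec, check_admissible
from ontopart.trees import PhyloTree

LOG_ZERO = -1e10  # guard for impossible data (e.g. variability at zero length)


@dataclass
class MkParameters:
    """Continuous parameters of a (possibly partitioned) Mk model.

    ``gamma_shape``: None for equal rates, a float for a shared gamma
    shape, or a sequence of per-partition shapes.  ``rate_multipliers``:
    None when among-partition rates are not modelled, else one
    multiplier per partition with character-count-weighted mean one.
    """

    gamma_shape: object = None
    n_gamma_categories: int = 4
    rate_multipliers: object = None

    def shape_for(self, p: int):
        if self.gamma_shape is None:
            return None
        if np.isscalar(self.gamma_shape):
            return float(self.gamma_shape)
        return float(self.gamma_shape[p])

    def multiplier_for(self, p: int) -> float:
        if self.rate_multipliers is None:
            return 1.0
        return float(self.rate_multipliers[p])


def validate_multipliers(multipliers, weights, tol: float = 1e-9) -> None:
    m = np.asarray(multipliers, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(m < 0):
        raise OntopartError("rate multipliers must be nonnegative")
    if abs(float(w @ m) - 1.0) > tol:
        raise OntopartError(
            f"weighted mean of rate multipliers is {float(w @ m)!r}, expected 1"
        )


def discrete_gamma_rates(shape: float, ncat: int = 4) -> np.ndarray:
    """Category rates of the mean-one discrete gamma (equal-probability
    categories represented by their conditional means)."""
    if shape <= 0:
        raise ValueError("gamma shape must be positive")
    if ncat == 1:
        return np.ones(1)
    edges = gamma_dist.ppf(np.linspace(0, 1, ncat + 1), a=shape, scale=1.0 / shape)
    # E[X | a<X<b] for Gamma(shape, rate=shape) via the regularized
    # incomplete gamma of shape+1
    upper = gammainc(shape + 1, edges[1:] * shape)
    lower = gammainc(shape + 1, edges[:-1] * shape)
    rates = ncat * (upper - lower)
    return rates / rates.mean()  # exact mean 1 despite tail rounding


def transition_matrix(k: int, t: float) -> np.ndarray:
    """Closed-form Mk transition probabilities for one branch."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if t < 0:
        raise ValueError("branch length must be nonnegative")
    e = np.exp(-k * t / (k - 1))
    p_same = 1.0 / k + (k - 1) / k * e
    p_diff = 1.0 / k - 1.0 / k * e
    return np.full((k, k), p_diff) + np.eye(k) * (p_same - p_diff)


def _transition_tensor(k: int, ts: np.ndarray) -> np.ndarray:
    """(len(ts), k, k) stack of transition matrices."""
    ts = np.asarray(ts, dtype=float)
    e = np.exp(-k * ts / (k - 1))[:, None, None]
    same = 1.0 / k + (k - 1) / k * e
    diff = 1.0 / k - 1.0 / k * e
    out = np.broadcast_to(diff, (len(ts), k, k)).copy()
    idx = np.arange(k)
    out[:, idx, idx] = same[:, 0, 0][:, None]
    return out


def _edge_length(node, partition_index: int) -> float:
    t = node.length
    if isinstance(t, np.ndarray):
        return float(t[partition_index])
    return float(t)


def _prune_logliks(
    tree: PhyloTree,
    leaf_partials: dict,
    k: int,
    rates: np.ndarray,
    partition_index: int = 0,
) -> np.ndarray:
    """Per-character log likelihoods by pruning.

    ``leaf_partials`` maps taxon -> (nchar, k) array.  ``rates`` are the
    gamma-category rates already scaled by the partition multiplier;
    categories are equally probable and averaged at the root with
    uniform 1/k state frequencies.
    """
    ncat = len(rates)
    some = next(iter(leaf_partials.values()))
    nchar = some.shape[0]
    partial: dict = {}
    logscale = np.zeros(nchar)
    for node in tree.postorder():
        if node.is_leaf:
            lp = leaf_partials[node.taxon]
            partial[id(node)] = np.broadcast_to(lp, (ncat, nchar, k)).copy()
            continue
        acc = np.ones((ncat, nchar, k))
        for child in node.children:
            t = _edge_length(child, partition_index)
            P = _transition_tensor(k, t * rates)  # (ncat, k, k)
            acc *= np.einsum("cij,cnj->cni", P, partial.pop(id(child)))
        scale = acc.max(axis=(0, 2))
        safe = np.where(scale > 0, scale, 1.0)
        acc /= safe[None, :, None]
        logscale += np.where(scale > 0, np.log(safe), LOG_ZERO)
        partial[id(node)] = acc
    root = partial[id(tree.root)]
    lik = root.sum(axis=2).mean(axis=0) / k  # (nchar,)
    with np.errstate(divide="ignore"):
        return np.where(lik > 0, np.log(np.maximum(lik, 1e-300)), LOG_ZERO) + logscale


def _leaf_partials_from_cells(cells_by_taxon: dict, state_map: dict, k: int):
    """Leaf partial vectors for one column: one-hot for a scored state,
    ones for missing or polymorphic cells."""
    out = {}
    for taxon, cell in cells_by_taxon.items():
        v = np.ones(k)
        if cell is not None and len(cell) == 1:
            s = next(iter(cell))
            if s not in state_map:
                raise OntopartError(f"state {s} outside the character's state set")
            v = np.zeros(k)
            v[state_map[s]] = 1.0
        out[taxon] = v[None, :]
    return out


def character_log_likelihood(
    tree: PhyloTree,
    char: dict,
    params: MkParameters,
    partition: int = 0,
    k: int | None = None,
) -> float:
    """Uncorrected log likelihood of one character (no Mkv correction).

    ``char`` maps taxon -> cell (frozenset of states or None).  ``k``
    defaults to the number of distinct observed states (minimum 2);
    states are then relabelled 0..k-1 in sorted order.
    """
    observed = sorted({s for c in char.values() if c is not None and len(c) == 1 for s in c})
    if k is None:
        state_map = {s: i for i, s in enumerate(observed)}
        k = max(len(observed), 2)
    else:
        if observed and max(observed) >= k:
            raise OntopartError(f"state {max(observed)} >= k={k}")
        state_map = {s: s for s in range(k)}
    shape = params.shape_for(partition)
    rates = (
        np.ones(1)
        if shape is None
        else discrete_gamma_rates(shape, params.n_gamma_categories)
    )
    rates = rates * params.multiplier_for(partition)
    partials = _leaf_partials_from_cells(char, state_map, k)
    return float(_prune_logliks(tree, partials, k, rates, partition)[0])


def constant_pattern_log_prob(
    tree: PhyloTree, k: int, rates: np.ndarray, partition_index: int = 0
) -> float:
    """log sum_s Pr(all taxa in state s) under the same tree and rates."""
    taxa = [leaf.taxon for leaf in tree.leaves()]
    partials = {}
    for taxon in taxa:
        eye = np.eye(k)
        partials[taxon] = eye  # column c = pattern "all taxa in state c"
    logp = _prune_logliks(tree, partials, k, rates, partition_index)
    m = logp.max()
    return float(m + np.log(np.exp(logp - m).sum()))


class MkvLikelihood:
    """Reusable Mkv likelihood evaluator for one (matrix, scheme,
    linkage) triple.

    Leaf partial vectors are precomputed per partition and per observed
    state count, so repeated evaluation across trees and parameter
    values (the MCMC inner loop) costs only the pruning passes.
    """

    def __init__(self, matrix, scheme, linkage: LinkageSpec, validate: bool = True):
        check_admissible(scheme, linkage)
        if frozenset(matrix.char_ids) != scheme.characters():
            raise OntopartError(
                "partition scheme does not cover the matrix characters"
            )
        self.matrix = matrix
        self.scheme = scheme
        self.linkage = linkage
        self.block_sizes = [len(chars) for _, chars in scheme.blocks]
        self.weights = np.asarray(self.block_sizes, float) / sum(self.block_sizes)
        self.taxa = list(matrix.taxa)

        col_of = {cid: j for j, cid in enumerate(matrix.char_ids)}
        self.partition_groups: list = []  # per partition: list of (k, partials, cols)
        for _, chars in scheme.blocks:
            by_k: dict = {}
            for cid in sorted(chars):
                j = col_of[cid]
                observed = sorted(matrix.observed_states(j))
                if validate and len(observed) <= 1:
                    raise AscertainmentError(
                        f"character {cid} is constant; inconsistent with "
                        "variable coding"
                    )
                k = max(len(observed), 2)
                state_map = {s: i for i, s in enumerate(observed)}
                by_k.setdefault(k, []).append((j, state_map))
            groups = []
            for k, cols in by_k.items():
                # the k trailing pseudo-columns are the constant patterns
                # "all taxa in state s", pruned in the same pass as the
                # data columns to share the ascertainment denominator
                partials = {}
                for ti, taxon in enumerate(matrix.taxa):
                    arr = np.ones((len(cols) + k, k))
                    for c, (j, state_map) in enumerate(cols):
                        cell = matrix.data[ti][j]
                        if cell is not None and len(cell) == 1:
                            s = next(iter(cell))
                            arr[c] = 0.0
                            arr[c, state_map[s]] = 1.0
                    arr[len(cols):] = np.eye(k)
                    partials[taxon] = arr
                groups.append((k, partials, [j for j, _ in cols]))
            self.partition_groups.append(groups)

    def _rates_for(self, p: int, params: MkParameters) -> np.ndarray:
        shape = params.shape_for(p) if self.linkage.rates != "equal" else None
        base = (
            np.ones(1)
            if shape is None
            else discrete_gamma_rates(shape, params.n_gamma_categories)
        )
        if self.linkage.rate_multiplier != "absent":
            base = base * params.multiplier_for(p)
        return base

    def log_likelihood(self, tree: PhyloTree, params: MkParameters,
                       per_character: bool = False):
        if set(self.taxa) != set(tree.taxa):
            raise OntopartError("tree taxa do not match matrix taxa")
        if self.linkage.rate_multiplier != "absent":
            if params.rate_multipliers is None:
                raise OntopartError("linkage requires rate multipliers")
            validate_multipliers(params.rate_multipliers, self.weights)
        if self.linkage.rates == "equal" and params.gamma_shape is not None:
            raise OntopartError("equal-rates linkage takes no gamma shape")
        per_char_logl = np.zeros(self.matrix.n_char)
        for p, groups in enumerate(self.partition_groups):
            partition_index = p if self.linkage.brlens == "unlinked" else 0
            rates = self._rates_for(p, params)
            for k, partials, cols in groups:
                all_logl = _prune_logliks(tree, partials, k, rates, partition_index)
                logl = all_logl[: len(cols)]
                const_logl = all_logl[len(cols):]
                m = const_logl.max()
                log_pconst = float(m + np.log(np.exp(const_logl - m).sum()))
                pconst = np.exp(min(log_pconst, 0.0))
                if pconst >= 1.0 - 1e-15:
                    # variability impossible (e.g. all branch lengths zero)
                    corrected = np.full(len(cols), LOG_ZERO)
                else:
                    corrected = logl - np.log1p(-pconst)
                per_char_logl[cols] = corrected
        total = float(per_char_logl.sum())
        if per_character:
            return total, per_char_logl
        return total


def dataset_log_likelihood(
    tree: PhyloTree,
    matrix,
    scheme,
    linkage: LinkageSpec,
    params: MkParameters,
    per_character: bool = False,
):
    """Mkv (variable-characters-only) log likelihood of a whole matrix.

    Each character is corrected with its own observed state count k_i,
    gamma mixture, partition multiplier and (when branch lengths are
    unlinked) partition-specific branch lengths.  Constant characters
    are rejected: they are inconsistent with variable-only coding.
    Convenience wrapper over :class:`MkvLikelihood`.
    """
    return MkvLikelihood(matrix, scheme, linkage).log_likelihood(
        tree, params, per_character=per_character
    )
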