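"""Parsimony scoring, search, tree statistics and instability profiling.

Characters are unordered (Fitch); missing cells are ambiguous over all
states and polymorphic cells over their listed states.  Implied
weighting uses the Goloboff fit written as a cost: a character with
``es`` extra steps on a tree contributes ``es / (es + k)``; lower totals
are better and large concavity constants ``k`` approach equal weights.

The search is random-addition Wagner trees followed by SPR swapping to a
local optimum ("TBR-lite": correctness of the scores, not reproduction
of any particular search engine, is the contract).  The taxon/character
instability profile is a simplified positional-congruence protocol:
rooted-triplet leaf stability averaged over tree pairs, iterative
pruning of the least stable leaf, and per-character step differences to
identify the characters supporting each instability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ontopart.errors import OntopartError
from ontopart.matrix_io import CharacterMatrix
from ontopart.trees import Node, PhyloTree

FULL_MASK = 0b111  # states 0..2


# ---------------------------------------------------------------------------
# Fitch scoring


def _column_masks(matrix: CharacterMatrix) -> dict:
    """taxon -> uint8 array of state bitmasks, one per character."""
    out = {}
    for i, taxon in enumerate(matrix.taxa):
        masks = np.empty(matrix.n_char, dtype=np.uint8)
        for j, cell in enumerate(matrix.data[i]):
            if cell is None:
                masks[j] = FULL_MASK
            else:
                m = 0
                for s in cell:
                    m |= 1 << s
                masks[j] = m
        out[taxon] = masks
    return out


def fitch_length(tree: PhyloTree, matrix: CharacterMatrix):
    """Minimum mutation count of every character on ``tree`` (Fitch).

    Returns ``(total, per_character)`` with ``per_character`` a numpy int
    array aligned with ``matrix.char_ids``.  Works on binary trees and on
    trees with a basal multifurcation (children folded sequentially,
    which preserves the unrooted score).
    """
    if set(t.taxon for t in tree.leaves()) != set(matrix.taxa):
        raise OntopartError("tree leaves do not match matrix taxa")
    leaf_masks = _column_masks(matrix)
    steps = np.zeros(matrix.n_char, dtype=np.int64)
    state: dict = {}
    for node in tree.postorder():
        if node.is_leaf:
            state[id(node)] = leaf_masks[node.taxon]
            continue
        children = [state.pop(id(c)) for c in node.children]
        acc = children[0]
        for other in children[1:]:
            inter = acc & other
            union = acc | other
            miss = inter == 0
            steps += miss
            acc = np.where(miss, union, inter).astype(np.uint8)
        state[id(node)] = acc
    return int(steps.sum()), steps


def min_steps(matrix: CharacterMatrix) -> np.ndarray:
    """Per-character minimum conceivable steps: observed states - 1."""
    return np.array(
        [max(len(matrix.observed_states(j)) - 1, 0) for j in range(matrix.n_char)]
    )


def max_steps(matrix: CharacterMatrix) -> np.ndarray:
    """Per-character maximum steps on any tree: n_obs - largest state
    class (polymorphic cells excluded from the tallies)."""
    out = np.zeros(matrix.n_char, dtype=np.int64)
    for j in range(matrix.n_char):
        tally: dict = {}
        n_obs = 0
        for cell in matrix.column(j):
            if cell is None or len(cell) != 1:
                continue
            n_obs += 1
            s = next(iter(cell))
            tally[s] = tally.get(s, 0) + 1
        out[j] = n_obs - max(tally.values()) if tally else 0
    return out


def implied_weights_score(tree: PhyloTree, matrix: CharacterMatrix, k: float) -> float:
    """Goloboff cost F = sum_i es_i / (es_i + k); lower is better."""
    if k <= 0:
        raise ValueError("concavity k must be positive")
    _, per_char = fitch_length(tree, matrix)
    es = per_char - min_steps(matrix)
    return float((es / (es + k)).sum())


# ---------------------------------------------------------------------------
# Tree statistics


@dataclass(frozen=True)
class TreeScore:
    """Length and homoplasy statistics of one tree.

    ``ci``/``ri`` are computed over all characters; the
    ``*_informative`` variants exclude parsimony-uninformative
    characters (the convention differs between programs, so both are
    reported).  ``fit`` is the implied-weights cost when a concavity was
    supplied.
    """

    length: int
    ci: float
    ri: float
    ci_informative: float
    ri_informative: float
    fit: float | None = None
    per_character: tuple = field(default=(), repr=False)


def tree_stats(tree: PhyloTree, matrix: CharacterMatrix, k: float | None = None) -> TreeScore:
    length, per_char = fitch_length(tree, matrix)
    m = min_steps(matrix)
    g = max_steps(matrix)

    def ci_ri(idx):
        L = int(per_char[idx].sum())
        mm = int(m[idx].sum())
        gg = int(g[idx].sum())
        ci = mm / L if L > 0 else 1.0
        ri = (gg - L) / (gg - mm) if gg > mm else 1.0
        return ci, ri

    every = np.arange(matrix.n_char)
    informative = np.array(
        [j for j in range(matrix.n_char) if _informative(matrix, j)], dtype=int
    )
    ci, ri = ci_ri(every)
    if informative.size:
        ci_inf, ri_inf = ci_ri(informative)
    else:
        ci_inf, ri_inf = 1.0, 1.0
    fit = None
    if k is not None:
        es = per_char - m
        fit = float((es / (es + k)).sum())
    return TreeScore(
        length=length,
        ci=ci,
        ri=ri,
        ci_informative=ci_inf,
        ri_informative=ri_inf,
        fit=fit,
        per_character=tuple(int(x) for x in per_char),
    )


def _informative(matrix, j) -> bool:
    tally: dict = {}
    for cell in matrix.column(j):
        if cell is None:
            continue
        for s in cell:
            tally[s] = tally.get(s, 0) + 1
    return sum(1 for c in tally.values() if c >= 2) >= 2


# ---------------------------------------------------------------------------
# Topology enumeration and rearrangement


def all_unrooted_topologies(taxa):
    """Yield every unrooted binary topology over ``taxa`` (as trees with
    a basal trifurcation); (2n-5)!! trees for n taxa."""
    taxa = list(taxa)
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa")

    def rec(tree_taxa_index):
        if tree_taxa_index == 3:
            root = Node()
            for t in taxa[:3]:
                root.add(Node(taxon=t, length=1.0))
            yield PhyloTree(root)
            return
        for smaller in rec(tree_taxa_index - 1):
            label = taxa[tree_taxa_index - 1]
            edges = smaller.edges()
            for i in range(len(edges)):
                tree = smaller.copy()
                target = tree.edges()[i]
                parent = target.parent
                mid = Node(length=1.0)
                parent.children[parent.children.index(target)] = mid
                mid.parent = parent
                mid.add(target)
                mid.add(Node(taxon=label, length=1.0))
                yield PhyloTree(tree.root)

    yield from rec(len(taxa))


def spr_neighbors(tree: PhyloTree):
    """All subtree-prune-regraft neighbours of ``tree`` (new copies).

    Pairs that would be no-ops (regrafting next to the original
    position) or invalid (regrafting inside the pruned subtree) are
    skipped; duplicates by unrooted topology may still occur and are the
    caller's concern.
    """
    n_nodes = len(list(tree.postorder()))
    for prune_idx in range(n_nodes):
        for graft_idx in range(n_nodes):
            if prune_idx == graft_idx:
                continue
            t = tree.copy()
            nodes = list(t.postorder())
            p, g = nodes[prune_idx], nodes[graft_idx]
            if p.parent is None or g.parent is None:
                continue
            anc = g
            inside = False
            while anc is not None:
                if anc is p:
                    inside = True
                    break
                anc = anc.parent
            if inside or g is p.parent:
                continue
            parent = p.parent
            parent.children.remove(p)
            p.parent = None
            if len(parent.children) == 1:
                only = parent.children[0]
                if g is parent:
                    continue  # graft edge vanished with the suppressed node
                if parent.parent is None:
                    only.parent = None  # old root dropped
                else:
                    gp = parent.parent
                    only.length = only.length + parent.length
                    only.parent = gp
                    gp.children[gp.children.index(parent)] = only
            if g.parent is None:
                continue  # nothing left to graft onto on that side
            gparent = g.parent
            mid = Node(length=g.length / 2)
            g.length = g.length / 2
            gparent.children[gparent.children.index(g)] = mid
            mid.parent = gparent
            mid.add(g)
            mid.add(p)
            root = mid
            while root.parent is not None:
                root = root.parent
            if root.is_leaf:
                continue
            yield PhyloTree(root)


# ---------------------------------------------------------------------------
# Heuristic search


@dataclass
class ParsimonyConfig:
    weighting: str = "equal"  # or "implied"
    k: float = 10.0
    n_replicates: int = 10
    max_trees: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.weighting not in {"equal", "implied"}:
            raise ValueError("weighting must be 'equal' or 'implied'")
        if self.k <= 0:
            raise ValueError("concavity k must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class SearchResult:
    trees: list
    score: float
    length: int
    truncated: bool
    stats: TreeScore


def _wagner_tree(matrix: CharacterMatrix, order, score_fn) -> PhyloTree:
    root = Node()
    for t in order[:3]:
        root.add(Node(taxon=t, length=1.0))
    tree = PhyloTree(root)
    for label in order[3:]:
        best, best_tree = None, None
        edges = tree.edges()
        for i in range(len(edges)):
            cand = tree.copy()
            target = cand.edges()[i]
            parent = target.parent
            mid = Node(length=1.0)
            parent.children[parent.children.index(target)] = mid
            mid.parent = parent
            mid.add(target)
            mid.add(Node(taxon=label, length=1.0))
            cand = PhyloTree(cand.root)
            partial = _restrict_matrix(matrix, cand.taxa)
            s = score_fn(cand, partial)
            if best is None or s < best - 1e-12:
                best, best_tree = s, cand
        tree = best_tree
    return tree


def _restrict_matrix(matrix: CharacterMatrix, taxa) -> CharacterMatrix:
    keep = set(taxa)
    idx = [i for i, t in enumerate(matrix.taxa) if t in keep]
    return CharacterMatrix(
        taxa=[matrix.taxa[i] for i in idx],
        data=[list(matrix.data[i]) for i in idx],
        char_ids=list(matrix.char_ids),
    )


def heuristic_search(matrix: CharacterMatrix, config: ParsimonyConfig) -> SearchResult:
    """Random-addition Wagner start + SPR swapping, pooled best trees.

    The pool holds every distinct unrooted topology attaining the best
    score found; ``truncated`` flags that the ``max_trees`` buffer
    filled.  Seed-reproducible.
    """
    if matrix.n_taxa < 4:
        raise OntopartError("need at least 4 taxa to search")
    rng = np.random.default_rng(config.seed)

    if config.weighting == "equal":
        def score_fn(tree, mat):
            return float(fitch_length(tree, mat)[0])
    else:
        def score_fn(tree, mat):
            return implied_weights_score(tree, mat, config.k)

    best_score = None
    pool: dict = {}
    truncated = False
    for _ in range(config.n_replicates):
        order = list(matrix.taxa)
        rng.shuffle(order)
        tree = _wagner_tree(matrix, order, score_fn)
        score = score_fn(tree, matrix)
        improved = True
        while improved:
            improved = False
            for nb in spr_neighbors(tree):
                s = score_fn(nb, matrix)
                if s < score - 1e-9:
                    tree, score = nb, s
                    improved = True
                    break
        if best_score is None or score < best_score - 1e-9:
            best_score = score
            pool = {tree.topology_key(): tree}
            truncated = False
        elif abs(score - best_score) <= 1e-9:
            if len(pool) < config.max_trees:
                pool.setdefault(tree.topology_key(), tree)
            else:
                truncated = True
        # collect equal-score SPR plateau neighbours of the final tree
        if abs(score - best_score) <= 1e-9:
            for nb in spr_neighbors(tree):
                if abs(score_fn(nb, matrix) - best_score) <= 1e-9:
                    if len(pool) < config.max_trees:
                        pool.setdefault(nb.topology_key(), nb)
                    else:
                        truncated = True

    trees = sorted(pool.values(), key=lambda t: t.to_newick())
    best_tree = trees[0]
    stats = tree_stats(
        best_tree, matrix, k=config.k if config.weighting == "implied" else None
    )
    return SearchResult(
        trees=trees,
        score=float(best_score),
        length=stats.length,
        truncated=truncated,
        stats=stats,
    )


def exhaustive_search(matrix: CharacterMatrix, weighting="equal", k=10.0):
    """Exact search over all unrooted topologies (oracle; tiny n only)."""
    best, best_trees = None, []
    for tree in all_unrooted_topologies(matrix.taxa):
        s = (
            float(fitch_length(tree, matrix)[0])
            if weighting == "equal"
            else implied_weights_score(tree, matrix, k)
        )
        if best is None or s < best - 1e-9:
            best, best_trees = s, [tree]
        elif abs(s - best) <= 1e-9:
            best_trees.append(tree)
    return best, best_trees


# ---------------------------------------------------------------------------
# Instability profiling


@dataclass
class InstabilityProfile:
    """Result of the iterative rogue-leaf analysis.

    ``unstable_leaves`` lists (taxon, stability-at-flag-time) in pruning
    order; ``character_frequencies`` maps character id -> number of
    unstable leaves whose instability the character supports;
    ``stable_taxa`` is the final retained taxon set.
    """

    unstable_leaves: list
    character_frequencies: dict
    stable_taxa: list


def _lca_depths(tree: PhyloTree, taxa_index: dict) -> np.ndarray:
    n = len(taxa_index)
    depth = np.zeros((n, n), dtype=np.int32)
    below: dict = {}
    node_depth: dict = {id(tree.root): 0}
    for node in tree.preorder():
        if node.parent is not None:
            node_depth[id(node)] = node_depth[id(node.parent)] + 1
    for node in tree.postorder():
        if node.is_leaf:
            idx = taxa_index.get(node.taxon)
            below[id(node)] = [] if idx is None else [idx]
            continue
        kids = [below.pop(id(c)) for c in node.children]
        d = node_depth[id(node)]
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                for x in kids[a]:
                    for y in kids[b]:
                        depth[x, y] = depth[y, x] = d
        merged = [x for kid in kids for x in kid]
        below[id(node)] = merged
    return depth


def _triplet_resolution(depth, x, y, z):
    """Which pair of {x,y,z} forms the cherry (deepest LCA); 0=xy,1=xz,2=yz,
    -1 = unresolved tie."""
    d = (depth[x, y], depth[x, z], depth[y, z])
    m = max(d)
    winners = [i for i, v in enumerate(d) if v == m]
    return winners[0] if len(winners) == 1 else -1


def leaf_stability(trees, max_pairs: int = 45) -> dict:
    """Per-leaf stability: mean over tree pairs of the fraction of
    rooted triplets containing the leaf that resolve identically.

    Trees are rerooted on a common reference leaf first so triplet
    comparisons are well-defined.
    """
    if len(trees) < 2:
        raise OntopartError("instability undefined for fewer than two trees")
    taxa = sorted(trees[0].taxa)
    for t in trees[1:]:
        if sorted(t.taxa) != taxa:
            raise OntopartError("trees share no common taxon set")
    ref = taxa[0]
    others = [t for t in taxa if t != ref]
    index = {t: i for i, t in enumerate(others)}
    depths = [_lca_depths(t.rerooted_at(ref), index) for t in trees]
    n = len(others)
    pairs = [
        (i, j)
        for i in range(len(trees))
        for j in range(i + 1, len(trees))
    ][:max_pairs]
    agree = {t: [] for t in others}
    for (i, j) in pairs:
        di, dj = depths[i], depths[j]
        for leaf in range(n):
            same = tot = 0
            for x in range(n):
                if x == leaf:
                    continue
                for y in range(x + 1, n):
                    if y == leaf:
                        continue
                    tot += 1
                    if _triplet_resolution(di, leaf, x, y) == _triplet_resolution(
                        dj, leaf, x, y
                    ):
                        same += 1
            agree[others[leaf]].append(same / tot if tot else 1.0)
    out = {t: float(np.mean(v)) for t, v in agree.items()}
    out[ref] = 1.0  # reference leaf anchors every comparison
    return out


def _restrict_tree(tree: PhyloTree, taxa) -> PhyloTree:
    keep = set(taxa)
    t = tree.copy()
    changed = True
    while changed:
        changed = False
        for leaf in t.leaves():
            if leaf.taxon not in keep:
                parent = leaf.parent
                parent.children.remove(leaf)
                changed = True
        # suppress unary internals
        for node in list(t.postorder()):
            if not node.is_leaf and len(node.children) == 1 and node.parent is not None:
                only = node.children[0]
                only.length = only.length + node.length
                only.parent = node.parent
                node.parent.children[node.parent.children.index(node)] = only
                changed = True
        root = t.root
        while not root.is_leaf and len(root.children) == 1:
            root = root.children[0]
            root.parent = None
            changed = True
        t = PhyloTree(root)
    return t


def instability_profile(
    matrix: CharacterMatrix,
    trees,
    stability_threshold: float = 0.9,
    max_pairs: int = 45,
) -> InstabilityProfile:
    """Iteratively detect rogue leaves and the characters supporting
    their instability (simplified positional-congruence protocol).

    A leaf is flagged when its triplet stability falls below
    ``stability_threshold``; after each flag the leaf is pruned from all
    trees and stabilities recomputed.  A character supports a flagged
    leaf's instability when its Fitch length differs between at least
    one pair of trees that disagree on the leaf's placement yet agree
    once the leaf is pruned.
    """
    if len(trees) < 2:
        raise OntopartError("instability undefined for fewer than two trees")
    current = list(trees)
    remaining = sorted(trees[0].taxa)
    unstable: list = []
    freq: dict = {}
    while len(remaining) > 4:
        stab = leaf_stability(current, max_pairs=max_pairs)
        worst = min(stab, key=lambda t: (stab[t], t))
        if stab[worst] >= stability_threshold:
            break
        unstable.append((worst, stab[worst]))
        implicated = _supporting_characters(matrix, current, worst, max_pairs)
        for cid in implicated:
            freq[cid] = freq.get(cid, 0) + 1
        remaining = [t for t in remaining if t != worst]
        current = [_restrict_tree(t, remaining) for t in current]
        # drop now-identical trees to keep the pair set meaningful
        seen = {}
        for t in current:
            seen.setdefault(t.topology_key(), t)
        current = list(seen.values())
        if len(current) < 2:
            break
    return InstabilityProfile(
        unstable_leaves=unstable,
        character_frequencies=dict(sorted(freq.items())),
        stable_taxa=remaining,
    )


def _supporting_characters(matrix, trees, leaf, max_pairs) -> set:
    reduced_taxa = [t for t in trees[0].taxa if t != leaf]
    reduced_matrix = _restrict_matrix(matrix, reduced_taxa)
    full_matrix = _restrict_matrix(matrix, trees[0].taxa)
    keys = [t.topology_key() for t in trees]
    reduced = [_restrict_tree(t, reduced_taxa) for t in trees]
    reduced_keys = [t.topology_key() for t in reduced]
    per_char = [fitch_length(t, full_matrix)[1] for t in trees]
    out: set = set()
    pairs = 0
    for i in range(len(trees)):
        for j in range(i + 1, len(trees)):
            if pairs >= max_pairs:
                return out
            if keys[i] == keys[j] or reduced_keys[i] != reduced_keys[j]:
                continue
            pairs += 1
            diff = np.nonzero(per_char[i] != per_char[j])[0]
            out.update(full_matrix.char_ids[d] for d in diff)
    return out
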