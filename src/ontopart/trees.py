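"""Rooted phylogenetic trees shared by the likelihood, MCMC, parsimony
and simulation modules.

A light mutable structure: nodes hold children, parent, a branch length
and (for leaves) a taxon label.  Branch lengths are scalars, or 1-D
arrays of per-partition lengths when branch lengths are unlinked across
partitions (all edges then carry arrays of the same length, indexing the
same partitions).

Newick parsing goes through dendropy; writing is a direct recursive
emitter so that per-partition length vectors can be selected.
"""

from __future__ import annotations

import numpy as np
import dendropy

from ontopart.errors import OntopartError


class Node:
    __slots__ = ("children", "parent", "length", "taxon", "support")

    def __init__(self, taxon=None, length=0.0):
        self.children: list = []
        self.parent = None
        self.length = length
        self.taxon = taxon
        self.support = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """Rooted tree over a fixed taxon set."""

    def __init__(self, root: Node):
        self.root = root
        labels = [leaf.taxon for leaf in self.leaves()]
        if any(lab is None for lab in labels):
            raise OntopartError("every leaf needs a taxon label")
        if len(set(labels)) != len(labels):
            raise OntopartError("duplicated leaf labels")
        self.taxa = sorted(labels)

    # -- traversal ------------------------------------------------------
    def postorder(self):
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def preorder(self):
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(node.children))
        return out

    def leaves(self):
        return [n for n in self.postorder() if n.is_leaf]

    def edges(self):
        """All non-root nodes (each owns the edge to its parent)."""
        return [n for n in self.postorder() if n.parent is not None]

    def internal_edges(self):
        return [n for n in self.edges() if not n.is_leaf]

    @property
    def n_leaves(self) -> int:
        return len(self.taxa)

    # -- copying --------------------------------------------------------
    def copy(self) -> "PhyloTree":
        def rec(node):
            length = node.length
            if isinstance(length, np.ndarray):
                length = length.copy()
            clone = Node(taxon=node.taxon, length=length)
            for child in node.children:
                clone.add(rec(child))
            return clone

        return PhyloTree(rec(self.root))

    # -- newick ---------------------------------------------------------
    def to_newick(self, partition: int | None = None) -> str:
        def blen(node):
            t = node.length
            if isinstance(t, np.ndarray):
                t = t[partition if partition is not None else 0]
            return f"{float(t):.10g}"

        def rec(node):
            if node.is_leaf:
                label = node.taxon
                if any(ch in label for ch in " (),:;"):
                    label = f"'{label}'"
                return f"{label}:{blen(node)}"
            inner = ",".join(rec(c) for c in node.children)
            if node.parent is None:
                return f"({inner})"
            return f"({inner}):{blen(node)}"

        return rec(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        dtree = dendropy.Tree.get(data=newick, schema="newick")

        def rec(dnode):
            taxon = dnode.taxon.label if dnode.taxon else None
            length = dnode.edge.length if dnode.edge.length is not None else 0.0
            node = Node(taxon=taxon, length=length)
            for dchild in dnode.child_nodes():
                node.add(rec(dchild))
            return node

        return cls(rec(dtree.seed_node))

    # -- splits ---------------------------------------------------------
    def bipartitions(self) -> frozenset:
        """Nontrivial splits of the unrooted topology, each encoded as the
        frozenset of taxa on the side not containing the reference taxon
        (the lexicographically smallest label)."""
        ref = self.taxa[0]
        full = frozenset(self.taxa)
        below: dict = {}
        splits = set()
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset({node.taxon})
            else:
                s = frozenset().union(*(below[id(c)] for c in node.children))
                below[id(node)] = s
                if node.parent is None:
                    continue
                side = full - s if ref in s else s
                if 2 <= len(side) <= len(full) - 2:
                    splits.add(side)
        return frozenset(splits)

    def topology_key(self) -> frozenset:
        """Unrooted-topology identity (set of nontrivial splits plus the
        taxon set, so trees over different leaf sets never compare equal)."""
        return frozenset({frozenset(self.taxa)}) | self.bipartitions()

    # -- rerooting ------------------------------------------------------
    def rerooted_at(self, taxon: str) -> "PhyloTree":
        """A new tree rooted in the middle of the edge leading to
        ``taxon``.

        Branch lengths are preserved edge-wise on the unrooted tree; the
        chosen leaf edge is split in half (likelihoods under a reversible
        chain do not depend on the split point).
        """
        nodes = list(self.postorder())
        adj: dict = {id(n): [] for n in nodes}
        for n in nodes:
            if n.parent is not None:
                adj[id(n)].append((n.parent, n.length))
                adj[id(n.parent)].append((n, n.length))
        leaf = next(n for n in nodes if n.taxon == taxon)
        if leaf.parent is None:
            return self.copy()
        half = leaf.length / 2

        def build(orig, came_from, length):
            clone = Node(taxon=orig.taxon, length=length)
            for nbr, ln in adj[id(orig)]:
                if nbr is came_from:
                    continue
                clone.add(build(nbr, orig, ln))
            return clone

        new_root = Node()
        new_root.add(Node(taxon=leaf.taxon, length=half))
        new_root.add(build(leaf.parent, leaf, half))
        _suppress_unary(new_root)
        return PhyloTree(new_root)


def _suppress_unary(root: Node) -> None:
    stack = [root]
    while stack:
        node = stack.pop()
        for child in list(node.children):
            while len(child.children) == 1:
                only = child.children[0]
                only.length = only.length + child.length
                only.parent = node
                node.children[node.children.index(child)] = only
                child = only
            stack.append(child)


def tree_from_splits(taxa, splits_with_support) -> "PhyloTree":
    """Build a rooted representation of the tree defined by a set of
    pairwise compatible splits (used by consensus construction).

    ``splits_with_support`` maps frozenset(taxa on one side) -> support;
    the support is attached to the created node's ``support`` slot.
    Splits incompatible with already-inserted ones are skipped.
    """
    root = Node()
    leaf_nodes = {}
    for t in sorted(taxa):
        leaf_nodes[t] = root.add(Node(taxon=t, length=1.0))
    for side in sorted(splits_with_support, key=len, reverse=True):
        # maximal current nodes whose clades sit fully inside the split
        tops = {}
        for t in side:
            n = leaf_nodes[t]
            while n.parent is not None and _clade_leafset(n.parent) <= side:
                n = n.parent
            tops[id(n)] = n
        tops = list(tops.values())
        parent_ids = {id(n.parent) for n in tops}
        covered = frozenset().union(*(_clade_leafset(n) for n in tops))
        if len(parent_ids) != 1 or covered != side:
            continue  # incompatible with what is already inserted
        parent = tops[0].parent
        new = Node(length=1.0)
        new.support = splits_with_support[side]
        for n in tops:
            parent.children.remove(n)
            new.add(n)
        parent.add(new)
    return PhyloTree(root)


def _clade_leafset(node: Node) -> frozenset:
    out = set()
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.add(n.taxon)
        stack.extend(n.children)
    return frozenset(out)
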