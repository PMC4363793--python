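"""Anatomy-ontology graphs and hierarchical partition schemes.

A *part_of* relation table (entity, parent) over anatomical regions and
characters is translated into a rooted graph: internal nodes are regions,
tips are characters.  The **elementary categories** are the regions whose
children are all characters — the finest anatomical grouping the ontology
offers.  A **hierarchical cut** is a partition of the characters in which
every block is the complete tip set of one node of the graph; cuts are the
partition schemes the Bayesian model comparison ranges over.

Regions may have several parents (a rooted DAG): overlapping
supercategories such as "wing apparatus + pterothorax" and
"thorax + legs" are anatomically natural and both can license blocks.
Characters belong to exactly one region and the graph must be acyclic
with a single root.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import pandas as pd

from ontopart.errors import CoverageError, CycleError, RelationError

CHAR_PATTERN = re.compile(r"^c(\d+)$")


@dataclass
class RelationTable:
    """Rows of (entity, parent) *part_of* pairs.

    Characters are written ``c<ID>`` (1-based); everything else is a
    region name.  Exactly one entity (the root, e.g. ``body``) appears
    only as a parent.
    """

    rows: list  # list[(entity, parent)]

    @classmethod
    def from_csv(cls, path) -> "RelationTable":
        df = pd.read_csv(path)
        cols = [c.lower() for c in df.columns]
        if cols[:2] != ["entity", "parent"]:
            raise RelationError("relation CSV must have header 'entity,parent'")
        return cls(rows=[(str(a).strip(), str(b).strip()) for a, b in df.values])

    def to_csv(self, path) -> None:
        pd.DataFrame(self.rows, columns=["entity", "parent"]).to_csv(path, index=False)


@dataclass(frozen=True)
class PartitionScheme:
    """A disjoint cover of the character set by labelled blocks."""

    id: str
    blocks: tuple  # tuple[(label, frozenset[int]), ...]

    @property
    def n_partitions(self) -> int:
        return len(self.blocks)

    @property
    def labels(self) -> list:
        return [lab for lab, _ in self.blocks]

    @property
    def block_sets(self) -> list:
        return [chars for _, chars in self.blocks]

    def characters(self) -> frozenset:
        out = frozenset()
        for _, chars in self.blocks:
            out |= chars
        return out

    def block_of(self, char_id: int) -> int:
        """Index of the block containing ``char_id``."""
        for i, (_, chars) in enumerate(self.blocks):
            if char_id in chars:
                return i
        raise KeyError(char_id)

    def key(self) -> frozenset:
        """Label-independent identity: the set of block character sets."""
        return frozenset(chars for _, chars in self.blocks)

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "blocks": [
                {"label": lab, "chars": sorted(chars)} for lab, chars in self.blocks
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PartitionScheme":
        return cls(
            id=str(d["id"]),
            blocks=tuple(
                (b["label"], frozenset(b["chars"])) for b in d["blocks"]
            ),
        )


@dataclass
class OntologyGraph:
    """Rooted tree-like graph of regions with characters at the tips."""

    graph: nx.DiGraph  # edges parent -> child
    root: str
    characters: frozenset  # character ids (ints)
    elementary: list  # elementary-category names, table order
    tip_sets: dict  # node name -> frozenset of character ids
    designated_schemes: list | None = None  # curated published selection
    _category_sets: dict = field(default_factory=dict, repr=False)

    def elementary_tip_sets(self) -> dict:
        return {name: self.tip_sets[name] for name in self.elementary}

    def block_label(self, categories) -> str:
        """'+'-joined category names in elementary (table) order."""
        order = {name: i for i, name in enumerate(self.elementary)}
        return "+".join(sorted(categories, key=order.__getitem__))

    def node_category_set(self, node: str) -> frozenset | None:
        """The elementary categories whose union is ``node``'s tip set, or
        None when the tip set is not a union of complete categories."""
        if node in self._category_sets:
            return self._category_sets[node]
        tips = self.tip_sets[node]
        cats = [c for c in self.elementary if self.tip_sets[c] & tips]
        union = frozenset().union(*(self.tip_sets[c] for c in cats)) if cats else frozenset()
        result = frozenset(cats) if union == tips and tips else None
        self._category_sets[node] = result
        return result


def build_graph(table: RelationTable, matrix) -> OntologyGraph:
    """Translate a *part_of* relation table into an :class:`OntologyGraph`.

    ``matrix`` supplies the character ids the tips must cover (a
    :class:`~ontopart.matrix_io.CharacterMatrix` or any object with a
    ``char_ids`` attribute).
    """
    g = nx.DiGraph()
    parents: dict = {}
    for entity, parent in table.rows:
        if not entity or not parent:
            raise RelationError(f"blank entity/parent in row {(entity, parent)!r}")
        parents.setdefault(entity, set()).add(parent)
        g.add_edge(parent, entity)

    for entity, ps in parents.items():
        if CHAR_PATTERN.match(entity) and len(ps) > 1:
            raise RelationError(
                f"character {entity} has multiple parents: {sorted(ps)}"
            )

    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        path = " -> ".join(a for a, _ in cycle) + " -> " + cycle[-1][1]
        raise CycleError(f"relation table contains a cycle: {path}")

    roots = [n for n in g.nodes if g.in_degree(n) == 0]
    if len(roots) != 1:
        raise RelationError(f"expected exactly one root, found {sorted(roots)}")
    root = roots[0]

    tip_entities = {n for n in g.nodes if CHAR_PATTERN.match(n)}
    for tip in tip_entities:
        if g.out_degree(tip):
            raise RelationError(f"character {tip} used as a parent")
    char_of = {tip: int(CHAR_PATTERN.match(tip).group(1)) for tip in tip_entities}

    matrix_chars = frozenset(matrix.char_ids)
    graph_chars = frozenset(char_of.values())
    missing = matrix_chars - graph_chars
    if missing:
        raise CoverageError(
            f"characters absent from the relation table: {sorted(missing)}"
        )

    tip_sets = {}
    for node in g.nodes:
        if node in tip_entities:
            tip_sets[node] = frozenset({char_of[node]})
        else:
            tip_sets[node] = frozenset(
                char_of[d] for d in nx.descendants(g, node) if d in tip_entities
            )

    # elementary categories: regions whose children are all characters,
    # in order of first appearance in the table
    elementary = []
    for _, parent in table.rows:
        if parent in tip_entities or parent in elementary:
            continue
        children = list(g.successors(parent))
        if children and all(c in tip_entities for c in children):
            elementary.append(parent)

    elem_union: set = set()
    for name in elementary:
        if tip_sets[name] & elem_union:
            raise RelationError(
                f"elementary categories overlap at {name!r}"
            )
        elem_union |= tip_sets[name]
    if elem_union != set(graph_chars):
        raise CoverageError(
            "elementary-category tip sets do not partition the characters"
        )

    return OntologyGraph(
        graph=g,
        root=root,
        characters=graph_chars,
        elementary=elementary,
        tip_sets=tip_sets,
    )


# ---------------------------------------------------------------------------
# Scheme enumeration and validation


def _candidate_blocks(graph: OntologyGraph) -> dict:
    """Map frozenset-of-categories -> representative node name, for every
    node whose tip set is a union of complete elementary categories."""
    out: dict = {}
    for node in graph.graph.nodes:
        if CHAR_PATTERN.match(node):
            continue
        cats = graph.node_category_set(node)
        if cats:
            out.setdefault(cats, node)
    return out


def _exact_covers(universe: tuple, blocks: list):
    """All exact covers of ``universe`` (tuple of category names) using
    ``blocks`` (frozensets of category names).  Backtracking on the first
    uncovered category."""
    by_cat: dict = {c: [] for c in universe}
    for b in blocks:
        for c in b:
            by_cat[c].append(b)

    def rec(remaining: frozenset):
        if not remaining:
            yield []
            return
        first = next(c for c in universe if c in remaining)
        for b in by_cat[first]:
            if b <= remaining:
                for rest in rec(remaining - b):
                    yield [b] + rest

    yield from rec(frozenset(universe))


def _scheme_from_category_blocks(graph, cat_blocks, scheme_id) -> PartitionScheme:
    blocks = []
    for cats in cat_blocks:
        chars = frozenset().union(*(graph.tip_sets[c] for c in cats))
        blocks.append((graph.block_label(cats), chars))
    order = {name: i for i, name in enumerate(graph.elementary)}
    blocks.sort(key=lambda b: min(order[c] for c in b[0].split("+")))
    return PartitionScheme(id=str(scheme_id), blocks=tuple(blocks))


def enumerate_schemes(graph: OntologyGraph, policy: str = "auto") -> list:
    """Enumerate partition schemes licensed by the ontology graph.

    ``policy="all"`` returns every hierarchical cut: each block is the
    complete tip set of one graph node, blocks partition the characters;
    deduplicated and canonically ordered (number of partitions
    descending, then lexicographic block labels).  The fully split
    elementary scheme and the single-block scheme are always present
    (the root and the elementary categories are nodes).

    ``policy="designated"`` returns the curated scheme selection the
    graph carries (e.g. the published nine-scheme set of the Scarabaeinae
    study fixture), validated against the graph.  ``policy="auto"``
    (default) uses the designated selection when present, otherwise all
    cuts.
    """
    if policy not in {"auto", "all", "designated"}:
        raise ValueError(f"unknown policy {policy!r}")
    if policy == "designated" and graph.designated_schemes is None:
        raise ValueError("graph carries no designated schemes")
    if policy in {"auto", "designated"} and graph.designated_schemes is not None:
        schemes = []
        for i, groups in enumerate(graph.designated_schemes, start=1):
            cat_blocks = [frozenset(g) for g in groups]
            scheme = _scheme_from_category_blocks(graph, cat_blocks, i)
            ok, diag = validate_scheme(scheme, graph)
            if not ok:
                raise RelationError(
                    f"designated scheme {i} is not a hierarchical cut: {diag}"
                )
            schemes.append(scheme)
        return schemes

    blocks = list(_candidate_blocks(graph))
    universe = tuple(graph.elementary)
    seen = set()
    raw = []
    for cover in _exact_covers(universe, blocks):
        key = frozenset(cover)
        if key in seen:
            continue
        seen.add(key)
        raw.append(cover)
    raw.sort(
        key=lambda cover: (
            -len(cover),
            sorted(graph.block_label(c) for c in cover),
        )
    )
    return [
        _scheme_from_category_blocks(graph, cover, i)
        for i, cover in enumerate(raw, start=1)
    ]


def validate_scheme(scheme: PartitionScheme, graph: OntologyGraph):
    """Check that ``scheme`` is a hierarchical cut of ``graph``.

    Returns ``(ok, diagnostics)``; diagnostics name blocks that are not
    the complete tip set of any node, and coverage/disjointness defects.
    """
    diagnostics = []
    node_tip_sets = {
        graph.tip_sets[n]
        for n in graph.graph.nodes
        if not CHAR_PATTERN.match(n)
    }
    for lab, chars in scheme.blocks:
        if not chars:
            diagnostics.append(f"block {lab!r} is empty")
        elif chars not in node_tip_sets:
            diagnostics.append(f"block {lab!r} is not the tip set of any node")
    for (la, a), (lb, b) in combinations(scheme.blocks, 2):
        if a & b:
            diagnostics.append(f"blocks {la!r} and {lb!r} overlap")
    if scheme.characters() != graph.characters:
        diagnostics.append("blocks do not cover the character set")
    return (not diagnostics, diagnostics)


def schemes_to_json(schemes, path) -> None:
    with open(path, "w") as fh:
        json.dump([s.to_dict() for s in schemes], fh, indent=1)


def schemes_from_json(path) -> list:
    with open(path) as fh:
        return [PartitionScheme.from_dict(d) for d in json.load(fh)]
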