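"""Synthetic trees, ontologies and partitioned Mkv matrices with known truth.

The generator emulates the data-generating process the inference modules
assume: a rooted binary tree with exponential branch lengths, characters
evolved under the k-state Mk model with discrete-gamma among-character
rates, per-partition rate multipliers with weighted mean one, optional
per-partition branch-length scalings, rejection conditioning on
variability (matrix contains no constant characters, matching the Mkv
ascertainment assumption exactly), and optional post-hoc injection of
autapomorphic characters.

It also ships the Scarabaeinae ontology fixture: the eleven elementary
anatomical categories with their published character assignments (205
characters total) and the nine published partition schemes designated on
the graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import dendropy

from ontopart.errors import SimulationError
from ontopart.matrix_io import CharacterMatrix
from ontopart.mk_model import discrete_gamma_rates, transition_matrix
from ontopart.ontology import OntologyGraph, RelationTable, build_graph
from ontopart.trees import Node, PhyloTree

# ---------------------------------------------------------------------------
# Scarabaeinae fixture: elementary categories and their character ids.
# Category order follows the published scheme listing, so that merged
# block labels read ES+SG+GC+AS, E+W+Pt, M+H, Pt+Pr+L.

SCARABAEINAE_CATEGORIES = {
    "ES": list(range(20, 53)) + list(range(57, 65)),  # endophallic sclerites
    "SG": list(range(53, 57)),                        # spiculum gastrale
    "GC": list(range(1, 20)),                         # genital capsule
    "AS": list(range(193, 206)),                      # abdominal sternites
    "E": list(range(65, 96)),                         # elytra
    "W": list(range(96, 117)),                        # wings
    "Pt": list(range(183, 193)),                      # pterothorax
    "M": list(range(117, 147)),                       # mouthparts
    "H": list(range(147, 157)),                       # head
    "Pr": list(range(157, 167)),                      # prothorax
    "L": list(range(167, 183)),                       # legs
}

#: The nine published partition schemes as groups of elementary categories.
SCARABAEINAE_SCHEMES = [
    [["ES"], ["SG"], ["GC"], ["AS"], ["E"], ["W"], ["Pt"], ["M"], ["H"], ["Pr"], ["L"]],
    [["ES"], ["SG"], ["GC"], ["AS"], ["E", "W", "Pt"], ["M", "H"], ["Pr"], ["L"]],
    [["ES", "SG", "GC"], ["AS"], ["E", "W", "Pt"], ["M", "H"], ["Pr"], ["L"]],
    [["ES", "SG", "GC", "AS"], ["E", "W"], ["Pt"], ["M", "H"], ["Pr"], ["L"]],
    [["ES", "SG", "GC", "AS"], ["E"], ["W"], ["Pt"], ["M", "H"], ["Pr"], ["L"]],
    [["ES", "SG", "GC", "AS"], ["E", "W", "Pt"], ["M"], ["H"], ["Pr"], ["L"]],
    [["ES", "SG", "GC", "AS"], ["E", "W"], ["M", "H"], ["Pt", "Pr", "L"]],
    [["ES", "SG", "GC", "AS"], ["E", "W", "Pt"], ["M", "H"], ["Pr"], ["L"]],
    [["ES", "SG", "GC", "AS", "E", "W", "Pt", "M", "H", "Pr", "L"]],
]

# region structure above the categories; Pt sits under both the wing
# apparatus supercategory and the thorax+legs supercategory (rooted DAG)
_SCARABAEINAE_REGIONS = [
    ("ES", "aedeagus"),
    ("SG", "aedeagus"),
    ("GC", "aedeagus"),
    ("aedeagus", "abdomen"),
    ("AS", "abdomen"),
    ("E", "wing_set"),
    ("W", "wing_set"),
    ("wing_set", "pterothorax_region"),
    ("Pt", "pterothorax_region"),
    ("Pt", "thorax_legs"),
    ("Pr", "thorax_legs"),
    ("L", "thorax_legs"),
    ("M", "head_region"),
    ("H", "head_region"),
    ("abdomen", "body"),
    ("head_region", "body"),
    ("pterothorax_region", "body"),
    ("thorax_legs", "body"),
]


def ontology_fixture(style: str = "scarabaeinae", categories: dict | None = None,
                     table: RelationTable | None = None) -> RelationTable:
    """A *part_of* relation table.

    ``scarabaeinae``: the packaged fixture (205 characters, 11
    categories, DAG of supercategories).  ``star``: the given
    ``categories`` (name -> list of character ids) directly under the
    root.  ``custom``: return ``table`` unchanged.
    """
    if style == "scarabaeinae":
        rows = []
        for cat, chars in SCARABAEINAE_CATEGORIES.items():
            rows.extend((f"c{cid}", cat) for cid in chars)
        rows.extend(_SCARABAEINAE_REGIONS)
        return RelationTable(rows=rows)
    if style == "star":
        if not categories:
            raise ValueError("star style needs a categories mapping")
        rows = []
        for cat, chars in categories.items():
            rows.extend((f"c{cid}", cat) for cid in chars)
        rows.extend((cat, "body") for cat in categories)
        return RelationTable(rows=rows)
    if style == "custom":
        if table is None:
            raise ValueError("custom style needs a table")
        return table
    raise ValueError(f"unknown fixture style {style!r}")


class _CharIds:
    def __init__(self, char_ids):
        self.char_ids = list(char_ids)


def scarabaeinae_graph(char_ids=None) -> OntologyGraph:
    """The fixture ontology graph with the nine published schemes
    designated on it."""
    if char_ids is None:
        char_ids = range(1, 206)
    graph = build_graph(ontology_fixture("scarabaeinae"), _CharIds(char_ids))
    graph.designated_schemes = SCARABAEINAE_SCHEMES
    return graph


# ---------------------------------------------------------------------------
# Simulation


@dataclass
class SimulationSpec:
    """Conditions for one synthetic dataset.

    ``partition_sizes`` gives the number of characters per partition;
    ``rate_multipliers`` must have character-count-weighted mean one.
    ``gamma_shape`` is None (equal rates), a float (shared) or a
    per-partition sequence.  ``branch_scalings`` optionally scales all
    branch lengths per partition (unlinked branch lengths truth).
    ``prop_three_state`` is the fraction of characters evolved with
    three states.  ``autapomorphy_fraction`` is the target fraction of
    autapomorphic characters injected post hoc.
    """

    n_taxa: int = 8
    tree_model: str = "uniform"  # or "yule"
    branch_rate: float = 10.0    # exponential rate; mean length 0.1
    partition_sizes: tuple = (100,)
    rate_multipliers: tuple | None = None
    gamma_shape: object = None
    n_gamma_categories: int = 4
    branch_scalings: tuple | None = None
    prop_three_state: float = 0.0
    autapomorphy_fraction: float = 0.0
    condition_on_variable: bool = True
    rejection_cap: int = 10000
    seed: int = 0

    def __post_init__(self):
        sizes = np.asarray(self.partition_sizes)
        if self.rate_multipliers is not None:
            w = sizes / sizes.sum()
            m = np.asarray(self.rate_multipliers, dtype=float)
            if abs(float(w @ m) - 1.0) > 1e-9:
                raise ValueError("rate multipliers must have weighted mean 1")
        if not 0 <= self.prop_three_state <= 1:
            raise ValueError("prop_three_state must be in [0,1]")
        if not 0 <= self.autapomorphy_fraction <= 1:
            raise ValueError("autapomorphy_fraction must be in [0,1]")

    @property
    def n_char(self) -> int:
        return int(sum(self.partition_sizes))


def simulate_tree(spec: SimulationSpec, rng: np.random.Generator | None = None) -> PhyloTree:
    """A random rooted binary tree over taxa t1..tN.

    ``uniform``: leaves are attached one by one to a uniformly chosen
    edge, branch lengths iid Exponential(``branch_rate``).  ``yule``: a
    pure-birth tree (unit birth rate) whose branch lengths are rescaled
    to mean ``1/branch_rate``.
    """
    if spec.n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    labels = [f"t{i+1}" for i in range(spec.n_taxa)]
    if spec.tree_model == "yule":
        tns = dendropy.TaxonNamespace(labels)
        dtree = dendropy.model.birthdeath.birth_death_tree(
            birth_rate=1.0,
            death_rate=0.0,
            num_extant_tips=spec.n_taxa,
            taxon_namespace=tns,
            rng=_PyRandom(rng),
        )
        tree = PhyloTree.from_newick(dtree.as_string(schema="newick"))
        lengths = [e.length for e in tree.edges()]
        mean = float(np.mean([t for t in lengths if t > 0])) or 1.0
        target = 1.0 / spec.branch_rate
        for e in tree.edges():
            e.length = float(e.length) * target / mean
        return tree
    if spec.tree_model != "uniform":
        raise ValueError(f"unknown tree model {spec.tree_model!r}")

    root = Node()
    root.add(Node(taxon=labels[0], length=1.0))
    root.add(Node(taxon=labels[1], length=1.0))
    tree = PhyloTree(root)
    for label in labels[2:]:
        edges = tree.edges()
        target = edges[rng.integers(len(edges))]
        parent = target.parent
        mid = Node(length=1.0)
        parent.children[parent.children.index(target)] = mid
        mid.parent = parent
        mid.add(target)
        mid.add(Node(taxon=label, length=1.0))
        tree = PhyloTree(root)
    # lengths drawn only after the topology is fixed, so every edge
    # (internal ones included) is iid Exponential(branch_rate)
    for e in tree.edges():
        e.length = float(rng.exponential(1.0 / spec.branch_rate))
    return tree


class _PyRandom:
    """Adapter exposing the stdlib-random surface dendropy's simulators
    use, backed by a numpy Generator."""

    def __init__(self, rng):
        self._rng = rng

    def random(self):
        return float(self._rng.random())

    def uniform(self, a, b):
        return float(self._rng.uniform(a, b))

    def expovariate(self, lambd):
        return float(self._rng.exponential(1.0 / lambd))

    def gauss(self, mu, sigma):
        if sigma == 0:
            return float(mu)
        return float(self._rng.normal(mu, sigma))

    def randint(self, a, b):
        return int(self._rng.integers(a, b + 1))

    def sample(self, population, k):
        population = list(population)
        idx = self._rng.choice(len(population), size=k, replace=False)
        return [population[i] for i in idx]

    def choice(self, seq):
        seq = list(seq)
        return seq[int(self._rng.integers(len(seq)))]

    def shuffle(self, seq):
        self._rng.shuffle(seq)


def _simulate_column(tree, k, eff_rate, scaling, rng):
    """Evolve one character down the tree; returns taxon -> state."""
    states = {}
    out = {}
    for node in tree.preorder():
        if node.parent is None:
            states[id(node)] = int(rng.integers(k))
        else:
            t = float(node.length) * scaling * eff_rate
            P = transition_matrix(k, t)
            prev = states[id(node.parent)]
            states[id(node)] = int(rng.choice(k, p=P[prev]))
        if node.is_leaf:
            out[node.taxon] = states[id(node)]
    return out


def simulate_matrix(tree: PhyloTree, spec: SimulationSpec,
                    rng: np.random.Generator | None = None):
    """Simulate a character matrix on ``tree`` under ``spec``.

    Returns ``(matrix, truth)`` where ``truth`` records the partition,
    state count, gamma-category rate and rejection count of every
    character, plus the :class:`SimulationSpec`-level parameters.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    taxa = sorted(tree.taxa)
    n_p = len(spec.partition_sizes)
    multipliers = (
        np.asarray(spec.rate_multipliers, dtype=float)
        if spec.rate_multipliers is not None
        else np.ones(n_p)
    )
    scalings = (
        np.asarray(spec.branch_scalings, dtype=float)
        if spec.branch_scalings is not None
        else np.ones(n_p)
    )

    def rates_for(p: int) -> np.ndarray:
        if spec.gamma_shape is None:
            return np.ones(1)
        shape = (
            float(spec.gamma_shape)
            if np.isscalar(spec.gamma_shape)
            else float(spec.gamma_shape[p])
        )
        return discrete_gamma_rates(shape, spec.n_gamma_categories)

    columns = []
    truth_chars = []
    for p, size in enumerate(spec.partition_sizes):
        cat_rates = rates_for(p)
        for _ in range(size):
            k = 3 if rng.random() < spec.prop_three_state else 2
            attempts = 0
            while True:
                attempts += 1
                r = float(cat_rates[rng.integers(len(cat_rates))])
                col = _simulate_column(
                    tree, k, r * multipliers[p], scalings[p], rng
                )
                if not spec.condition_on_variable or len(set(col.values())) > 1:
                    break
                if attempts >= spec.rejection_cap:
                    raise SimulationError(
                        f"variability rejection cap hit in partition {p} "
                        "(signal too weak)"
                    )
            columns.append(col)
            truth_chars.append(
                {"partition": p, "k": k, "rate": r, "attempts": attempts}
            )

    data = [
        [frozenset({col[t]}) for col in columns]
        for t in taxa
    ]
    matrix = CharacterMatrix(taxa=taxa, data=data)
    n_aut = _inject_autapomorphies(matrix, spec.autapomorphy_fraction, rng)
    truth = {
        "tree_newick": tree.to_newick(),
        "partition_sizes": list(spec.partition_sizes),
        "rate_multipliers": multipliers.tolist(),
        "branch_scalings": scalings.tolist(),
        "gamma_shape": spec.gamma_shape
        if spec.gamma_shape is None or np.isscalar(spec.gamma_shape)
        else list(spec.gamma_shape),
        "characters": truth_chars,
        "n_injected_autapomorphies": n_aut,
    }
    return matrix, truth


def _char_state_counts(matrix, j):
    tally = {}
    for cell in matrix.column(j):
        if cell is None:
            continue
        for s in cell:
            tally[s] = tally.get(s, 0) + 1
    return tally


def _is_autapomorphic(tally) -> bool:
    return len(tally) >= 2 and sum(1 for c in tally.values() if c >= 2) < 2


def _inject_autapomorphies(matrix, fraction, rng) -> int:
    """Convert informative characters into autapomorphic ones until the
    target fraction is met: all carriers of the rarest state but one are
    recoded to the majority state (variability preserved)."""
    if fraction <= 0:
        return 0
    target = int(round(fraction * matrix.n_char))
    current = [
        j for j in range(matrix.n_char)
        if _is_autapomorphic(_char_state_counts(matrix, j))
    ]
    need = target - len(current)
    if need <= 0:
        return 0
    informative = [
        j for j in range(matrix.n_char)
        if j not in set(current) and len(_char_state_counts(matrix, j)) >= 2
    ]
    rng.shuffle(informative)
    done = 0
    for j in informative:
        if done >= need:
            break
        tally = _char_state_counts(matrix, j)
        minor = min(tally, key=tally.get)
        major = max(tally, key=tally.get)
        carriers = [
            i for i in range(matrix.n_taxa)
            if matrix.data[i][j] == frozenset({minor})
        ]
        keep = carriers[int(rng.integers(len(carriers)))]
        for i in carriers:
            if i != keep:
                matrix.data[i][j] = frozenset({major})
        done += 1
    return done


# ---------------------------------------------------------------------------
# Study-shaped stand-in matrix


def study_shaped_matrix(seed: int = 0) -> CharacterMatrix:
    """A synthetic stand-in with the shape of the study's supplementary
    matrix: 110 taxa, 205 characters, exactly 29 parsimony-uninformative
    (autapomorphic) characters, characters 181 and 182 three-state, a
    sprinkling of missing cells.  Synthetic data — the cell values are
    simulated, only the summary shape mirrors the real matrix.
    """
    rng = np.random.default_rng(seed)
    spec = SimulationSpec(
        n_taxa=110,
        partition_sizes=(205,),
        gamma_shape=0.8,
        branch_rate=10.0,
        condition_on_variable=True,
        seed=seed,
    )
    tree = simulate_tree(spec, rng)
    matrix, _ = simulate_matrix(tree, spec, rng)

    # characters 181/182 carry a third state on two taxa each
    for cid in (181, 182):
        j = cid - 1
        rows = rng.choice(matrix.n_taxa, size=2, replace=False)
        for i in rows:
            matrix.data[i][j] = frozenset({2})

    # force exactly 29 autapomorphic characters
    def groups():
        aut, inf = [], []
        for j in range(matrix.n_char):
            tally = _char_state_counts(matrix, j)
            (aut if _is_autapomorphic(tally) else inf).append(j)
        return aut, inf

    aut, inf = groups()
    protected = {180, 181}
    while len(aut) > 29:
        j = next(x for x in aut if x not in protected)
        # give the rarest state a second carrier -> informative
        tally = _char_state_counts(matrix, j)
        minor = min(tally, key=tally.get)
        non_carriers = [
            i for i in range(matrix.n_taxa)
            if matrix.data[i][j] is not None and minor not in matrix.data[i][j]
        ]
        matrix.data[int(rng.choice(non_carriers))][j] = frozenset({minor})
        aut, inf = groups()
    while len(aut) < 29:
        j = next(x for x in inf if x not in protected)
        tally = _char_state_counts(matrix, j)
        minor = min(tally, key=tally.get)
        major = max(tally, key=tally.get)
        carriers = [
            i for i in range(matrix.n_taxa)
            if matrix.data[i][j] == frozenset({minor})
        ]
        for i in carriers[1:]:
            matrix.data[i][j] = frozenset({major})
        aut, inf = groups()

    # missing cells that cannot change any classification: only overwrite
    # majority-state cells with at least 3 carriers
    n_missing = int(0.05 * matrix.n_taxa * matrix.n_char)
    for _ in range(n_missing):
        i = int(rng.integers(matrix.n_taxa))
        j = int(rng.integers(matrix.n_char))
        cell = matrix.data[i][j]
        if cell is None or len(cell) != 1:
            continue
        s = next(iter(cell))
        tally = _char_state_counts(matrix, j)
        if tally.get(s, 0) >= max(tally.values()) and tally[s] > 3:
            matrix.data[i][j] = None
    return matrix
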