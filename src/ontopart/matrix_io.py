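"""Discrete morphological character matrices: NEXUS I/O and bookkeeping.

The dialect supported is the one standard for morphology: a DATA or
CHARACTERS block with ``FORMAT SYMBOLS="012" MISSING=? GAP=-`` and a
non-interleaved MATRIX of single-symbol cells.  Cells may be ``?`` or
``-`` (both treated as missing) or a polymorphism set ``{01}``.  Larger
symbol alphabets are rejected: the models downstream are defined for
two- and three-state unordered characters only.

Character identifiers are 1-based everywhere user-facing and survive
column exclusion, so per-character reports keep the numbering of the
original matrix.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from ontopart.errors import DimensionError, NexusParseError, OntopartError

ALLOWED_SYMBOLS = "012"
MISSING_SYMBOLS = "?-"

#: Cell representation: frozenset of integer states; ``None`` = missing.
Cell = "frozenset[int] | None"


@dataclass
class CharacterMatrix:
    """Taxa x characters grid of discrete states with missing data.

    ``data[i][j]`` is a frozenset of integer states for taxon ``i`` and
    column ``j`` (singleton for a plain score, larger for a polymorphic
    cell) or ``None`` for missing.  ``char_ids[j]`` is the 1-based
    identifier of column ``j``; after :func:`exclude_characters` these
    are no longer consecutive.
    """

    taxa: list[str]
    data: list[list[frozenset | None]]
    char_ids: list[int] = field(default_factory=list)

    def __post_init__(self):
        if not self.char_ids:
            self.char_ids = list(range(1, self.n_char + 1))
        self.validate()

    # -- basic geometry -------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_char(self) -> int:
        return len(self.data[0]) if self.data else 0

    def validate(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            raise OntopartError("duplicated taxon labels")
        if len(self.data) != len(self.taxa):
            raise DimensionError(
                f"{len(self.taxa)} taxa but {len(self.data)} matrix rows"
            )
        widths = {len(row) for row in self.data}
        if len(widths) > 1:
            raise DimensionError(f"rows of unequal length: {sorted(widths)}")
        if len(self.char_ids) != self.n_char:
            raise DimensionError(
                f"{len(self.char_ids)} character ids for {self.n_char} columns"
            )
        if len(set(self.char_ids)) != len(self.char_ids):
            raise OntopartError("duplicated character ids")
        if any(cid < 1 for cid in self.char_ids):
            raise OntopartError("character ids must be 1-based positive")
        nmax = len(ALLOWED_SYMBOLS)
        for row in self.data:
            for cell in row:
                if cell is None:
                    continue
                if not cell or any(s < 0 or s >= nmax for s in cell):
                    raise OntopartError(f"cell states {set(cell)} outside 0..{nmax-1}")

    # -- per-character views --------------------------------------------
    def column(self, j: int) -> list:
        """Column ``j`` (0-based position) as a list of cells."""
        return [row[j] for row in self.data]

    def column_by_id(self, char_id: int) -> list:
        return self.column(self.char_ids.index(char_id))

    def observed_states(self, j: int) -> set:
        """Distinct states observed in column ``j``, unions of polymorphic
        cells included, missing ignored."""
        out: set = set()
        for cell in self.column(j):
            if cell is not None:
                out |= cell
        return out

    @property
    def n_states_per_char(self) -> list[int]:
        """Observed-state count k_j per column (>= 1; >= 2 once constant
        characters are filtered out)."""
        return [max(len(self.observed_states(j)), 1) for j in range(self.n_char)]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CharacterMatrix)
            and self.taxa == other.taxa
            and self.char_ids == other.char_ids
            and self.data == other.data
        )


@dataclass(frozen=True)
class CharacterClassification:
    """Per-character labels and summary counts.

    Labels: ``constant`` (at most one distinct state observed),
    ``parsimony_informative`` (at least two states each present in >= 2
    taxa), ``autapomorphic_uninformative`` (anything else — variable but
    unable to group taxa under parsimony).
    """

    labels: dict  # char_id -> label
    n_constant: int
    n_autapomorphic: int
    n_informative: int

    @property
    def n_uninformative(self) -> int:
        """Parsimony-uninformative count (constant + autapomorphic)."""
        return self.n_constant + self.n_autapomorphic


# ---------------------------------------------------------------------------
# NEXUS reading


def _parse_cells(line: str, lineno: int) -> list:
    cells = []
    i = 0
    while i < len(line):
        ch = line[i]
        if ch.isspace():
            i += 1
            continue
        if ch in MISSING_SYMBOLS:
            cells.append(None)
            i += 1
        elif ch in ALLOWED_SYMBOLS:
            cells.append(frozenset({int(ch)}))
            i += 1
        elif ch in "{(":
            close = "}" if ch == "{" else ")"
            j = line.find(close, i)
            if j < 0:
                raise NexusParseError(f"line {lineno}: unterminated polymorphism set")
            states = set()
            for sym in line[i + 1 : j]:
                if sym.isspace() or sym == ",":
                    continue
                if sym not in ALLOWED_SYMBOLS:
                    raise NexusParseError(
                        f"line {lineno}: symbol {sym!r} not in {ALLOWED_SYMBOLS!r}"
                    )
                states.add(int(sym))
            if not states:
                raise NexusParseError(f"line {lineno}: empty polymorphism set")
            cells.append(frozenset(states))
            i = j + 1
        else:
            raise NexusParseError(
                f"line {lineno}: symbol {ch!r} not in {ALLOWED_SYMBOLS!r}"
            )
    return cells


def read_nexus(path) -> CharacterMatrix:
    """Read a morphological matrix from a NEXUS DATA/CHARACTERS block.

    Raises :class:`NexusParseError` on malformed content (the message
    names the line) and :class:`DimensionError` when the declared
    NTAX/NCHAR disagree with the matrix body.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()

    # strip [..] comments (single-line; the dialect needs no more)
    lines = [re.sub(r"\[[^\]]*\]", "", ln) for ln in lines]

    ntax = nchar = None
    in_matrix = False
    taxa: list[str] = []
    rows: list[list] = []
    saw_block = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        upper = line.upper()
        if upper.startswith("BEGIN") and ("DATA" in upper or "CHARACTERS" in upper):
            saw_block = True
            continue
        m = re.search(r"\bNTAX\s*=\s*(\d+)", upper)
        if m:
            ntax = int(m.group(1))
        m = re.search(r"\bNCHAR\s*=\s*(\d+)", upper)
        if m:
            nchar = int(m.group(1))
        if upper.startswith("FORMAT"):
            m = re.search(r'SYMBOLS\s*=\s*"([^"]*)"', line, flags=re.I)
            if m and any(s not in ALLOWED_SYMBOLS for s in m.group(1).replace(" ", "")):
                raise NexusParseError(
                    f"line {lineno}: symbol set {m.group(1)!r} not supported "
                    f"(only {ALLOWED_SYMBOLS!r})"
                )
            continue
        if upper.startswith("MATRIX"):
            in_matrix = True
            continue
        if in_matrix:
            if line == ";" or upper.startswith("END"):
                in_matrix = False
                continue
            body = line[:-1] if line.endswith(";") else line
            parts = body.split(None, 1)
            if len(parts) < 2:
                raise NexusParseError(f"line {lineno}: matrix row without states")
            label = parts[0].strip("'\"")
            taxa.append(label)
            rows.append(_parse_cells(parts[1], lineno))
            if line.endswith(";"):
                in_matrix = False

    if not saw_block or not rows:
        raise NexusParseError("no DATA/CHARACTERS block with a MATRIX found")
    if ntax is None or nchar is None:
        raise NexusParseError("DIMENSIONS with NTAX and NCHAR required")
    if len(taxa) != ntax:
        raise DimensionError(f"NTAX={ntax} but {len(taxa)} rows in matrix")
    for label, row in zip(taxa, rows):
        if len(row) != nchar:
            raise DimensionError(
                f"NCHAR={nchar} but taxon {label!r} has {len(row)} states"
            )
    return CharacterMatrix(taxa=taxa, data=rows)


def write_nexus(matrix: CharacterMatrix, path) -> None:
    """Write ``matrix`` so that :func:`read_nexus` round-trips it.

    Note: 1-based character ids surviving a previous exclusion are
    recorded in a ``[charids ...]`` comment and are NOT recovered by
    ``read_nexus`` (NEXUS has no standard slot for them).
    """
    symbols = "".join(
        sorted({str(s) for j in range(matrix.n_char) for s in matrix.observed_states(j)})
    ) or "01"

    def fmt(cell) -> str:
        if cell is None:
            return "?"
        if len(cell) == 1:
            return str(next(iter(cell)))
        return "{" + "".join(str(s) for s in sorted(cell)) + "}"

    width = max((len(t) for t in matrix.taxa), default=1) + 2
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN DATA;\n")
        fh.write(f"    DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_char};\n")
        fh.write(f'    FORMAT DATATYPE=STANDARD SYMBOLS="{symbols}" MISSING=? GAP=-;\n')
        if matrix.char_ids != list(range(1, matrix.n_char + 1)):
            fh.write(f"    [charids {' '.join(map(str, matrix.char_ids))}]\n")
        fh.write("    MATRIX\n")
        for label, row in zip(matrix.taxa, matrix.data):
            safe = f"'{label}'" if re.search(r"\s", label) else label
            fh.write(f"    {safe:<{width}}{''.join(fmt(c) for c in row)}\n")
        fh.write("    ;\nEND;\n")


# ---------------------------------------------------------------------------
# Classification and exclusion


def classify_characters(matrix: CharacterMatrix) -> CharacterClassification:
    """Label every character as constant, autapomorphic-uninformative or
    parsimony-informative.

    A character is parsimony-informative iff at least two distinct states
    each occur in two or more taxa (missing ignored; a polymorphic cell
    counts toward each of its states).
    """
    labels = {}
    counts = {"constant": 0, "autapomorphic_uninformative": 0, "parsimony_informative": 0}
    for j, cid in enumerate(matrix.char_ids):
        tally: dict = {}
        for cell in matrix.column(j):
            if cell is None:
                continue
            for s in cell:
                tally[s] = tally.get(s, 0) + 1
        if len(tally) <= 1:
            label = "constant"
        elif sum(1 for c in tally.values() if c >= 2) >= 2:
            label = "parsimony_informative"
        else:
            label = "autapomorphic_uninformative"
        labels[cid] = label
        counts[label] += 1
    return CharacterClassification(
        labels=labels,
        n_constant=counts["constant"],
        n_autapomorphic=counts["autapomorphic_uninformative"],
        n_informative=counts["parsimony_informative"],
    )


def exclude_characters(matrix: CharacterMatrix, ids) -> CharacterMatrix:
    """Drop the columns with the given 1-based ids; remaining characters
    keep their original identifiers."""
    ids = set(ids)
    unknown = ids - set(matrix.char_ids)
    if unknown:
        raise KeyError(f"unknown character ids: {sorted(unknown)}")
    keep = [j for j, cid in enumerate(matrix.char_ids) if cid not in ids]
    return CharacterMatrix(
        taxa=list(matrix.taxa),
        data=[[row[j] for j in keep] for row in matrix.data],
        char_ids=[matrix.char_ids[j] for j in keep],
    )
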