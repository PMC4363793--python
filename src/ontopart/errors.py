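"""Exception hierarchy shared across the package."""


class OntopartError(Exception):
    """Base class for all package errors."""


class NexusParseError(OntopartError):
    """Malformed NEXUS content; message names the offending line."""


class DimensionError(OntopartError):
    """NTAX/NCHAR declarations disagree with the matrix body."""


class RelationError(OntopartError):
    """Invalid *part_of* relation table (bad parent structure)."""


class CycleError(RelationError):
    """Relation table contains a cycle; message lists the path."""


class CoverageError(RelationError):
    """Characters missing from the ontology; message lists ids."""


class AdmissibilityError(OntopartError):
    """Linkage combination not admissible for the partition scheme."""


class AscertainmentError(OntopartError):
    """Constant character under variable-only (Mkv) coding."""


class ComparabilityError(OntopartError):
    """Quantities from incompatible dataset variants were compared."""


class SimulationError(OntopartError):
    """Synthetic-data generation failed (e.g. rejection cap exceeded)."""
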