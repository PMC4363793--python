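"""Parameter–partition model enumeration and parameter counting.

A model is a partition scheme plus a **linkage specification** saying
how the partitions share parameters:

* branch lengths: ``linked`` (one relative branch-length set for all
  partitions) or ``unlinked`` (one per partition);
* rate multiplier: ``absent`` (all partitions evolve at the same average
  rate) or ``unlinked`` (per-partition relative rates constrained to
  weighted mean one);
* among-character rate variation: ``equal``, ``shared_gamma`` (one gamma
  shape for all partitions) or ``per_partition_gamma``.

The free-parameter count is ``B + R + G`` with ``B = 1`` (linked) or
``P`` (unlinked) branch-length blocks, ``R = 0`` or ``P`` multipliers,
and ``G = 0``, ``1`` or ``P`` gamma shapes — branch lengths counted as
one block per partition, which is the convention that reproduces the
published per-model counts.

The twelve combinations are numbered by fixed slots; for multi-partition
schemes the two fully linked no-multiplier slots (1 and 3) are dropped
because they are observationally identical to the corresponding
unpartitioned models, leaving ten; a single-partition scheme admits
exactly slots 1 and 3.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from ontopart.errors import AdmissibilityError
from ontopart.ontology import PartitionScheme

BRLENS = ("linked", "unlinked")
MULTIPLIER = ("absent", "unlinked")
RATES = ("equal", "shared_gamma", "per_partition_gamma")

#: slot number (1..12) -> (brlens, rate_multiplier, rates)
SLOT_TABLE = {
    m * 6 + r * 2 + b + 1: (BRLENS[b], MULTIPLIER[m], RATES[r])
    for m in range(2)
    for r in range(3)
    for b in range(2)
}
SLOT_OF = {spec: slot for slot, spec in SLOT_TABLE.items()}

#: slots whose likelihood structure differs from an unpartitioned model
MULTI_PARTITION_SLOTS = (2, 4, 5, 6, 7, 8, 9, 10, 11, 12)
SINGLE_PARTITION_SLOTS = (1, 3)


@dataclass(frozen=True)
class LinkageSpec:
    brlens: str = "linked"
    rate_multiplier: str = "absent"
    rates: str = "equal"

    def __post_init__(self):
        if self.brlens not in BRLENS:
            raise ValueError(f"brlens must be one of {BRLENS}")
        if self.rate_multiplier not in MULTIPLIER:
            raise ValueError(f"rate_multiplier must be one of {MULTIPLIER}")
        if self.rates not in RATES:
            raise ValueError(f"rates must be one of {RATES}")

    @property
    def slot(self) -> int:
        return SLOT_OF[(self.brlens, self.rate_multiplier, self.rates)]


def check_admissible(scheme: PartitionScheme, linkage: LinkageSpec) -> None:
    """Raise :class:`AdmissibilityError` if the linkage makes no sense
    for the scheme's partition count."""
    if scheme.n_partitions == 1:
        if (
            linkage.brlens != "linked"
            or linkage.rate_multiplier != "absent"
            or linkage.rates == "per_partition_gamma"
        ):
            raise AdmissibilityError(
                f"linkage {linkage} not admissible for a single-partition scheme"
            )


def count_parameters(scheme: PartitionScheme, linkage: LinkageSpec) -> int:
    """Free-parameter count B + R + G of the model (see module docstring)."""
    check_admissible(scheme, linkage)
    p = scheme.n_partitions
    b = 1 if linkage.brlens == "linked" else p
    r = 0 if linkage.rate_multiplier == "absent" else p
    g = {"equal": 0, "shared_gamma": 1, "per_partition_gamma": p}[linkage.rates]
    return b + r + g


@dataclass(frozen=True)
class ModelDescriptor:
    """A scheme, a linkage, and the derived parameter count.

    ``id`` follows the "scheme.slot" convention, e.g. ``"8.11"``.
    ``autapomorphy_variant`` tags which dataset variant the model is run
    on ("with" or "without" autapomorphic characters); it is a dataset
    tag, not a parameter.
    """

    id: str
    scheme: PartitionScheme
    linkage: LinkageSpec
    param_count: int
    autapomorphy_variant: str = "with"

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "scheme": self.scheme.to_dict(),
            "linkage": {
                "brlens": self.linkage.brlens,
                "rate_multiplier": self.linkage.rate_multiplier,
                "rates": self.linkage.rates,
            },
            "param_count": self.param_count,
            "autapomorphy_variant": self.autapomorphy_variant,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelDescriptor":
        return cls(
            id=d["id"],
            scheme=PartitionScheme.from_dict(d["scheme"]),
            linkage=LinkageSpec(**d["linkage"]),
            param_count=d["param_count"],
            autapomorphy_variant=d.get("autapomorphy_variant", "with"),
        )


def enumerate_models(schemes, autapomorphy_variant: str = "with") -> list:
    """Enumerate the admissible, non-degenerate models over ``schemes``.

    Multi-partition schemes get the ten linkage slots that are not
    observationally identical to an unpartitioned model; a
    single-partition scheme gets slots 1 and 3.  Over the nine
    Scarabaeinae schemes this yields 8 x 10 + 2 = 82 models.
    """
    if not schemes:
        raise ValueError("schemes must be nonempty")
    if len({s.key() for s in schemes}) != len(schemes):
        raise ValueError("schemes must be deduplicated")
    models = []
    for scheme in schemes:
        slots = (
            SINGLE_PARTITION_SLOTS
            if scheme.n_partitions == 1
            else MULTI_PARTITION_SLOTS
        )
        for slot in slots:
            linkage = LinkageSpec(*SLOT_TABLE[slot])
            models.append(
                ModelDescriptor(
                    id=f"{scheme.id}.{slot}",
                    scheme=scheme,
                    linkage=linkage,
                    param_count=count_parameters(scheme, linkage),
                    autapomorphy_variant=autapomorphy_variant,
                )
            )
    return models


def models_to_json(models, path) -> None:
    with open(path, "w") as fh:
        json.dump([m.to_dict() for m in models], fh, indent=1)


def models_from_json(path) -> list:
    with open(path) as fh:
        return [ModelDescriptor.from_dict(d) for d in json.load(fh)]


def models_to_tsv(models) -> str:
    """TSV mirroring the published model-table columns."""
    lines = [
        "PS\tNoP\tID\tbrlens\trate_multiplier\trates\tn_parameters"
    ]
    for m in models:
        lines.append(
            "\t".join(
                [
                    str(m.scheme.id),
                    str(m.scheme.n_partitions),
                    m.id,
                    m.linkage.brlens,
                    m.linkage.rate_multiplier,
                    m.linkage.rates,
                    str(m.param_count),
                ]
            )
        )
    return "\n".join(lines) + "\n"
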