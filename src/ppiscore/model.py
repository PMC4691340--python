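"""Shared data model for interaction records and canonical binary interactions.

Every pipeline stage operates on these types. Raw source records
(:class:`InteractionRecord`) carry participants with experimental roles and
per-row evidence; after integration they collapse into canonical
:class:`BinaryInteraction` objects keyed by an unordered pair of accessions
with merged, publication-unique evidence.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

__all__ = [
    "MoleculeKind",
    "Role",
    "ProteinRef",
    "EvidenceItem",
    "InteractionRecord",
    "BinaryInteraction",
    "MalformedRecordError",
    "pair_key",
    "merge_evidence",
]


class MalformedRecordError(ValueError):
    """A record violates a structural invariant (empty ID, bad taxon...)."""


class MoleculeKind(enum.Enum):
    PROTEIN = "protein"
    NON_PROTEIN = "non_protein"


class Role(enum.Enum):
    BAIT = "bait"
    PREY = "prey"
    NEUTRAL = "neutral"


@dataclass(frozen=True)
class ProteinRef:
    """One interaction participant as found in a source record.

    ``source_id`` is the accession exactly as the source gave it;
    ``canonical_id`` is filled in by the ID-mapping step. ``taxon`` is the
    NCBI taxonomy ID and must be positive — records without a usable taxon
    are rejected at parse time because the cross-species filter needs it.
    """

    source_id: str
    taxon: int
    canonical_id: str | None = None
    molecule_kind: MoleculeKind = MoleculeKind.PROTEIN
    role: Role = Role.NEUTRAL
    id_db: str = ""

    def __post_init__(self) -> None:
        if not self.source_id:
            raise MalformedRecordError("participant with empty source_id")
        if self.canonical_id is not None and not self.canonical_id:
            raise MalformedRecordError("canonical_id present but empty")
        if self.taxon <= 0:
            raise MalformedRecordError(
                f"participant {self.source_id!r} has non-positive taxon {self.taxon}"
            )


@dataclass(frozen=True)
class EvidenceItem:
    """Evidence from one publication supporting an interaction.

    ``interaction_types`` and ``detection_methods`` are controlled-vocabulary
    term names (the sentinel ``"unknown"`` replaces invalid terms). ``scale``
    is the number of associations that publication reported, used downstream
    to split small-scale (<=100) from high-throughput evidence.
    """

    pubmed_id: str
    interaction_types: frozenset[str]
    detection_methods: frozenset[str]
    scale: int = 1
    source_dbs: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.pubmed_id:
            raise MalformedRecordError("evidence with empty pubmed_id")
        if not self.interaction_types or not self.detection_methods:
            raise MalformedRecordError(
                f"evidence {self.pubmed_id}: empty type or method set"
            )
        if self.scale < 1:
            raise MalformedRecordError(
                f"evidence {self.pubmed_id}: scale {self.scale} < 1"
            )

    def with_scale(self, scale: int) -> "EvidenceItem":
        return replace(self, scale=scale)


@dataclass
class InteractionRecord:
    """A raw source record: a binary pair or an n-ary complex."""

    participants: list[ProteinRef]
    evidence: list[EvidenceItem]
    source_db: str

    def __post_init__(self) -> None:
        if not self.participants:
            raise MalformedRecordError("record with no participants")

    @property
    def is_complex(self) -> bool:
        return len(self.participants) > 2

    def baits(self) -> list[ProteinRef]:
        return [p for p in self.participants if p.role is Role.BAIT]

    def preys(self) -> list[ProteinRef]:
        return [p for p in self.participants if p.role is not Role.BAIT]


def pair_key(a: str, b: str) -> tuple[str, str]:
    """Order-invariant canonical key for an unordered protein pair.

    ``pair_key(a, b) == pair_key(b, a)``; self-pairs map to ``(a, a)``.
    Realizes the rule that interactions duplicated across sources (in either
    participant order) are one interaction.
    """
    if not a or not b:
        raise MalformedRecordError("pair_key requires two non-empty IDs")
    return (a, b) if a <= b else (b, a)


def merge_evidence(items: Iterable[EvidenceItem]) -> list[EvidenceItem]:
    """Collapse evidence to one item per distinct Pubmed ID.

    Types, methods and source databases are set-unions over all inputs with
    that Pubmed ID; ``scale`` is the maximum (conservative toward the
    high-throughput label). Output is sorted by pubmed_id, so merging is
    deterministic and idempotent.
    """
    by_pubmed: dict[str, list[EvidenceItem]] = {}
    for it in items:
        by_pubmed.setdefault(it.pubmed_id, []).append(it)
    merged: list[EvidenceItem] = []
    for pubmed in sorted(by_pubmed):
        group = by_pubmed[pubmed]
        merged.append(
            EvidenceItem(
                pubmed_id=pubmed,
                interaction_types=frozenset().union(
                    *(g.interaction_types for g in group)
                ),
                detection_methods=frozenset().union(
                    *(g.detection_methods for g in group)
                ),
                scale=max(g.scale for g in group),
                source_dbs=frozenset().union(*(g.source_dbs for g in group)),
            )
        )
    return merged


@dataclass
class BinaryInteraction:
    """Canonical unordered protein pair with merged evidence.

    Both members share ``taxon``; ``evidence`` holds exactly one item per
    distinct Pubmed ID (enforced by construction through
    :func:`merge_evidence`).
    """

    pair: tuple[str, str]
    taxon: int
    evidence: list[EvidenceItem] = field(default_factory=list)

    @classmethod
    def build(
        cls,
        a: str,
        b: str,
        taxon: int,
        evidence: Sequence[EvidenceItem] = (),
    ) -> "BinaryInteraction":
        return cls(pair=pair_key(a, b), taxon=taxon, evidence=merge_evidence(evidence))

    @property
    def n_publications(self) -> int:
        return len(self.evidence)

    def n_small_scale(self, cutoff: int = 100) -> int:
        return sum(1 for e in self.evidence if e.scale <= cutoff)

    def add_evidence(self, items: Iterable[EvidenceItem]) -> None:
        self.evidence = merge_evidence([*self.evidence, *items])
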