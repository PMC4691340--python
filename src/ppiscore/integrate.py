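"""Integration of raw source records into deduplicated binary interactions.

The pipeline mirrors the curation flow used by consolidated interaction
databases: n-ary complexes are expanded to binary pairs with the spoke model,
non-physical evidence and non-protein or cross-species pairs are filtered,
identifiers are remapped to canonical accessions, duplicates across sources
are merged, and species with too few interactions are dropped. Every
expanded pair is accounted for exactly once — either in the accepted set or
in the reject report under a single reason.

Stage order (fixed): spoke expansion -> term normalization -> physicality
filter -> protein/same-species filter -> canonicalization -> deduplication ->
species threshold. The order affects only reject attribution, never the
final interaction set.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .config import PipelineConfig, Vocabulary, default_config
from .model import (
    BinaryInteraction,
    EvidenceItem,
    InteractionRecord,
    MoleculeKind,
    ProteinRef,
    Role,
    merge_evidence,
    pair_key,
)

__all__ = [
    "FilterReport",
    "PairRecord",
    "spoke_expand",
    "normalize_terms",
    "filter_physical",
    "filter_protein_same_species",
    "canonicalize",
    "deduplicate",
    "species_threshold",
    "integrate_records",
]

REASONS = (
    "non_protein",
    "cross_species",
    "indirect_type",
    "genetic_method",
    "no_bait_complex",
    "unmappable_id",
    "duplicate",
    "species_below_threshold",
)


@dataclass
class FilterReport:
    """Audit trail of the integration run.

    ``counters`` counts expanded pairs per rejection reason; ``accepted`` is
    the number of surviving unique interactions, so
    ``accepted + sum(counters) == total expanded pairs``. The reject list and
    term-remap events replace the manual-curation checkpoints of the original
    workflow with an auditable log.
    """

    counters: Counter = field(default_factory=Counter)
    rejected: list[tuple[tuple[str, str], str]] = field(default_factory=list)
    accepted: int = 0
    expanded: int = 0
    term_remap_events: int = 0
    census: list[tuple[int, int, bool]] = field(default_factory=list)

    def reject(self, pair: tuple[str, str], reason: str) -> None:
        assert reason in REASONS, reason
        self.counters[reason] += 1
        self.rejected.append((pair, reason))

    def conserved(self) -> bool:
        return self.accepted + sum(self.counters.values()) == self.expanded


@dataclass
class PairRecord:
    """One expanded binary pair awaiting filtering/canonicalization."""

    a: ProteinRef
    b: ProteinRef
    evidence: list[EvidenceItem]
    source_db: str

    def source_pair(self) -> tuple[str, str]:
        return pair_key(self.a.source_id, self.b.source_id)


def spoke_expand(record: InteractionRecord) -> list[PairRecord]:
    """Expand a record into binary pairs under the spoke model.

    Binary records (and declared self-interactions) pass through unchanged.
    Complexes pair each prey with the bait; with k >= 2 baits all C(k,2)
    bait-bait pairs are also emitted (multiple baits are assumed to bind each
    other). No prey-prey pairs are ever produced. A complex without any bait
    yields an empty list — the caller records it as ``no_bait_complex``.
    """
    ps = record.participants
    if len(ps) == 1:  # declared self-interaction
        return [PairRecord(ps[0], ps[0], list(record.evidence), record.source_db)]
    baits = [p for p in ps if p.role is Role.BAIT]
    # two participants: a plain binary record unless it is a role-annotated
    # co-purification fragment without a bait (prey-only -> no-bait complex)
    if len(ps) == 2:
        if baits or all(p.role is Role.NEUTRAL for p in ps):
            return [PairRecord(ps[0], ps[1], list(record.evidence), record.source_db)]
        return []
    if not baits:
        return []
    preys = [p for p in ps if p.role is not Role.BAIT]
    pairs = [
        PairRecord(b1, b2, list(record.evidence), record.source_db)
        for b1, b2 in itertools.combinations(baits, 2)
    ]
    pairs.extend(
        PairRecord(b, p, list(record.evidence), record.source_db)
        for b in baits
        for p in preys
    )
    return pairs


def normalize_terms(
    pair: PairRecord, vocabulary: Vocabulary
) -> tuple[PairRecord, int]:
    """Replace invalid CV terms with "unknown"; returns (pair, remap count)."""
    remaps = 0
    new_evidence = []
    for ev in pair.evidence:
        types = set()
        for t in ev.interaction_types:
            if vocabulary.is_valid_type(t):
                types.add(t)
            else:
                types.add("unknown")
                remaps += 1
        methods = set()
        for m in ev.detection_methods:
            if vocabulary.is_valid_method(m):
                methods.add(m)
            else:
                methods.add("unknown")
                remaps += 1
        new_evidence.append(
            EvidenceItem(
                pubmed_id=ev.pubmed_id,
                interaction_types=frozenset(types),
                detection_methods=frozenset(methods),
                scale=ev.scale,
                source_dbs=ev.source_dbs,
            )
        )
    pair.evidence = new_evidence
    return pair, remaps


def _evidence_passes_physical(ev: EvidenceItem, vocabulary: Vocabulary) -> tuple[bool, str]:
    """Check one evidence item against the physicality rules.

    The interaction type must be in the physical whitelist — or "unknown",
    which the curation flow retains and scores poorly rather than discarding.
    Methods in the excluded list (genetic interference) are pruned; evidence
    left without any method fails.
    """
    acceptable_types = vocabulary.physical_types | {"unknown"}
    if not (ev.interaction_types & acceptable_types):
        return False, "indirect_type"
    if not (ev.detection_methods - vocabulary.excluded_methods):
        return False, "genetic_method"
    return True, ""


def filter_physical(
    pair: PairRecord, vocabulary: Vocabulary
) -> tuple[PairRecord | None, str]:
    """Keep a pair if at least one evidence item is physical.

    Failing evidence items are pruned from kept pairs; a pair left with no
    evidence is rejected with the reason of its first failing item
    (``indirect_type`` before ``genetic_method``).
    """
    kept: list[EvidenceItem] = []
    reasons: list[str] = []
    for ev in pair.evidence:
        ok, reason = _evidence_passes_physical(ev, vocabulary)
        if ok:
            methods = ev.detection_methods - vocabulary.excluded_methods
            if methods != ev.detection_methods:
                ev = EvidenceItem(
                    pubmed_id=ev.pubmed_id,
                    interaction_types=ev.interaction_types,
                    detection_methods=frozenset(methods),
                    scale=ev.scale,
                    source_dbs=ev.source_dbs,
                )
            kept.append(ev)
        else:
            reasons.append(reason)
    if not kept:
        reason = "indirect_type" if "indirect_type" in reasons else "genetic_method"
        return None, reason
    pair.evidence = kept
    return pair, ""


def filter_protein_same_species(pair: PairRecord) -> tuple[PairRecord | None, str]:
    """Keep only protein-protein pairs whose participants share a taxon."""
    if (
        pair.a.molecule_kind is not MoleculeKind.PROTEIN
        or pair.b.molecule_kind is not MoleculeKind.PROTEIN
    ):
        return None, "non_protein"
    if pair.a.taxon != pair.b.taxon:
        return None, "cross_species"
    return pair, ""


def canonicalize(
    pair: PairRecord, id_mapping: Mapping[str, str]
) -> tuple[tuple[str, str] | None, str]:
    """Map both source IDs to canonical accessions via the mapping table.

    IDs absent from the table are rejected (``unmappable_id``) — the manual
    confirmation step of the original workflow becomes an auditable reject.
    """
    ca = id_mapping.get(pair.a.source_id)
    cb = id_mapping.get(pair.b.source_id)
    if ca is None or cb is None:
        return None, "unmappable_id"
    return pair_key(ca, cb), ""


def deduplicate(
    canonical_pairs: Iterable[tuple[tuple[str, str], int, list[EvidenceItem]]],
    report: FilterReport | None = None,
) -> list[BinaryInteraction]:
    """Group canonical pairs by key and merge their evidence.

    Input items are ``(pair_key, taxon, evidence)``. Output is sorted by pair
    key; every pair beyond the first with a given key counts as ``duplicate``
    in the report.
    """
    groups: dict[tuple[str, str], tuple[int, list[EvidenceItem]]] = {}
    for key, taxon, evidence in canonical_pairs:
        if key in groups:
            if report is not None:
                report.reject(key, "duplicate")
            groups[key] = (groups[key][0], groups[key][1] + list(evidence))
        else:
            groups[key] = (taxon, list(evidence))
    return [
        BinaryInteraction(pair=key, taxon=taxon, evidence=merge_evidence(ev))
        for key, (taxon, ev) in sorted(groups.items())
    ]


def species_threshold(
    interactions: Sequence[BinaryInteraction],
    min_count: int = 10,
    report: FilterReport | None = None,
) -> list[BinaryInteraction]:
    """Drop all interactions of any taxon with fewer than ``min_count``.

    The census (taxon, count, retained) is recorded in the report.
    """
    counts = Counter(i.taxon for i in interactions)
    retained_taxa = {t for t, c in counts.items() if c >= min_count}
    if report is not None:
        report.census = [
            (t, c, t in retained_taxa) for t, c in sorted(counts.items())
        ]
        for i in interactions:
            if i.taxon not in retained_taxa:
                report.reject(i.pair, "species_below_threshold")
    return [i for i in interactions if i.taxon in retained_taxa]


def integrate_records(
    records: Iterable[InteractionRecord],
    id_mapping: Mapping[str, str],
    *,
    min_species_count: int = 10,
    pubmed_scales: Mapping[str, int] | None = None,
    config: PipelineConfig | None = None,
) -> tuple[list[BinaryInteraction], FilterReport]:
    """Run the full integration pipeline over raw records.

    Returns the deduplicated, species-thresholded interactions (sorted by
    pair key) and the filter report. ``pubmed_scales`` attaches the
    per-publication association count to evidence (default scale 1). The
    result is invariant under permutation of the input records and stable
    under re-integration of its own output.
    """
    cfg = config or default_config()
    vocabulary = cfg.vocabulary
    report = FilterReport()
    surviving: list[tuple[tuple[str, str], int, list[EvidenceItem]]] = []

    for record in records:
        pairs = spoke_expand(record)
        if not pairs:
            report.expanded += 1
            report.reject(
                pair_key(
                    record.participants[0].source_id,
                    record.participants[0].source_id,
                ),
                "no_bait_complex",
            )
            continue
        for pair in pairs:
            report.expanded += 1
            pair, remaps = normalize_terms(pair, vocabulary)
            report.term_remap_events += remaps
            kept, reason = filter_physical(pair, vocabulary)
            if kept is None:
                report.reject(pair.source_pair(), reason)
                continue
            kept2, reason = filter_protein_same_species(kept)
            if kept2 is None:
                report.reject(pair.source_pair(), reason)
                continue
            key, reason = canonicalize(kept2, id_mapping)
            if key is None:
                report.reject(pair.source_pair(), reason)
                continue
            evidence = kept2.evidence
            if pubmed_scales:
                evidence = [
                    ev.with_scale(pubmed_scales.get(ev.pubmed_id, ev.scale))
                    for ev in evidence
                ]
            surviving.append((key, kept2.a.taxon, evidence))

    # sort before grouping so dedup (and hence everything downstream) is
    # independent of input record order
    surviving.sort(key=lambda t: (t[0], t[1], [e.pubmed_id for e in t[2]]))
    interactions = deduplicate(surviving, report)
    interactions = species_threshold(interactions, min_species_count, report)
    report.accepted = len(interactions)
    return interactions, report
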