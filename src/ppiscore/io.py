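"""Readers and writers for interaction data and sidecar annotation tables.

Supported formats:

* PSI-MITAB 2.5 (15 columns) and 2.7 (42 columns, experimental roles used),
  tab-separated, ``#`` header/comment lines skipped.
* A compact PSI-MI XML 2.5 dialect: ``entry`` elements with interactorList /
  experimentList / interactionList, experimentRef and interactorRef
  resolution, participant experimentalRole elements. The expanded XML form
  is out of scope.
* Headered TSV sidecar tables (UTF-8, ``#`` comments): protein→Pfam domains,
  protein→GO terms, protein→compartments, interacting domain pairs, homolog
  map, identifier mapping and per-publication experiment scales.

Readers never silently drop a row: every malformed row becomes an entry in
the returned reject list.
"""

from __future__ import annotations

import csv
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

from .model import (
    BinaryInteraction,
    EvidenceItem,
    InteractionRecord,
    MoleculeKind,
    ProteinRef,
    Role,
    pair_key,
)

__all__ = [
    "MitabDialectError",
    "PsimiXmlError",
    "MitabReadResult",
    "SidecarTables",
    "read_mitab",
    "write_mitab",
    "read_psimi_xml",
    "load_sidecar_tables",
    "write_scored_tsv",
    "read_scored_tsv",
]

MITAB25_COLUMNS = 15
MITAB27_COLUMNS = 42

#: identifier-database prefixes that denote non-protein molecules
NON_PROTEIN_PREFIXES = frozenset(
    {"chebi", "chembl", "chembl compound", "pubchem", "rnacentral", "complex portal"}
)

#: precedence when one interactor carries several cross-references
_DB_PRECEDENCE = (
    "uniprotkb",
    "refseq",
    "entrez gene/locuslink",
    "entrezgene/locuslink",
    "ensembl",
)


class MitabDialectError(ValueError):
    pass


class PsimiXmlError(ValueError):
    pass


@dataclass
class MitabReadResult:
    """Parsed records plus per-row rejects (row number, reason)."""

    records: list[InteractionRecord]
    rejects: list[tuple[int, str]] = field(default_factory=list)

    def __iter__(self) -> Iterator[InteractionRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


_FIELD_RE = re.compile(r'^(?P<db>[^:]+):"?(?P<acc>[^"(]+)"?(?:\((?P<desc>[^)]*)\))?$')


def _parse_field(field_text: str) -> tuple[str, str, str]:
    """Split a MITAB field into (db, accession, description)."""
    m = _FIELD_RE.match(field_text.strip())
    if not m:
        return ("", field_text.strip(), "")
    return (m.group("db").lower(), m.group("acc"), m.group("desc") or "")


def _term_name(field_text: str) -> str:
    """Extract a CV term name from e.g. ``psi-mi:"MI:0018"(two hybrid)``."""
    if field_text in ("-", ""):
        return ""
    db, acc, desc = _parse_field(field_text)
    return desc if desc else acc


def _parse_taxid(field_text: str) -> int | None:
    if field_text in ("-", ""):
        return None
    _, acc, _ = _parse_field(field_text)
    try:
        return int(acc)
    except ValueError:
        return None


def _molecule_kind(db: str) -> MoleculeKind:
    return (
        MoleculeKind.NON_PROTEIN
        if db.lower() in NON_PROTEIN_PREFIXES
        else MoleculeKind.PROTEIN
    )


_ROLE_NAMES = {"bait": Role.BAIT, "prey": Role.PREY}


def read_mitab(path: str | Path, dialect: str = "mitab25") -> MitabReadResult:
    """Read a PSI-MITAB file into one :class:`InteractionRecord` per row.

    Molecule kind is inferred from the identifier prefix; rows whose taxon
    cannot be parsed are rejected into the report rather than raising. A
    wrong column count raises :class:`MitabDialectError` naming the row.
    """
    expected = {"mitab25": MITAB25_COLUMNS, "mitab27": MITAB27_COLUMNS}.get(dialect)
    if expected is None:
        raise MitabDialectError(f"unknown MITAB dialect {dialect!r}")
    records: list[InteractionRecord] = []
    rejects: list[tuple[int, str]] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (row[0].startswith("#")):
                continue
            if len(row) != expected:
                raise MitabDialectError(
                    f"{path}: row {lineno} has {len(row)} columns, "
                    f"expected {expected} for {dialect}"
                )
            db_a, acc_a, _ = _parse_field(row[0])
            db_b, acc_b, _ = _parse_field(row[1])
            tax_a = _parse_taxid(row[9])
            tax_b = _parse_taxid(row[10])
            if row[1] in ("-", ""):  # MITAB convention for self-interactions
                db_b, acc_b, tax_b = db_a, acc_a, tax_a
            if not acc_a or not acc_b:
                rejects.append((lineno, "missing interactor identifier"))
                continue
            if tax_a is None or tax_b is None:
                rejects.append((lineno, "unparseable taxon"))
                continue
            method = _term_name(row[6]) or "unknown"
            itype = _term_name(row[11]) or "unknown"
            source_db = _term_name(row[12]) or "unknown"
            pubmed = ""
            for part in row[8].split("|"):
                db, acc, _ = _parse_field(part)
                if db == "pubmed":
                    pubmed = acc
                    break
            if not pubmed:
                rejects.append((lineno, "missing pubmed identifier"))
                continue
            role_a = role_b = Role.NEUTRAL
            if dialect == "mitab27":
                role_a = _ROLE_NAMES.get(_term_name(row[18]).lower(), Role.NEUTRAL)
                role_b = _ROLE_NAMES.get(_term_name(row[19]).lower(), Role.NEUTRAL)
            participants = [
                ProteinRef(
                    source_id=acc_a,
                    taxon=tax_a,
                    molecule_kind=_molecule_kind(db_a),
                    role=role_a,
                    id_db=db_a,
                ),
                ProteinRef(
                    source_id=acc_b,
                    taxon=tax_b,
                    molecule_kind=_molecule_kind(db_b),
                    role=role_b,
                    id_db=db_b,
                ),
            ]
            evidence = EvidenceItem(
                pubmed_id=pubmed,
                interaction_types=frozenset({itype}),
                detection_methods=frozenset({method}),
                source_dbs=frozenset({source_db}),
            )
            records.append(
                InteractionRecord(
                    participants=participants,
                    evidence=[evidence],
                    source_db=source_db,
                )
            )
    return MitabReadResult(records=records, rejects=rejects)


# ---------------------------------------------------------------------------
# PSI-MI XML (compact subset)
# ---------------------------------------------------------------------------


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _find(elem: ET.Element, *names: str) -> ET.Element | None:
    for child in elem.iter():
        if _local(child.tag) in names:
            return child
    return None


def _children(elem: ET.Element, name: str) -> list[ET.Element]:
    return [c for c in elem.iter() if _local(c.tag) == name]


def _short_label(elem: ET.Element | None) -> str:
    if elem is None:
        return ""
    lbl = _find(elem, "shortLabel")
    return (lbl.text or "").strip() if lbl is not None else ""


def read_psimi_xml(path: str | Path, source_db: str | None = None) -> list[InteractionRecord]:
    """Read interaction records from a compact PSI-MI XML 2.5 file.

    Complex records keep bait/prey roles from ``experimentalRole`` elements;
    participants without a role are neutral. Dangling ``interactorRef`` or
    ``experimentRef`` raises :class:`PsimiXmlError` naming the reference.
    """
    tree = ET.parse(path)
    root = tree.getroot()
    records: list[InteractionRecord] = []
    for entry in _children(root, "entry"):
        entry_source = source_db
        src = next(iter(_children(entry, "source")), None)
        if entry_source is None:
            entry_source = _short_label(src) or "unknown"

        interactors: dict[str, ProteinRef] = {}
        ilist = next(iter(_children(entry, "interactorList")), None)
        if ilist is not None:
            for inter in _children(ilist, "interactor"):
                iid = inter.get("id", "")
                xref = _find(inter, "primaryRef")
                db = (xref.get("db", "") if xref is not None else "").lower()
                acc = xref.get("id", "") if xref is not None else ""
                org = _find(inter, "organism")
                tax = int(org.get("ncbiTaxId", "0")) if org is not None else 0
                kind = _molecule_kind(db)
                itype = next(iter(_children(inter, "interactorType")), None)
                if itype is not None and _short_label(itype) not in ("protein", ""):
                    kind = MoleculeKind.NON_PROTEIN
                if tax <= 0:
                    raise PsimiXmlError(
                        f"{path}: interactor {iid or acc!r} lacks a valid ncbiTaxId"
                    )
                interactors[iid] = ProteinRef(
                    source_id=acc, taxon=tax, molecule_kind=kind, id_db=db
                )

        experiments: dict[str, tuple[str, str]] = {}
        elist = next(iter(_children(entry, "experimentList")), None)
        if elist is not None:
            for exp in _children(elist, "experimentDescription"):
                eid = exp.get("id", "")
                bibref = next(iter(_children(exp, "bibref")), None)
                pubmed = ""
                if bibref is not None:
                    ref = _find(bibref, "primaryRef")
                    if ref is not None and ref.get("db", "").lower() == "pubmed":
                        pubmed = ref.get("id", "")
                det = next(
                    iter(_children(exp, "interactionDetectionMethod")), None
                )
                method = _short_label(det) or "unknown"
                experiments[eid] = (pubmed or "unknown", method)

        xlist = next(iter(_children(entry, "interactionList")), None)
        if xlist is None:
            continue
        for interaction in _children(xlist, "interaction"):
            participants: list[ProteinRef] = []
            plist = next(iter(_children(interaction, "participantList")), None)
            for part in _children(plist, "participant") if plist is not None else []:
                ref = next(iter(_children(part, "interactorRef")), None)
                if ref is None or (ref.text or "").strip() not in interactors:
                    missing = (ref.text or "").strip() if ref is not None else "?"
                    raise PsimiXmlError(
                        f"{path}: dangling interactorRef {missing!r}"
                    )
                base = interactors[(ref.text or "").strip()]
                role_el = next(iter(_children(part, "experimentalRole")), None)
                role = _ROLE_NAMES.get(_short_label(role_el).lower(), Role.NEUTRAL)
                participants.append(
                    ProteinRef(
                        source_id=base.source_id,
                        taxon=base.taxon,
                        molecule_kind=base.molecule_kind,
                        role=role,
                        id_db=base.id_db,
                    )
                )
            itype_el = next(iter(_children(interaction, "interactionType")), None)
            itype = _short_label(itype_el) or "unknown"
            evidence: list[EvidenceItem] = []
            erefs = [
                (e.text or "").strip()
                for e in _children(interaction, "experimentRef")
            ]
            for eref in erefs:
                if eref not in experiments:
                    raise PsimiXmlError(f"{path}: dangling experimentRef {eref!r}")
                pubmed, method = experiments[eref]
                evidence.append(
                    EvidenceItem(
                        pubmed_id=pubmed,
                        interaction_types=frozenset({itype}),
                        detection_methods=frozenset({method}),
                        source_dbs=frozenset({entry_source}),
                    )
                )
            if not evidence:
                evidence = [
                    EvidenceItem(
                        pubmed_id="unknown",
                        interaction_types=frozenset({itype}),
                        detection_methods=frozenset({"unknown"}),
                        source_dbs=frozenset({entry_source}),
                    )
                ]
            records.append(
                InteractionRecord(
                    participants=participants,
                    evidence=evidence,
                    source_db=entry_source,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Sidecar tables
# ---------------------------------------------------------------------------


def _unordered(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class SidecarTables:
    """Annotation knowledge consulted by the annotation scorer.

    All protein keys are canonical accessions; domain pairs are stored
    order-invariantly. Proteins absent from a table contribute empty sets.
    """

    domains: dict[str, frozenset[str]] = field(default_factory=dict)
    go_terms: dict[str, frozenset[tuple[str, str]]] = field(default_factory=dict)
    compartments: dict[str, frozenset[str]] = field(default_factory=dict)
    domain_pairs: set[tuple[str, str]] = field(default_factory=set)
    homologs: dict[tuple[str, str], list[tuple[str, str, int]]] = field(
        default_factory=dict
    )
    id_mapping: dict[str, str] = field(default_factory=dict)
    pubmed_scales: dict[str, int] = field(default_factory=dict)

    def add_domain_pair(self, d1: str, d2: str) -> None:
        self.domain_pairs.add(_unordered(d1, d2))

    def has_domain_pair(self, d1: str, d2: str) -> bool:
        return _unordered(d1, d2) in self.domain_pairs


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str).dropna(how="all")


def load_sidecar_tables(
    directory: str | Path | None = None,
    *,
    domains: str | Path | None = None,
    go_terms: str | Path | None = None,
    compartments: str | Path | None = None,
    domain_pairs: str | Path | None = None,
    homologs: str | Path | None = None,
    id_mapping: str | Path | None = None,
    pubmed_scales: str | Path | None = None,
) -> SidecarTables:
    """Load sidecar TSVs from a directory (standard filenames) or explicit paths.

    Standard filenames: ``domains.tsv``, ``go_terms.tsv``, ``compartments.tsv``,
    ``domain_pairs.tsv``, ``homologs.tsv``, ``id_mapping.tsv``,
    ``pubmed_scales.tsv``. Missing files yield empty tables.
    """

    def resolve(explicit: str | Path | None, name: str) -> Path | None:
        if explicit is not None:
            return Path(explicit)
        if directory is not None:
            p = Path(directory) / name
            return p if p.exists() else None
        return None

    tables = SidecarTables()
    p = resolve(domains, "domains.tsv")
    if p is not None:
        for prot, grp in _read_tsv(p).groupby("protein"):
            tables.domains[str(prot)] = frozenset(grp["domain"])
    p = resolve(go_terms, "go_terms.tsv")
    if p is not None:
        df = _read_tsv(p)
        if "aspect" not in df.columns:
            df["aspect"] = ""
        for prot, grp in df.groupby("protein"):
            tables.go_terms[str(prot)] = frozenset(
                zip(grp["go_term"], grp["aspect"].fillna(""))
            )
    p = resolve(compartments, "compartments.tsv")
    if p is not None:
        for prot, grp in _read_tsv(p).groupby("protein"):
            tables.compartments[str(prot)] = frozenset(grp["compartment"])
    p = resolve(domain_pairs, "domain_pairs.tsv")
    if p is not None:
        for _, row in _read_tsv(p).iterrows():
            tables.add_domain_pair(row["domain_a"], row["domain_b"])
    p = resolve(homologs, "homologs.tsv")
    if p is not None:
        for _, row in _read_tsv(p).iterrows():
            key = pair_key(row["id_a"], row["id_b"])
            tables.homologs.setdefault(key, []).append(
                (row["homolog_a"], row["homolog_b"], int(row["taxon"]))
            )
    p = resolve(id_mapping, "id_mapping.tsv")
    if p is not None:
        df = _read_tsv(p)
        tables.id_mapping = dict(zip(df["source_id"], df["canonical_id"]))
    p = resolve(pubmed_scales, "pubmed_scales.tsv")
    if p is not None:
        df = _read_tsv(p)
        tables.pubmed_scales = {
            str(r["pubmed_id"]): int(r["n_associations"]) for _, r in df.iterrows()
        }
    return tables


# ---------------------------------------------------------------------------
# Scored output
# ---------------------------------------------------------------------------

_SCORED_HEADER = [
    "id_a",
    "id_b",
    "taxon",
    "n_publications",
    "n_small_scale",
    "annotation_score",
    "method_score",
    "combined_score",
    "high_confidence",
    "evidence",
]


def _evidence_summary(interaction: BinaryInteraction) -> str:
    parts = []
    for ev in interaction.evidence:
        methods = ",".join(sorted(ev.detection_methods))
        types = ",".join(sorted(ev.interaction_types))
        parts.append(f"pubmed:{ev.pubmed_id}({types};{methods};scale={ev.scale})")
    return "|".join(parts)


def write_scored_tsv(
    scored: Sequence[tuple[BinaryInteraction, "ScoreSet"]],
    path: str | Path,
    small_scale_cutoff: int = 100,
) -> int:
    """Write scored interactions as a deterministic TSV; returns rows written.

    Rows are sorted by pair key and scores serialized to 6 decimals, so the
    same input always produces byte-identical output.
    """
    rows = sorted(scored, key=lambda t: t[0].pair)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_SCORED_HEADER)
        for interaction, ss in rows:
            w.writerow(
                [
                    interaction.pair[0],
                    interaction.pair[1],
                    interaction.taxon,
                    interaction.n_publications,
                    interaction.n_small_scale(small_scale_cutoff),
                    f"{ss.annotation:.6f}",
                    f"{ss.method:.6f}",
                    f"{ss.combined:.6f}",
                    int(ss.high_confidence),
                    _evidence_summary(interaction),
                ]
            )
    return len(rows)


def read_scored_tsv(path: str | Path) -> pd.DataFrame:
    """Read a scored TSV back as a DataFrame (scores as floats)."""
    return pd.read_csv(
        path,
        sep="\t",
        dtype={
            "id_a": str,
            "id_b": str,
            "taxon": int,
            "n_publications": int,
            "n_small_scale": int,
            "annotation_score": float,
            "method_score": float,
            "combined_score": float,
            "high_confidence": int,
            "evidence": str,
        },
    )


def write_mitab(
    interactions: Sequence[BinaryInteraction],
    path: str | Path,
    scores: dict[tuple[str, str], "ScoreSet"] | None = None,
) -> int:
    """Export binary interactions as MITAB 2.5, one row per evidence item.

    When scores are given they go into the confidence column as
    ``annotation:x|method:y|combined:z`` entries.
    """
    n = 0
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for interaction in sorted(interactions, key=lambda i: i.pair):
            a, b = interaction.pair
            conf = "-"
            if scores is not None and interaction.pair in scores:
                ss = scores[interaction.pair]
                conf = (
                    f"annotation:{ss.annotation:.6f}"
                    f"|method:{ss.method:.6f}"
                    f"|combined:{ss.combined:.6f}"
                )
            for ev in interaction.evidence:
                method = sorted(ev.detection_methods)[0]
                itype = sorted(ev.interaction_types)[0]
                srcdb = sorted(ev.source_dbs)[0] if ev.source_dbs else "unknown"
                w.writerow(
                    [
                        f"uniprotkb:{a}",
                        f"uniprotkb:{b}",
                        "-",
                        "-",
                        "-",
                        "-",
                        f"psi-mi:\"MI:0000\"({method})",
                        "-",
                        f"pubmed:{ev.pubmed_id}",
                        f"taxid:{interaction.taxon}",
                        f"taxid:{interaction.taxon}",
                        f"psi-mi:\"MI:0000\"({itype})",
                        f"psi-mi:\"MI:0000\"({srcdb})",
                        "-",
                        conf,
                    ]
                )
                n += 1
    return n
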