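"""Synthetic interaction corpora with controlled statistical structure.

The generator emits everything the pipeline consumes — per-database MITAB
files, compact PSI-MI XML files with co-purification complexes, and the
sidecar annotation tables — plus a ground-truth record that an independent
brute-force oracle (:func:`expected_integration`) turns into the exact
expected outcome of integration. That makes every pipeline stage and the
score evaluation testable without downloading any source database.

The default configuration mirrors the statistical shape of real integrated
interactomes: most interactions are supported by a single publication
(default 88% overall), the bulk of evidence comes from high-throughput
screens, and both the experimental profile (detection-method category,
interaction type, publication count, experiment scale) and the annotation
features (interacting Pfam domains, shared GO terms, interologs) are
conditioned on whether an interaction is planted as true or spurious, so
the method-based and annotation-based scores are both informative but
neither has privileged access to the evaluation labels. Defective records — cross-species, non-protein participants,
colocalization-only or genetic-interference evidence, complexes without a
bait, unmappable identifiers, a species below the census threshold — are
planted in known numbers.

Everything is fully determined by the seed.
"""

from __future__ import annotations

import itertools
import json
import xml.etree.ElementTree as ET
from collections import Counter
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from .config import PipelineConfig, default_config

__all__ = ["SynthConfig", "SynthCorpus", "generate_corpus", "expected_integration"]


@dataclass(frozen=True)
class SynthConfig:
    """Stated world of the synthetic corpus; fully determined by ``seed``."""

    seed: int = 0
    n_proteins: int = 160
    n_taxa: int = 3
    n_interactions: int = 400
    #: interactions planted in an extra taxon kept below the census threshold
    rare_taxon_interactions: int = 4
    complex_fraction: float = 0.2
    multi_bait_prob: float = 0.2
    max_preys: int = 4
    self_pair_prob: float = 0.02
    n_databases: int = 3
    duplication_prob: float = 0.3
    spurious_fraction: float = 0.3
    #: P(single supporting publication | status); weighted mix ~= 0.88
    single_pub_prob_true: float = 0.87
    single_pub_prob_spurious: float = 0.91
    max_pubs: int = 8
    #: P(a publication is small-scale | status)
    small_scale_prob_true: float = 0.4
    small_scale_prob_spurious: float = 0.03
    small_scale_range: tuple[int, int] = (1, 100)
    high_throughput_range: tuple[int, int] = (101, 5000)
    #: feature enrichment P(feature | true) / P(feature | spurious)
    p_domain_true: float = 0.5
    p_domain_spurious: float = 0.08
    p_go_true: float = 0.6
    p_go_spurious: float = 0.10
    p_homolog_true: float = 0.45
    p_homolog_spurious: float = 0.04
    colocalize_prob_true: float = 0.9
    unannotated_fraction: float = 0.1
    invalid_term_fraction: float = 0.0
    alt_id_fraction: float = 0.15
    n_cross_species: int = 5
    n_non_protein: int = 5
    n_colocalization: int = 5
    n_genetic: int = 5
    n_no_bait: int = 3
    n_unmappable: int = 5
    min_species_count: int = 10

    def validate(self) -> None:
        by_taxon = self.n_proteins // self.n_taxa
        possible = self.n_taxa * by_taxon * (by_taxon + 1) // 2
        if self.n_interactions > possible:
            raise ValueError(
                f"{self.n_interactions} interactions infeasible with "
                f"{self.n_proteins} proteins in {self.n_taxa} taxa"
            )
        for name in (
            "complex_fraction",
            "duplication_prob",
            "spurious_fraction",
            "invalid_term_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")


_METHOD_TERMS = {
    "biophysical": ["x-ray crystallography", "surface plasmon resonance"],
    "biochemical": ["tandem affinity purification", "pull down", "anti tag coimmunoprecipitation"],
    "protein complementation assay": ["two hybrid", "two hybrid array"],
    "imaging technique": ["fluorescence microscopy"],
    "unknown": ["experimental interaction detection"],
}
_METHOD_DIST_TRUE = (
    ("biophysical", 0.25),
    ("biochemical", 0.25),
    ("protein complementation assay", 0.30),
    ("imaging technique", 0.15),
    ("unknown", 0.05),
)
_METHOD_DIST_SPURIOUS = (
    ("protein complementation assay", 0.35),
    ("biochemical", 0.20),
    ("imaging technique", 0.25),
    ("unknown", 0.20),
)
_TYPE_DIST_TRUE = (
    ("direct interaction", 0.35),
    ("physical association", 0.50),
    ("association", 0.15),
)
_TYPE_DIST_SPURIOUS = (
    ("direct interaction", 0.10),
    ("physical association", 0.25),
    ("association", 0.65),
)
_COMPARTMENTS = ["nucleus", "cytoplasm", "membrane", "mitochondrion", "er", "golgi"]


def _choice(rng: np.random.Generator, dist: tuple[tuple[str, float], ...]) -> str:
    names = [n for n, _ in dist]
    probs = np.array([p for _, p in dist])
    return str(rng.choice(names, p=probs / probs.sum()))


@dataclass
class SynthCorpus:
    """Generated corpus: file paths plus the in-memory ground truth."""

    out_dir: Path
    mitab_paths: list[Path]
    xml_paths: list[Path]
    sidecar_dir: Path
    truth: dict[str, Any]

    @property
    def truth_path(self) -> Path:
        return self.out_dir / "truth.json"


def generate_corpus(config: SynthConfig, out_dir: str | Path) -> SynthCorpus:
    """Generate a complete synthetic corpus under ``out_dir``.

    Emits one MITAB 2.5 file per synthetic database (binary records and
    planted defective rows), one XML file per database holding its
    co-purification complexes, the sidecar TSVs, and ``truth.json`` with the
    record-level ground truth.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sidecars = out / "sidecars"
    sidecars.mkdir(exist_ok=True)
    rng = np.random.default_rng(config.seed)

    taxa = [9000 + i + 1 for i in range(config.n_taxa)]
    rare_taxon = 9999
    proteins: dict[str, int] = {}
    by_taxon: dict[int, list[str]] = {t: [] for t in taxa}
    for i in range(config.n_proteins):
        t = taxa[i % config.n_taxa]
        pid = f"SYNP{i + 1:06d}"
        proteins[pid] = t
        by_taxon[t].append(pid)
    rare_proteins = [f"SYNR{i + 1:04d}" for i in range(8)]
    for pid in rare_proteins:
        proteins[pid] = rare_taxon
    by_taxon[rare_taxon] = rare_proteins

    unannotated = {
        p
        for p in sorted(proteins)
        if proteins[p] != rare_taxon
        and rng.random() < config.unannotated_fraction
    }

    compartments: dict[str, set[str]] = {}
    for p in sorted(proteins):
        if p in unannotated:
            continue
        k = 1 + int(rng.random() < 0.4)
        compartments[p] = set(
            rng.choice(_COMPARTMENTS, size=k, replace=False).tolist()
        )

    # ---- plan interactions ------------------------------------------------
    pubmed_counter = itertools.count(10_000_001)
    pubmed_scales: dict[str, int] = {}

    def new_pub(status: str) -> tuple[str, int]:
        pm = str(next(pubmed_counter))
        p_small = (
            config.small_scale_prob_true
            if status == "true"
            else config.small_scale_prob_spurious
        )
        if rng.random() < p_small:
            lo, hi = config.small_scale_range
        else:
            lo, hi = config.high_throughput_range
        scale = int(rng.integers(lo, hi + 1))
        pubmed_scales[pm] = scale
        return pm, scale

    def evidence_for(status: str, pm: str, scale: int) -> dict[str, Any]:
        dist = _METHOD_DIST_TRUE if status == "true" else _METHOD_DIST_SPURIOUS
        cat = _choice(rng, dist)
        method = _METHOD_TERMS[cat][int(rng.integers(len(_METHOD_TERMS[cat])))]
        tdist = _TYPE_DIST_TRUE if status == "true" else _TYPE_DIST_SPURIOUS
        itype = _choice(rng, tdist)
        if rng.random() < config.invalid_term_fraction:
            method = f"obsolete method {int(rng.integers(1000))}"
        if rng.random() < config.invalid_term_fraction:
            itype = f"obsolete type {int(rng.integers(1000))}"
        return {"pubmed": pm, "method": method, "type": itype}

    planned_pairs: dict[tuple[str, str], str] = {}  # pair key -> status

    def sample_pair(taxon: int) -> tuple[str, str] | None:
        pool = by_taxon[taxon]
        for _ in range(200):
            a = pool[int(rng.integers(len(pool)))]
            if rng.random() < config.self_pair_prob:
                b = a
            else:
                b = pool[int(rng.integers(len(pool)))]
            key = (a, b) if a <= b else (b, a)
            if key not in planned_pairs:
                return key
        return None

    n_complex_pairs = int(round(config.n_interactions * config.complex_fraction))
    n_binary = config.n_interactions - n_complex_pairs

    records: list[dict[str, Any]] = []

    def plan_status() -> str:
        return "spurious" if rng.random() < config.spurious_fraction else "true"

    # binary interactions
    binary_plans: list[dict[str, Any]] = []
    for _ in range(n_binary):
        taxon = taxa[int(rng.integers(len(taxa)))]
        key = sample_pair(taxon)
        if key is None:
            continue
        status = plan_status()
        planned_pairs[key] = status
        single_p = (
            config.single_pub_prob_true
            if status == "true"
            else config.single_pub_prob_spurious
        )
        n_pubs = (
            1
            if rng.random() < single_p
            else int(rng.integers(2, config.max_pubs + 1))
        )
        pubs = [new_pub(status) for _ in range(n_pubs)]
        binary_plans.append(
            {"pair": key, "taxon": taxon, "status": status, "pubs": pubs}
        )

    # complexes (bait + preys, single co-purification publication)
    complex_plans: list[dict[str, Any]] = []
    emitted_complex_pairs = 0
    while emitted_complex_pairs < n_complex_pairs:
        taxon = taxa[int(rng.integers(len(taxa)))]
        pool = by_taxon[taxon]
        n_baits = 2 if rng.random() < config.multi_bait_prob else 1
        n_preys = int(rng.integers(1, config.max_preys + 1))
        members = rng.choice(pool, size=n_baits + n_preys, replace=False).tolist()
        baits, preys = members[:n_baits], members[n_baits:]
        pair_keys = [
            (a, b) if a <= b else (b, a)
            for a, b in itertools.combinations(baits, 2)
        ] + [
            (b, p) if b <= p else (p, b) for b in baits for p in preys
        ]
        statuses = {}
        for key in pair_keys:
            if key not in planned_pairs:
                planned_pairs[key] = plan_status()
            statuses["|".join(key)] = planned_pairs[key]
        # co-purification: one publication, biased high-throughput
        pm, scale = new_pub("spurious" if rng.random() < 0.85 else "true")
        complex_plans.append(
            {
                "taxon": taxon,
                "baits": baits,
                "preys": preys,
                "statuses": statuses,
                "pub": (pm, scale),
            }
        )
        emitted_complex_pairs += len(pair_keys)

    # rare-taxon interactions (will fall below the species threshold)
    rare_plans: list[dict[str, Any]] = []
    for _ in range(config.rare_taxon_interactions):
        key = sample_pair(rare_taxon)
        if key is None:
            continue
        planned_pairs[key] = "true"
        rare_plans.append(
            {
                "pair": key,
                "taxon": rare_taxon,
                "status": "true",
                "pubs": [new_pub("true")],
            }
        )

    # ---- annotations ------------------------------------------------------
    domains: dict[str, set[str]] = {}
    go_terms: dict[str, set[tuple[str, str]]] = {}
    domain_pairs: list[tuple[str, str]] = []
    homologs: list[tuple[str, str, str, str, int]] = []
    dom_counter = itertools.count(1)
    go_counter = itertools.count(1)

    for p in sorted(proteins):
        if p in unannotated or proteins[p] == rare_taxon:
            continue
        for _ in range(1 + int(rng.integers(2))):
            domains.setdefault(p, set()).add(f"PFB{next(dom_counter):05d}")
        for _ in range(2 + int(rng.integers(3))):
            aspect = str(rng.choice(["C", "F", "P"]))
            go_terms.setdefault(p, set()).add(
                (f"GO:1{next(go_counter):06d}", aspect)
            )

    feature_truth: dict[str, dict[str, bool]] = {}
    for key in sorted(planned_pairs):
        a, b = key
        status = planned_pairs[key]
        annotatable = a not in unannotated and b not in unannotated
        p_dom = config.p_domain_true if status == "true" else config.p_domain_spurious
        p_go = config.p_go_true if status == "true" else config.p_go_spurious
        p_hom = config.p_homolog_true if status == "true" else config.p_homolog_spurious
        f_dom = annotatable and rng.random() < p_dom
        f_go = annotatable and rng.random() < p_go
        f_hom = annotatable and rng.random() < p_hom
        if a == b and annotatable:
            f_go = True  # a self-pair trivially shares every GO term
        if f_dom:
            d1 = f"PFI{next(dom_counter):05d}"
            d2 = f"PFI{next(dom_counter):05d}"
            domains.setdefault(a, set()).add(d1)
            domains.setdefault(b, set()).add(d2)
            domain_pairs.append((d1, d2) if d1 <= d2 else (d2, d1))
        if f_go:
            term = f"GO:0{next(go_counter):06d}"
            aspect = str(rng.choice(["C", "F", "P"]))
            go_terms.setdefault(a, set()).add((term, aspect))
            go_terms.setdefault(b, set()).add((term, aspect))
        if f_hom:
            other_taxon = int(rng.choice([4932, 7227, 6239]))
            homologs.append((a, b, f"H{a}", f"H{b}", other_taxon))
        if status == "true" and annotatable and a != b:
            if rng.random() < config.colocalize_prob_true:
                shared = sorted(compartments.get(a, {"cytoplasm"}))[0]
                compartments.setdefault(b, set()).add(shared)
        feature_truth["|".join(key)] = {
            "interacting_domains": f_dom,
            "shared_go_term": f_go,
            "homologous_interaction": f_hom,
        }

    # ---- identifier mapping ----------------------------------------------
    id_mapping: dict[str, str] = {p: p for p in sorted(proteins)}
    alt_ids: dict[str, str] = {}
    for p in sorted(proteins):
        if proteins[p] != rare_taxon and rng.random() < config.alt_id_fraction:
            alt = f"G{p[4:]}"
            alt_ids[p] = alt
            id_mapping[alt] = p

    def emit_id(p: str) -> tuple[str, str]:
        """(db_prefix, source_id) — sometimes through the alternate namespace."""
        if p in alt_ids and rng.random() < 0.5:
            return ("entrez gene/locuslink", alt_ids[p])
        return ("uniprotkb", p)

    # ---- record emission --------------------------------------------------
    dbs = [f"SynDB{i + 1}" for i in range(config.n_databases)]

    def record_binary(
        plan: dict[str, Any], db: str, resample_terms: bool = False
    ) -> None:
        a, b = plan["pair"]
        taxon = plan["taxon"]
        db_a, src_a = emit_id(a)
        db_b, src_b = emit_id(b)
        for pm, scale in plan["pubs"]:
            ev = evidence_for(plan["status"], pm, scale)
            records.append(
                {
                    "kind": "binary",
                    "db": db,
                    "participants": [
                        {"id": src_a, "db": db_a, "taxon": taxon, "molecule": "protein", "role": "neutral"},
                        {"id": src_b, "db": db_b, "taxon": taxon, "molecule": "protein", "role": "neutral"},
                    ],
                    "evidence": [ev],
                    "defect": None,
                }
            )

    for plan in binary_plans + rare_plans:
        primary = dbs[int(rng.integers(len(dbs)))]
        record_binary(plan, primary)
        if rng.random() < config.duplication_prob and len(dbs) > 1:
            others = [d for d in dbs if d != primary]
            record_binary(plan, others[int(rng.integers(len(others)))])

    for plan in complex_plans:
        db = dbs[int(rng.integers(len(dbs)))]
        pm, scale = plan["pub"]
        ev = evidence_for("spurious", pm, scale)
        participants = [
            {"id": p, "db": "uniprotkb", "taxon": plan["taxon"], "molecule": "protein", "role": "bait"}
            for p in plan["baits"]
        ] + [
            {"id": p, "db": "uniprotkb", "taxon": plan["taxon"], "molecule": "protein", "role": "prey"}
            for p in plan["preys"]
        ]
        records.append(
            {
                "kind": "complex",
                "db": db,
                "participants": participants,
                "evidence": [ev],
                "defect": None,
            }
        )

    # ---- planted defective records ---------------------------------------
    def planted_pub() -> str:
        pm, _ = new_pub("spurious")
        return pm

    for i in range(config.n_cross_species):
        a = by_taxon[taxa[0]][int(rng.integers(len(by_taxon[taxa[0]])))]
        b = by_taxon[taxa[1]][int(rng.integers(len(by_taxon[taxa[1]])))]
        records.append(
            {
                "kind": "binary",
                "db": dbs[int(rng.integers(len(dbs)))],
                "participants": [
                    {"id": a, "db": "uniprotkb", "taxon": proteins[a], "molecule": "protein", "role": "neutral"},
                    {"id": b, "db": "uniprotkb", "taxon": proteins[b], "molecule": "protein", "role": "neutral"},
                ],
                "evidence": [{"pubmed": planted_pub(), "method": "two hybrid", "type": "physical association"}],
                "defect": "cross_species",
            }
        )
    for i in range(config.n_non_protein):
        a = by_taxon[taxa[0]][int(rng.integers(len(by_taxon[taxa[0]])))]
        records.append(
            {
                "kind": "binary",
                "db": dbs[int(rng.integers(len(dbs)))],
                "participants": [
                    {"id": a, "db": "uniprotkb", "taxon": proteins[a], "molecule": "protein", "role": "neutral"},
                    {"id": f"CHEBI:{10000 + i}", "db": "chebi", "taxon": proteins[a], "molecule": "non_protein", "role": "neutral"},
                ],
                "evidence": [{"pubmed": planted_pub(), "method": "pull down", "type": "physical association"}],
                "defect": "non_protein",
            }
        )
    for i in range(config.n_colocalization):
        t = taxa[int(rng.integers(len(taxa)))]
        a = by_taxon[t][int(rng.integers(len(by_taxon[t])))]
        b = by_taxon[t][int(rng.integers(len(by_taxon[t])))]
        records.append(
            {
                "kind": "binary",
                "db": dbs[int(rng.integers(len(dbs)))],
                "participants": [
                    {"id": a, "db": "uniprotkb", "taxon": t, "molecule": "protein", "role": "neutral"},
                    {"id": b, "db": "uniprotkb", "taxon": t, "molecule": "protein", "role": "neutral"},
                ],
                "evidence": [{"pubmed": planted_pub(), "method": "fluorescence microscopy", "type": "colocalization"}],
                "defect": "indirect_type",
            }
        )
    for i in range(config.n_genetic):
        t = taxa[int(rng.integers(len(taxa)))]
        a = by_taxon[t][int(rng.integers(len(by_taxon[t])))]
        b = by_taxon[t][int(rng.integers(len(by_taxon[t])))]
        records.append(
            {
                "kind": "binary",
                "db": dbs[int(rng.integers(len(dbs)))],
                "participants": [
                    {"id": a, "db": "uniprotkb", "taxon": t, "molecule": "protein", "role": "neutral"},
                    {"id": b, "db": "uniprotkb", "taxon": t, "molecule": "protein", "role": "neutral"},
                ],
                "evidence": [{"pubmed": planted_pub(), "method": "genetic interference", "type": "physical association"}],
                "defect": "genetic_method",
            }
        )
    for i in range(config.n_no_bait):
        t = taxa[int(rng.integers(len(taxa)))]
        members = rng.choice(by_taxon[t], size=3, replace=False).tolist()
        records.append(
            {
                "kind": "complex",
                "db": dbs[0],
                "participants": [
                    {"id": p, "db": "uniprotkb", "taxon": t, "molecule": "protein", "role": "prey"}
                    for p in members
                ],
                "evidence": [{"pubmed": planted_pub(), "method": "tandem affinity purification", "type": "association"}],
                "defect": "no_bait_complex",
            }
        )
    for i in range(config.n_unmappable):
        t = taxa[int(rng.integers(len(taxa)))]
        a = by_taxon[t][int(rng.integers(len(by_taxon[t])))]
        records.append(
            {
                "kind": "binary",
                "db": dbs[int(rng.integers(len(dbs)))],
                "participants": [
                    {"id": a, "db": "uniprotkb", "taxon": t, "molecule": "protein", "role": "neutral"},
                    {"id": f"OBSOLETE{i + 1:04d}", "db": "uniprotkb", "taxon": t, "molecule": "protein", "role": "neutral"},
                ],
                "evidence": [{"pubmed": planted_pub(), "method": "two hybrid", "type": "physical association"}],
                "defect": "unmappable_id",
            }
        )

    # ---- write files ------------------------------------------------------
    mitab_paths = _write_mitab_files(out, dbs, records)
    xml_paths = _write_xml_files(out, dbs, records)
    _write_sidecars(
        sidecars, domains, go_terms, compartments, domain_pairs, homologs,
        id_mapping, pubmed_scales,
    )

    truth = {
        "config": asdict(config),
        "records": records,
        "pair_status": {"|".join(k): v for k, v in sorted(planned_pairs.items())},
        "features": feature_truth,
        "planted_defects": dict(
            Counter(r["defect"] for r in records if r["defect"])
        ),
        "taxa": taxa,
        "rare_taxon": rare_taxon,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)

    return SynthCorpus(
        out_dir=out,
        mitab_paths=mitab_paths,
        xml_paths=xml_paths,
        sidecar_dir=sidecars,
        truth=truth,
    )


def _write_mitab_files(
    out: Path, dbs: list[str], records: list[dict[str, Any]]
) -> list[Path]:
    paths = []
    for db in dbs:
        path = out / f"{db}.mitab25.tsv"
        with open(path, "w") as fh:
            fh.write("#mitab25 synthetic corpus\n")
            for rec in records:
                if rec["db"] != db or rec["kind"] != "binary":
                    continue
                pa, pb = rec["participants"]
                for ev in rec["evidence"]:
                    cols = [
                        f"{pa['db']}:{pa['id']}",
                        f"{pb['db']}:{pb['id']}",
                        "-",
                        "-",
                        "-",
                        "-",
                        f'psi-mi:"MI:0000"({ev["method"]})',
                        "-",
                        f"pubmed:{ev['pubmed']}",
                        f"taxid:{pa['taxon']}",
                        f"taxid:{pb['taxon']}",
                        f'psi-mi:"MI:0000"({ev["type"]})',
                        f'psi-mi:"MI:0000"({db})',
                        "-",
                        "-",
                    ]
                    fh.write("\t".join(cols) + "\n")
        paths.append(path)
    return paths


def _write_xml_files(
    out: Path, dbs: list[str], records: list[dict[str, Any]]
) -> list[Path]:
    paths = []
    for db in dbs:
        complexes = [r for r in records if r["db"] == db and r["kind"] == "complex"]
        if not complexes:
            continue
        root = ET.Element("entrySet", version="2.5")
        entry = ET.SubElement(root, "entry")
        src = ET.SubElement(ET.SubElement(ET.SubElement(entry, "source"), "names"), "shortLabel")
        src.text = db
        ilist = ET.SubElement(entry, "interactorList")
        elist = ET.SubElement(entry, "experimentList")
        xlist = ET.SubElement(entry, "interactionList")
        interactor_ids: dict[str, str] = {}
        next_id = itertools.count(1)
        exp_ids = itertools.count(1001)
        for rec in complexes:
            for p in rec["participants"]:
                if p["id"] in interactor_ids:
                    continue
                iid = str(next(next_id))
                interactor_ids[p["id"]] = iid
                inter = ET.SubElement(ilist, "interactor", id=iid)
                xref = ET.SubElement(inter, "xref")
                ET.SubElement(xref, "primaryRef", db=p["db"], id=p["id"])
                ET.SubElement(inter, "organism", ncbiTaxId=str(p["taxon"]))
            ev = rec["evidence"][0]
            eid = str(next(exp_ids))
            exp = ET.SubElement(elist, "experimentDescription", id=eid)
            bib = ET.SubElement(ET.SubElement(exp, "bibref"), "xref")
            ET.SubElement(bib, "primaryRef", db="pubmed", id=ev["pubmed"])
            det = ET.SubElement(exp, "interactionDetectionMethod")
            ET.SubElement(ET.SubElement(det, "names"), "shortLabel").text = ev["method"]
            interaction = ET.SubElement(xlist, "interaction")
            iexp = ET.SubElement(interaction, "experimentList")
            ET.SubElement(iexp, "experimentRef").text = eid
            plist = ET.SubElement(interaction, "participantList")
            for p in rec["participants"]:
                part = ET.SubElement(plist, "participant")
                ET.SubElement(part, "interactorRef").text = interactor_ids[p["id"]]
                if p["role"] in ("bait", "prey"):
                    roles = ET.SubElement(part, "experimentalRoleList")
                    role = ET.SubElement(roles, "experimentalRole")
                    ET.SubElement(ET.SubElement(role, "names"), "shortLabel").text = p["role"]
            itype = ET.SubElement(interaction, "interactionType")
            ET.SubElement(ET.SubElement(itype, "names"), "shortLabel").text = ev["type"]
        ET.indent(root)
        path = out / f"{db}.psimi25.xml"
        ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=True)
        paths.append(path)
    return paths


def _write_sidecars(
    sidecars: Path,
    domains: dict[str, set[str]],
    go_terms: dict[str, set[tuple[str, str]]],
    compartments: dict[str, set[str]],
    domain_pairs: list[tuple[str, str]],
    homologs: list[tuple[str, str, str, str, int]],
    id_mapping: dict[str, str],
    pubmed_scales: dict[str, int],
) -> None:
    with open(sidecars / "domains.tsv", "w") as fh:
        fh.write("protein\tdomain\n")
        for p in sorted(domains):
            for d in sorted(domains[p]):
                fh.write(f"{p}\t{d}\n")
    with open(sidecars / "go_terms.tsv", "w") as fh:
        fh.write("protein\tgo_term\taspect\n")
        for p in sorted(go_terms):
            for term, aspect in sorted(go_terms[p]):
                fh.write(f"{p}\t{term}\t{aspect}\n")
    with open(sidecars / "compartments.tsv", "w") as fh:
        fh.write("protein\tcompartment\n")
        for p in sorted(compartments):
            for c in sorted(compartments[p]):
                fh.write(f"{p}\t{c}\n")
    with open(sidecars / "domain_pairs.tsv", "w") as fh:
        fh.write("domain_a\tdomain_b\n")
        for d1, d2 in sorted(set(domain_pairs)):
            fh.write(f"{d1}\t{d2}\n")
    with open(sidecars / "homologs.tsv", "w") as fh:
        fh.write("id_a\tid_b\thomolog_a\thomolog_b\ttaxon\n")
        for a, b, ha, hb, t in sorted(homologs):
            fh.write(f"{a}\t{b}\t{ha}\t{hb}\t{t}\n")
    with open(sidecars / "id_mapping.tsv", "w") as fh:
        fh.write("source_id\tcanonical_id\n")
        for s in sorted(id_mapping):
            fh.write(f"{s}\t{id_mapping[s]}\n")
    with open(sidecars / "pubmed_scales.tsv", "w") as fh:
        fh.write("pubmed_id\tn_associations\n")
        for pm in sorted(pubmed_scales):
            fh.write(f"{pm}\t{pubmed_scales[pm]}\n")


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------


@dataclass
class ExpectedIntegration:
    """Exact expected outcome of integrating a synthetic corpus."""

    pairs: set[tuple[str, str]]
    pubmed_counts: dict[tuple[str, str], int]
    reject_counters: dict[str, int]
    expanded: int


def expected_integration(
    truth: dict[str, Any],
    id_mapping: dict[str, str],
    config: PipelineConfig | None = None,
) -> ExpectedIntegration:
    """Recompute the integration outcome by brute force from the ground truth.

    Applies the curation rules directly to the record-level ground truth —
    spoke expansion by roles, term validity, physicality, molecule kind,
    same-taxon, ID mapping, dedup by unordered canonical pair, distinct
    Pubmed counting and the per-species census threshold — without touching
    the pipeline implementation or the file parsers. This is the oracle the
    pipeline is tested against.
    """
    cfg = config or default_config()
    vocab = cfg.vocabulary
    min_count = int(truth["config"]["min_species_count"])
    counters: Counter = Counter()
    expanded = 0
    acc: dict[tuple[str, str], tuple[int, set[str]]] = {}

    for rec in truth["records"]:
        ps = rec["participants"]
        baits = [p for p in ps if p["role"] == "bait"]
        if rec["kind"] == "complex" or len(ps) > 2:
            if not baits:
                expanded += 1
                counters["no_bait_complex"] += 1
                continue
            preys = [p for p in ps if p["role"] != "bait"]
            pairs = [
                (a, b) for a, b in itertools.combinations(baits, 2)
            ] + [(b, p) for b in baits for p in preys]
        elif len(ps) == 1:
            pairs = [(ps[0], ps[0])]
        else:
            pairs = [(ps[0], ps[1])]

        for pa, pb in pairs:
            expanded += 1
            ok_evidence = []
            fail_reasons = []
            for ev in rec["evidence"]:
                itype = ev["type"] if vocab.is_valid_type(ev["type"]) else "unknown"
                method = (
                    ev["method"]
                    if vocab.is_valid_method(ev["method"])
                    else "unknown"
                )
                if itype not in (vocab.physical_types | {"unknown"}):
                    fail_reasons.append("indirect_type")
                    continue
                if method in vocab.excluded_methods:
                    fail_reasons.append("genetic_method")
                    continue
                ok_evidence.append(ev["pubmed"])
            if not ok_evidence:
                counters[
                    "indirect_type"
                    if "indirect_type" in fail_reasons
                    else "genetic_method"
                ] += 1
                continue
            if pa["molecule"] != "protein" or pb["molecule"] != "protein":
                counters["non_protein"] += 1
                continue
            if pa["taxon"] != pb["taxon"]:
                counters["cross_species"] += 1
                continue
            ca = id_mapping.get(pa["id"])
            cb = id_mapping.get(pb["id"])
            if ca is None or cb is None:
                counters["unmappable_id"] += 1
                continue
            key = (ca, cb) if ca <= cb else (cb, ca)
            if key in acc:
                counters["duplicate"] += 1
                acc[key][1].update(ok_evidence)
            else:
                acc[key] = (pa["taxon"], set(ok_evidence))

    taxon_counts = Counter(t for t, _ in acc.values())
    keep_taxa = {t for t, c in taxon_counts.items() if c >= min_count}
    pairs_out = set()
    pubmed_counts = {}
    for key, (taxon, pubs) in acc.items():
        if taxon in keep_taxa:
            pairs_out.add(key)
            pubmed_counts[key] = len(pubs)
        else:
            counters["species_below_threshold"] += 1
    return ExpectedIntegration(
        pairs=pairs_out,
        pubmed_counts=pubmed_counts,
        reject_counters=dict(counters),
        expanded=expanded,
    )
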