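"""Spoke expansion, filtering, canonicalization, dedup and the census threshold."""

import itertools
import random

import pytest

import ppiscore as pp
from ppiscore.integrate import (
    FilterReport,
    canonicalize,
    deduplicate,
    filter_physical,
    filter_protein_same_species,
    species_threshold,
    spoke_expand,
)
from ppiscore.model import (
    BinaryInteraction,
    EvidenceItem,
    InteractionRecord,
    MoleculeKind,
    ProteinRef,
    Role,
)


def protein(pid, taxon=9606, role=Role.NEUTRAL, kind=MoleculeKind.PROTEIN):
    return ProteinRef(source_id=pid, taxon=taxon, role=role, molecule_kind=kind)


def evidence(pubmed="111", itype="physical association", method="two hybrid"):
    return EvidenceItem(
        pubmed_id=pubmed,
        interaction_types=frozenset({itype}),
        detection_methods=frozenset({method}),
    )


def record(participants, ev=None, db="db1"):
    return InteractionRecord(
        participants=participants, evidence=ev or [evidence()], source_db=db
    )


def brute_force_spoke(roles):
    """Oracle: enumerate all unordered pairs, keep bait-bait and bait-prey."""
    pairs = []
    for (i, ri), (j, rj) in itertools.combinations(enumerate(roles), 2):
        if Role.BAIT in (ri, rj):
            pairs.append((i, j))
    return pairs


class TestSpokeExpand:
    def test_one_bait_two_preys(self):
        rec = record([
            protein("B", role=Role.BAIT), protein("P1", role=Role.PREY),
            protein("P2", role=Role.PREY),
        ])
        pairs = {frozenset({p.a.source_id, p.b.source_id}) for p in spoke_expand(rec)}
        assert pairs == {frozenset({"B", "P1"}), frozenset({"B", "P2"})}

    def test_two_baits_bind_each_other(self):
        rec = record([
            protein("B1", role=Role.BAIT), protein("B2", role=Role.BAIT),
            protein("P", role=Role.PREY),
        ])
        pairs = {frozenset({p.a.source_id, p.b.source_id}) for p in spoke_expand(rec)}
        assert pairs == {
            frozenset({"B1", "B2"}), frozenset({"B1", "P"}), frozenset({"B2", "P"}),
        }

    def test_no_bait_complex_rejected(self):
        rec = record([protein(f"P{i}", role=Role.PREY) for i in range(3)])
        assert spoke_expand(rec) == []

    def test_binary_passthrough_and_self(self):
        assert len(spoke_expand(record([protein("A"), protein("B")]))) == 1
        [self_pair] = spoke_expand(record([protein("A")]))
        assert (self_pair.a.source_id, self_pair.b.source_id) == ("A", "A")

    @pytest.mark.parametrize(
        "k,p",
        [(k, p) for k in range(0, 7) for p in range(0, 7) if 2 <= k + p <= 6],
    )
    def test_count_law_against_brute_force(self, k, p):
        """Emitted pair count is k*p + k(k-1)/2 and matches enumeration."""
        roles = [Role.BAIT] * k + [Role.PREY] * p
        rec = record([protein(f"X{i}", role=r) for i, r in enumerate(roles)])
        got = spoke_expand(rec)
        if k == 0:
            assert got == []
        else:
            assert len(got) == k * p + k * (k - 1) // 2
            assert len(got) == len(brute_force_spoke(roles))


class TestFilters:
    def _pair(self, ev):
        [pr] = spoke_expand(record([protein("A"), protein("B")], ev=ev))
        return pr

    def test_physical_kept(self, config):
        kept, _ = filter_physical(self._pair([evidence()]), config.vocabulary)
        assert kept is not None

    def test_genetic_interference_only_rejected(self, config):
        pr = self._pair([evidence(method="genetic interference")])
        kept, reason = filter_physical(pr, config.vocabulary)
        assert kept is None and reason == "genetic_method"

    def test_colocalization_only_rejected(self, config):
        pr = self._pair([evidence(itype="colocalization",
                                  method="fluorescence microscopy")])
        kept, reason = filter_physical(pr, config.vocabulary)
        assert kept is None and reason == "indirect_type"

    def test_failing_evidence_pruned_from_kept_record(self, config):
        pr = self._pair([
            evidence(pubmed="1"),
            evidence(pubmed="2", itype="colocalization"),
        ])
        kept, _ = filter_physical(pr, config.vocabulary)
        assert [e.pubmed_id for e in kept.evidence] == ["1"]

    def test_unknown_type_retained(self, config):
        """Evidence whose invalid type was remapped to 'unknown' is kept
        (it is scored poorly, not discarded)."""
        kept, _ = filter_physical(self._pair([evidence(itype="unknown")]),
                                  config.vocabulary)
        assert kept is not None

    def test_species_and_molecule_rules(self):
        ok = spoke_expand(record([protein("A", 9606), protein("B", 9606)]))[0]
        assert filter_protein_same_species(ok)[0] is not None
        cross = spoke_expand(record([protein("A", 9606), protein("B", 10090)]))[0]
        assert filter_protein_same_species(cross)[1] == "cross_species"
        chem = spoke_expand(
            record([protein("A"), protein("C", kind=MoleculeKind.NON_PROTEIN)])
        )[0]
        assert filter_protein_same_species(chem)[1] == "non_protein"


class TestCanonicalize:
    MAPPING = {"944988": "P0A7L0", "P1": "P1", "P2": "P2"}

    def test_table_lookup(self):
        pr = spoke_expand(record([protein("944988"), protein("P1")]))[0]
        key, _ = canonicalize(pr, self.MAPPING)
        assert key == ("P0A7L0", "P1")

    def test_unmapped_rejected(self):
        pr = spoke_expand(record([protein("MISSING"), protein("P1")]))[0]
        key, reason = canonicalize(pr, self.MAPPING)
        assert key is None and reason == "unmappable_id"

    def test_identity_row(self):
        pr = spoke_expand(record([protein("P1"), protein("P2")]))[0]
        assert canonicalize(pr, self.MAPPING)[0] == ("P1", "P2")


class TestDeduplicate:
    def test_order_invariance_and_merge(self):
        items = [
            (("A", "B"), 9606, [evidence("111")]),
            (("A", "B"), 9606, [evidence("111")]),
            (("A", "B"), 9606, [evidence("222")]),
        ]
        report = FilterReport()
        out = deduplicate(items, report)
        assert len(out) == 1
        assert out[0].n_publications == 2
        assert report.counters["duplicate"] == 2


class TestSpeciesThreshold:
    @staticmethod
    def _interactions(counts):
        out = []
        for taxon, n in counts.items():
            for i in range(n):
                out.append(BinaryInteraction.build(f"A{taxon}_{i}", f"B{taxon}_{i}",
                                                   taxon, [evidence(str(i + 1))]))
        return out

    def test_boundary(self):
        inter = self._interactions({1: 10, 2: 9})
        kept = species_threshold(inter, 10)
        assert {i.taxon for i in kept} == {1}
        assert len(kept) == 10

    def test_min_one_is_identity(self):
        inter = self._interactions({1: 3, 2: 1})
        assert species_threshold(inter, 1) == inter

    def test_census(self):
        report = FilterReport()
        species_threshold(self._interactions({1: 10, 2: 9}), 10, report)
        assert report.census == [(1, 10, True), (2, 9, False)]
        assert report.counters["species_below_threshold"] == 9


class TestPipeline:
    def test_conservation(self, integrated):
        _, report = integrated
        assert report.conserved()

    def test_order_insensitive(self, corpus_records, sidecars):
        shuffled = list(corpus_records)
        random.Random(99).shuffle(shuffled)
        a, ra = pp.integrate_records(
            corpus_records, sidecars.id_mapping, pubmed_scales=sidecars.pubmed_scales
        )
        b, rb = pp.integrate_records(
            shuffled, sidecars.id_mapping, pubmed_scales=sidecars.pubmed_scales
        )
        assert [i.pair for i in a] == [i.pair for i in b]
        assert [i.evidence for i in a] == [i.evidence for i in b]
        assert ra.census == rb.census
        assert ra.counters == rb.counters

    def test_idempotent_on_own_output(self, integrated):
        """Re-integrating the integrated set reproduces it exactly."""
        interactions, _ = integrated
        records = [
            InteractionRecord(
                participants=[
                    ProteinRef(source_id=i.pair[0], taxon=i.taxon),
                    ProteinRef(source_id=i.pair[1], taxon=i.taxon),
                ],
                evidence=list(i.evidence),
                source_db="self",
            )
            for i in interactions
        ]
        identity = {pid: pid for i in interactions for pid in i.pair}
        again, report = pp.integrate_records(records, identity)
        assert [i.pair for i in again] == [i.pair for i in interactions]
        assert [i.evidence for i in again] == [i.evidence for i in interactions]
        assert report.counters.get("duplicate", 0) == 0
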