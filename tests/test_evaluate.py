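"""Gold-standard construction and ROC/AUC against a pairwise oracle."""

import numpy as np
import pytest

import ppiscore as pp
from ppiscore.evaluate import (
    EvaluationError,
    build_gold_standard,
    compare_scores,
    label_scale,
    roc_auc,
)
from ppiscore.model import BinaryInteraction, EvidenceItem


def ev(pubmed, scale):
    return EvidenceItem(
        pubmed_id=pubmed,
        interaction_types=frozenset({"association"}),
        detection_methods=frozenset({"two hybrid"}),
        scale=scale,
    )


def inter(a, b, scales, taxon=4932):
    return BinaryInteraction.build(
        a, b, taxon, [ev(str(i + 1), s) for i, s in enumerate(scales)]
    )


class TestLabelScale:
    @pytest.mark.parametrize(
        "scale,expected",
        [(1, "small_scale"), (100, "small_scale"), (101, "high_throughput")],
    )
    def test_boundary(self, scale, expected):
        assert label_scale(ev("1", scale)) == expected


COMP = {
    "A": frozenset({"nucleus"}),
    "B": frozenset({"membrane"}),
    "C": frozenset({"nucleus", "cytoplasm"}),
    "D": frozenset({"cytoplasm"}),
}


class TestGoldStandard:
    def test_small_scale_evidence_makes_positive(self):
        interactions = [
            inter("A", "B", [5000, 80]),   # positive (one small-scale)
            inter("A", "D", [5000]),        # negative (HTP, disjoint)
        ]
        gold = build_gold_standard(interactions, COMP, seed=0)
        assert ("A", "B") in gold.positives
        assert gold.negatives == [("A", "D")]

    def test_overlapping_compartments_excluded(self):
        interactions = [
            inter("A", "C", [5000]),   # HTP but compartments overlap -> neither
            inter("A", "D", [5000]),
            inter("A", "B", [3]),
        ]
        gold = build_gold_standard(interactions, COMP, seed=0)
        assert ("A", "C") not in gold.negatives
        assert ("A", "C") not in gold.all_positives

    def test_unannotated_protein_cannot_be_negative(self):
        interactions = [
            inter("A", "Z", [5000]),   # Z has no compartment annotation
            inter("A", "D", [5000]),
            inter("A", "B", [3]),
        ]
        gold = build_gold_standard(interactions, COMP, seed=0)
        assert gold.negatives == [("A", "D")]

    def test_empty_negative_set_raises(self):
        with pytest.raises(EvaluationError, match="negative"):
            build_gold_standard([inter("A", "B", [3])], COMP, seed=0)

    def test_balanced_sampling_deterministic_and_seed_scoped(self):
        interactions = [inter(f"P{i}", f"Q{i}", [3]) for i in range(30)] + [
            inter("A", "D", [5000]),
            inter("A", "B", [5000]),
        ]
        g1 = build_gold_standard(interactions, COMP, seed=7)
        g2 = build_gold_standard(interactions, COMP, seed=7)
        g3 = build_gold_standard(interactions, COMP, seed=8)
        assert g1.positives == g2.positives
        assert len(g1.positives) == len(g1.negatives) == 2
        # seed changes only the positive draw, never the negatives
        assert g1.negatives == g3.negatives
        assert g1.positives != g3.positives or len(g1.all_positives) <= 2

    def test_partition(self, integrated, sidecars):
        interactions, _ = integrated
        gold = build_gold_standard(interactions, sidecars, seed=1)
        assert not set(gold.all_positives) & set(gold.negatives)


def pairwise_auc(labels, scores):
    """Oracle: Mann-Whitney P(s+ > s-) + 0.5 P(s+ == s-) by enumeration."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_worked_example(self):
        # 4 pos/neg pairs: 3 wins, 1 loss -> 0.75
        res = roc_auc([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1])
        assert res.auc == pytest.approx(0.75)

    def test_perfect_and_constant(self):
        assert roc_auc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]).auc == 1.0
        assert roc_auc([1, 0, 1, 0], [0.5] * 4).auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            roc_auc([1, 1], [0.5, 0.4])

    def test_curve_endpoints_and_monotone(self):
        rng = np.random.default_rng(5)
        res = roc_auc(rng.integers(0, 2, 50).tolist(),
                      rng.random(50).round(1).tolist())
        assert (res.fpr[0], res.tpr[0]) == (0.0, 0.0)
        assert (res.fpr[-1], res.tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(res.fpr) >= 0) and np.all(np.diff(res.tpr) >= 0)

    def test_matches_pairwise_oracle(self):
        """Trapezoidal AUC equals brute-force pairwise AUC, ties = 1/2."""
        rng = np.random.default_rng(17)
        for _ in range(40):
            n = int(rng.integers(4, 200))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = rng.random(n).round(2)  # rounded to force ties
            got = roc_auc(labels.tolist(), scores.tolist()).auc
            assert got == pytest.approx(pairwise_auc(labels, scores), abs=1e-12)


class TestCompareScores:
    def test_degenerate_scorers(self, integrated, sidecars, config):
        interactions, _ = integrated
        scored = pp.score_interactions(interactions, sidecars, config)
        gold = build_gold_standard(interactions, sidecars, seed=3)
        positives = set(gold.positives)
        aucs = compare_scores(
            scored,
            gold,
            extra_scores={
                "constant": lambda i, ss: 0.5,
                "label": lambda i, ss: 1.0 if i.pair in positives else 0.0,
            },
        )
        assert aucs["constant"] == pytest.approx(0.5)
        assert aucs["label"] == pytest.approx(1.0)
        for name in ("annotation", "method", "combined"):
            assert 0.0 <= aucs[name] <= 1.0

    def test_combined_beats_either_alone_in_majority(self):
        """On feature- and evidence-enriched corpora the combined score is at
        least as good as the better single score in a majority of seeds."""
        import tempfile
        from ppiscore.synth import SynthConfig, generate_corpus

        wins = 0
        n_seeds = 5
        for seed in range(n_seeds):
            with tempfile.TemporaryDirectory() as td:
                corpus = generate_corpus(SynthConfig(seed=200 + seed), td)
                tables = pp.load_sidecar_tables(corpus.sidecar_dir)
                records = []
                for p in corpus.mitab_paths:
                    records.extend(pp.read_mitab(p).records)
                for p in corpus.xml_paths:
                    records.extend(pp.read_psimi_xml(p))
                interactions, _ = pp.integrate_records(
                    records, tables.id_mapping,
                    pubmed_scales=tables.pubmed_scales,
                )
                scored = pp.score_interactions(interactions, tables)
                gold = build_gold_standard(interactions, tables, seed=seed)
                aucs = compare_scores(scored, gold)
                wins += aucs["combined"] >= max(aucs["annotation"], aucs["method"])
        assert wins > n_seeds / 2
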