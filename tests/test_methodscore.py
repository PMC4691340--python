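"""Method-based score: components, saturation, monotonicity, anti-inflation."""

import dataclasses
import itertools

import pytest
from hypothesis import given, settings, strategies as st

from ppiscore.methodscore import (
    MethodScore,
    detection_method_score,
    interaction_type_score,
    method_score,
    publication_score,
)
from ppiscore.model import BinaryInteraction, EvidenceItem, merge_evidence


def ev(pubmed, method="x-ray crystallography", itype="direct interaction",
       db="db1"):
    return EvidenceItem(
        pubmed_id=pubmed,
        interaction_types=frozenset({itype}),
        detection_methods=frozenset({method}),
        source_dbs=frozenset({db}),
    )


class TestPublicationScore:
    @pytest.mark.parametrize("n,expected", [(0, 0.0), (3, 3 / 7), (7, 1.0), (12, 1.0)])
    def test_values(self, n, expected, config):
        assert publication_score(n, config.method) == pytest.approx(expected)

    def test_monotone_up_to_saturation(self, config):
        vals = [publication_score(n, config.method) for n in range(11)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert all(b > a for a, b in zip(vals[:7], vals[1:8]))

    def test_negative_rejected(self, config):
        with pytest.raises(ValueError):
            publication_score(-1, config.method)


class TestDetectionComponent:
    def test_single_biophysical_closed_form(self, config):
        # one publication in a category with weight 1.0 -> 1.0 * min(1,7)/7
        got = detection_method_score([ev("1")], config.method, config.vocabulary)
        assert got == pytest.approx(1.0 / 7)

    def test_two_categories_frequency_weighted(self, config):
        # {biophysical 1.0, imaging 0.33}: mean(1.0, 0.33) * 2/7
        evidence = [ev("1"), ev("2", method="fluorescence microscopy")]
        got = detection_method_score(evidence, config.method, config.vocabulary)
        assert got == pytest.approx((1.0 + 0.33) / 2 * 2 / 7)

    def test_all_unknown_category(self, config):
        evidence = [ev(str(i), method="experimental interaction detection")
                    for i in range(3)]
        got = detection_method_score(evidence, config.method, config.vocabulary)
        assert got == pytest.approx(0.05 * 3 / 7)

    def test_submethod_inherits_parent_score(self, config):
        # two hybrid and two hybrid array are both complementation assays
        a = detection_method_score([ev("1", method="two hybrid")],
                                   config.method, config.vocabulary)
        b = detection_method_score([ev("1", method="two hybrid array")],
                                   config.method, config.vocabulary)
        assert a == b == pytest.approx(0.66 / 7)

    def test_unmerged_evidence_rejected(self, config):
        with pytest.raises(ValueError, match="merge"):
            detection_method_score([ev("1"), ev("1")], config.method,
                                   config.vocabulary)


class TestTypeComponent:
    def test_single_direct_interaction(self, config):
        got = interaction_type_score([ev("1")], config.method)
        assert got == pytest.approx(1.0 / 7)

    def test_unknown_floor(self, config):
        got = interaction_type_score([ev("1", itype="unknown")], config.method)
        assert got == pytest.approx(0.05 / 7)

    def test_repeat_publication_never_decreases(self, config):
        vals = [
            interaction_type_score(
                [ev(str(i), itype="physical association") for i in range(n)],
                config.method,
            )
            for n in range(1, 11)
        ]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestMethodScore:
    def test_total_is_mean(self):
        assert MethodScore(1, 1, 1).total == 1.0
        assert MethodScore(0, 0, 0).total == 0.0
        assert MethodScore(0.9, 0.75, 3 / 7).total == pytest.approx(0.69286, abs=1e-5)

    def test_empty_evidence_floor(self, config):
        inter = BinaryInteraction(pair=("A", "B"), taxon=1, evidence=[])
        ms = method_score(inter, config.method, config.vocabulary)
        assert ms.total == 0.0

    def test_saturated_interaction(self, config):
        inter = BinaryInteraction.build(
            "A", "B", 1, [ev(str(i)) for i in range(7)]
        )
        ms = method_score(inter, config.method, config.vocabulary)
        assert ms.total == pytest.approx(1.0)

    def test_database_redundancy_immunity(self, config):
        """Duplicating all evidence under another source db then re-merging
        leaves every component unchanged (anti-inflation)."""
        base = [ev("1"), ev("2", method="pull down", itype="physical association")]
        inter = BinaryInteraction.build("A", "B", 1, base)
        doubled = base + [dataclasses.replace(e, source_dbs=frozenset({"db2"}))
                          for e in base]
        inter2 = BinaryInteraction.build("A", "B", 1, doubled)
        a = method_score(inter, config.method, config.vocabulary)
        b = method_score(inter2, config.method, config.vocabulary)
        assert a == b


methods = st.sampled_from(
    ["x-ray crystallography", "two hybrid", "pull down",
     "fluorescence microscopy", "experimental interaction detection"]
)
types = st.sampled_from(
    ["direct interaction", "physical association", "association", "unknown"]
)
evidence_sets = st.lists(
    st.tuples(methods, types), min_size=0, max_size=12
).map(
    lambda pairs: [ev(str(i), method=m, itype=t) for i, (m, t) in enumerate(pairs)]
)


@settings(derandomize=True, max_examples=150)
@given(evidence_sets, st.tuples(methods, types))
def test_adding_evidence_never_decreases_score(evidence, extra):
    """Monotonicity of all components and the total under added evidence."""
    from ppiscore.config import default_config

    cfg = default_config()
    inter = BinaryInteraction.build("A", "B", 1, evidence)
    m, t = extra
    bigger = BinaryInteraction.build(
        "A", "B", 1, evidence + [ev(str(len(evidence)), method=m, itype=t)]
    )
    s0 = method_score(inter, cfg.method, cfg.vocabulary)
    s1 = method_score(bigger, cfg.method, cfg.vocabulary)
    assert s1.detection_component >= s0.detection_component - 1e-12
    assert s1.type_component >= s0.type_component - 1e-12
    assert s1.publication_component >= s0.publication_component
    assert s1.total >= s0.total - 1e-12
    for s in (s0, s1):
        for v in (s.detection_component, s.type_component,
                  s.publication_component, s.total):
            assert 0.0 <= v <= 1.0
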