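"""Method-based reliability score from merged experimental evidence.

The score follows the community MIScore recipe: three components in [0, 1] —
detection-method, interaction-type and publication — averaged into a single
method-based score. Evidence must already be merged to one item per distinct
Pubmed ID; that precondition is what prevents inflation of the score when
the same experiment is reported by several source databases.

Aggregation (the exact community formula is not public; this one preserves
its printed constraints): each component counts distinct (pubmed, category)
occurrences, and equals ``min(sum_c n_c * s_c / s, 1)`` where ``s_c`` is the
configured category weight and ``s`` the publication saturation (default 7).
Below saturation this is exactly the frequency-weighted category mean scaled
by ``n/s``; it is monotone under added evidence, bounded in [0, 1], and
saturates at ``s`` top-weight publications.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .config import MethodScoreConfig, Vocabulary, default_config
from .model import BinaryInteraction, EvidenceItem

__all__ = [
    "MethodScore",
    "publication_score",
    "detection_method_score",
    "interaction_type_score",
    "method_score",
]


@dataclass(frozen=True)
class MethodScore:
    detection_component: float
    type_component: float
    publication_component: float

    @property
    def total(self) -> float:
        return (
            self.detection_component
            + self.type_component
            + self.publication_component
        ) / 3.0


def publication_score(n_publications: int, config: MethodScoreConfig) -> float:
    """min(n, s)/s: 0 with no evidence, 1 at ``s`` (default 7) publications."""
    if n_publications < 0:
        raise ValueError(f"negative publication count {n_publications}")
    s = config.publication_saturation
    return min(n_publications, s) / s


def _check_merged(evidence: Sequence[EvidenceItem]) -> None:
    pubmeds = [e.pubmed_id for e in evidence]
    if len(pubmeds) != len(set(pubmeds)):
        raise ValueError(
            "evidence contains duplicate pubmed IDs; merge_evidence first "
            "(unmerged evidence would inflate the score)"
        )


def _occurrence_component(
    occurrences: Mapping[str, int],
    scores: Mapping[str, float],
    saturation: int,
) -> float:
    raw = sum(n * scores.get(cat, scores["unknown"]) for cat, n in occurrences.items())
    return min(raw / saturation, 1.0)


def detection_method_score(
    evidence: Sequence[EvidenceItem],
    config: MethodScoreConfig,
    vocabulary: Vocabulary | None = None,
) -> float:
    """Detection-method component over distinct (pubmed, category) occurrences.

    Every sub-method maps to one of the five scored categories (or
    "unknown") and inherits the parent category's configured score.
    """
    _check_merged(evidence)
    vocab = vocabulary or default_config().vocabulary
    occ: dict[str, int] = {}
    for ev in evidence:
        cats = {vocab.method_category(m) for m in ev.detection_methods}
        for c in cats:  # one occurrence per distinct (pubmed, category)
            occ[c] = occ.get(c, 0) + 1
    return _occurrence_component(occ, config.category_scores, config.publication_saturation)


def interaction_type_score(
    evidence: Sequence[EvidenceItem], config: MethodScoreConfig
) -> float:
    """Interaction-type component over distinct (pubmed, type) occurrences."""
    _check_merged(evidence)
    occ: dict[str, int] = {}
    for ev in evidence:
        types = {
            t if t in config.type_scores else "unknown"
            for t in ev.interaction_types
        }
        for t in types:
            occ[t] = occ.get(t, 0) + 1
    return _occurrence_component(occ, config.type_scores, config.publication_saturation)


def method_score(
    interaction: BinaryInteraction,
    config: MethodScoreConfig | None = None,
    vocabulary: Vocabulary | None = None,
) -> MethodScore:
    """Average of the detection, type and publication components.

    Empty evidence is a defined floor (all components 0), not an error:
    every interaction gets a score.
    """
    if config is None:
        config = default_config().method
    return MethodScore(
        detection_component=detection_method_score(
            interaction.evidence, config, vocabulary
        ),
        type_component=interaction_type_score(interaction.evidence, config),
        publication_component=publication_score(interaction.n_publications, config),
    )
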