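"""Gold-standard construction and ROC/AUC evaluation of reliability scores.

Positives are interactions supported by at least one small-scale experiment
(a publication reporting <= 100 associations); negatives are interactions
supported only by high-throughput experiments whose proteins are annotated
to disjoint cellular compartments. Positives are down-sampled uniformly to
the negative count so the two classes are balanced, and each score is
compared by the area under its ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .combine import ScoreSet
from .io import SidecarTables
from .model import BinaryInteraction, EvidenceItem

__all__ = [
    "GoldStandard",
    "RocResult",
    "EvaluationError",
    "label_scale",
    "build_gold_standard",
    "roc_auc",
    "compare_scores",
]


class EvaluationError(ValueError):
    pass


def label_scale(evidence: EvidenceItem, cutoff: int = 100) -> str:
    """Label one evidence item: ``small_scale`` iff its publication reported
    <= ``cutoff`` associations, else ``high_throughput``."""
    return "small_scale" if evidence.scale <= cutoff else "high_throughput"


@dataclass
class GoldStandard:
    positives: list[tuple[str, str]]
    negatives: list[tuple[str, str]]
    sampling_seed: int
    all_positives: list[tuple[str, str]] = field(default_factory=list)


def build_gold_standard(
    interactions: Sequence[BinaryInteraction],
    compartments: Mapping[str, frozenset[str]] | SidecarTables,
    seed: int,
    scale_cutoff: int = 100,
) -> GoldStandard:
    """Build balanced positive/negative sets from evidence scale and localization.

    Positive: >= 1 small-scale evidence item. Negative: all evidence
    high-throughput AND both proteins have known, disjoint compartment
    annotations (a protein without any localization cannot witness
    "different compartments"). Positives are down-sampled without
    replacement to the negative count using ``seed``; the negative set never
    depends on the seed.
    """
    comp = (
        compartments.compartments
        if isinstance(compartments, SidecarTables)
        else compartments
    )
    positives: list[tuple[str, str]] = []
    negatives: list[tuple[str, str]] = []
    for interaction in interactions:
        if not interaction.evidence:
            continue
        labels = [label_scale(e, scale_cutoff) for e in interaction.evidence]
        if "small_scale" in labels:
            positives.append(interaction.pair)
            continue
        a, b = interaction.pair
        ca = comp.get(a, frozenset())
        cb = comp.get(b, frozenset())
        if ca and cb and not (ca & cb):
            negatives.append(interaction.pair)
    if not negatives:
        raise EvaluationError(
            "empty negative set: no all-high-throughput interaction with "
            "disjoint compartment annotations"
        )
    rng = np.random.default_rng(seed)
    if len(positives) > len(negatives):
        idx = rng.choice(len(positives), size=len(negatives), replace=False)
        sampled = [positives[i] for i in sorted(idx)]
    else:
        sampled = list(positives)
    return GoldStandard(
        positives=sampled,
        negatives=negatives,
        sampling_seed=seed,
        all_positives=positives,
    )


@dataclass
class RocResult:
    """ROC curve (thresholds descending) and its trapezoidal AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.fpr.tolist(), self.tpr.tolist()))


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> RocResult:
    """ROC curve over all distinct score thresholds and its trapezoidal AUC.

    Tied scores collapse into a single step, which makes the trapezoidal
    area equal the Mann-Whitney statistic P(s+ > s-) + 0.5 P(s+ == s-).
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise EvaluationError("labels and scores must have equal length")
    if len(np.unique(y)) < 2:
        raise EvaluationError("both classes must be present to compute a ROC curve")
    fpr, tpr, thr = _roc_curve(y, s, drop_intermediate=False)
    return RocResult(thresholds=thr, fpr=fpr, tpr=tpr, auc=float(_trapezoid_auc(fpr, tpr)))


def compare_scores(
    scored: Sequence[tuple[BinaryInteraction, ScoreSet]],
    gold: GoldStandard,
    extra_scores: Mapping[str, Callable[[BinaryInteraction, ScoreSet], float]]
    | None = None,
) -> dict[str, float]:
    """AUC of the annotation, method and combined scores on one balanced draw.

    ``extra_scores`` adds externally supplied scorers evaluated on the same
    sets. Deterministic given the gold standard (hence given its seed).
    """
    by_pair = {i.pair: (i, ss) for i, ss in scored}
    pairs = list(gold.positives) + list(gold.negatives)
    missing = [p for p in pairs if p not in by_pair]
    if missing:
        raise EvaluationError(f"{len(missing)} gold-standard pairs lack scores")
    labels = [1] * len(gold.positives) + [0] * len(gold.negatives)
    scorers: dict[str, Callable[[BinaryInteraction, ScoreSet], float]] = {
        "annotation": lambda i, ss: ss.annotation,
        "method": lambda i, ss: ss.method,
        "combined": lambda i, ss: ss.combined,
    }
    if extra_scores:
        scorers.update(extra_scores)
    out: dict[str, float] = {}
    for name, fn in scorers.items():
        values = [fn(*by_pair[p]) for p in pairs]
        out[name] = roc_auc(labels, values).auc
    return out
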