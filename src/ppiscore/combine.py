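"""Combined reliability score and confidence classification.

The combined score is the geometric mean of the annotation-based and
method-based scores. An interaction is high confidence when the combined
score exceeds 0.281 (strict); the per-score flags use non-strict boundaries
(annotation >= 0.5, method >= 0.485) and are reported separately for
transparency. An optional config switch additionally grants high confidence
when either individual flag is set; it is off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .config import PipelineConfig, default_config
from .io import SidecarTables
from .model import BinaryInteraction
from .annoscore import annotation_score_for
from .methodscore import method_score

__all__ = ["ScoreSet", "combined_score", "classify", "score_interactions"]


@dataclass(frozen=True)
class ScoreSet:
    """All reliability scores and confidence flags for one interaction."""

    annotation: float
    method: float
    combined: float
    high_confidence: bool
    annotation_flag: bool
    method_flag: bool


def combined_score(annotation: float, method: float) -> float:
    """Geometric mean sqrt(a*m); symmetric, 0 if either score is 0."""
    for name, v in (("annotation", annotation), ("method", method)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} score {v} outside [0,1]")
    return math.sqrt(annotation * method)


def classify(
    annotation: float,
    method: float,
    config: PipelineConfig | None = None,
) -> ScoreSet:
    """Compute the combined score and confidence flags.

    Boundary semantics: combined strictly greater than the cutoff;
    annotation and method flags non-strict at theirs. Classification uses
    full double precision (before any serialization rounding).
    """
    cfg = config or default_config()
    combined = combined_score(annotation, method)
    annotation_flag = annotation >= cfg.annotation.high_confidence_cutoff
    method_flag = method >= cfg.method.high_confidence_cutoff
    high = combined > cfg.combine.high_confidence_cutoff
    if cfg.combine.either_score_rule:
        high = high or annotation_flag or method_flag
    return ScoreSet(
        annotation=annotation,
        method=method,
        combined=combined,
        high_confidence=high,
        annotation_flag=annotation_flag,
        method_flag=method_flag,
    )


def score_interactions(
    interactions: Sequence[BinaryInteraction],
    context: SidecarTables,
    config: PipelineConfig | None = None,
) -> list[tuple[BinaryInteraction, ScoreSet]]:
    """Score every interaction; no interaction is left without a ScoreSet."""
    cfg = config or default_config()
    out = []
    for interaction in interactions:
        _, _, anno = annotation_score_for(interaction, context, cfg.annotation)
        ms = method_score(interaction, cfg.method, cfg.vocabulary)
        out.append((interaction, classify(anno, ms.total, cfg)))
    return out
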