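"""Score-parameter configuration.

All tunable numbers (category/type weights, likelihood ratios, cutoffs, the
controlled-vocabulary tables) live in one JSON document. The shipped defaults
are stand-ins for the published community values where those are not freely
reproducible; every entry can be overridden from a user JSON file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

__all__ = [
    "MethodScoreConfig",
    "AnnotationScoreConfig",
    "CombineConfig",
    "Vocabulary",
    "PipelineConfig",
    "ConfigError",
    "load_config",
    "default_config",
]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class MethodScoreConfig:
    category_scores: Mapping[str, float]
    type_scores: Mapping[str, float]
    publication_saturation: int = 7
    high_confidence_cutoff: float = 0.485

    def __post_init__(self) -> None:
        for name, table in (
            ("category_scores", self.category_scores),
            ("type_scores", self.type_scores),
        ):
            if "unknown" not in table:
                raise ConfigError(f"{name} must include an 'unknown' entry")
            for term, s in table.items():
                if not 0.0 <= s <= 1.0:
                    raise ConfigError(f"{name}[{term!r}]={s} outside [0,1]")
            if any(table["unknown"] > s for t, s in table.items() if t != "unknown"):
                raise ConfigError(f"{name}: 'unknown' must not exceed known scores")
        if self.publication_saturation < 1:
            raise ConfigError("publication_saturation must be >= 1")


@dataclass(frozen=True)
class AnnotationScoreConfig:
    """Likelihood-ratio tables for the three annotation features.

    In ``naive_bayes_product`` mode the LR of a feature combination is the
    product of per-feature present/absent LRs; absent-LRs default to the cube
    root of ``baseline_lr`` so the no-feature combination yields exactly the
    baseline. ``explicit_table`` mode looks the 8 combinations up directly.
    """

    mode: str = "naive_bayes_product"
    baseline_lr: float = 0.163
    present_lr: Mapping[str, float] = field(
        default_factory=lambda: {
            "interacting_domains": 14.0,
            "shared_go_term": 3.0,
            "homologous_interaction": 4.0,
        }
    )
    absent_lr: Mapping[str, float] | None = None
    explicit_table: Mapping[str, float] | None = None
    lr_score_table: list[tuple[float, float]] | None = None
    go_aspects: frozenset[str] | None = None
    high_confidence_cutoff: float = 0.5

    FEATURES = ("interacting_domains", "shared_go_term", "homologous_interaction")

    def __post_init__(self) -> None:
        if self.mode not in ("naive_bayes_product", "explicit_table"):
            raise ConfigError(f"unknown annotation-score mode {self.mode!r}")
        if self.baseline_lr <= 0:
            raise ConfigError("baseline_lr must be positive")
        for f in self.FEATURES:
            if f not in self.present_lr:
                raise ConfigError(f"present_lr missing feature {f!r}")
            if self.present_lr[f] <= 0:
                raise ConfigError(f"present_lr[{f!r}] must be positive")
        if self.absent_lr is not None:
            for f in self.FEATURES:
                if self.absent_lr.get(f, 0) <= 0:
                    raise ConfigError(f"absent_lr[{f!r}] must be positive")
        if self.mode == "explicit_table" and self.explicit_table is None:
            raise ConfigError("explicit_table mode requires an explicit_table")

    def absent_lrs(self) -> dict[str, float]:
        if self.absent_lr is not None:
            return dict(self.absent_lr)
        root = self.baseline_lr ** (1.0 / 3.0)
        return {f: root for f in self.FEATURES}


@dataclass(frozen=True)
class CombineConfig:
    high_confidence_cutoff: float = 0.281
    either_score_rule: bool = False


@dataclass(frozen=True)
class Vocabulary:
    """Flat controlled-vocabulary tables (no ontology traversal).

    ``detection_method_categories`` maps every valid detection-method term to
    its scoring category; sub-methods inherit the parent category's score.
    Terms absent from these tables are invalid and remapped to "unknown".
    """

    detection_method_categories: Mapping[str, str]
    interaction_types: frozenset[str]
    physical_types: frozenset[str]
    excluded_methods: frozenset[str]

    def method_category(self, term: str) -> str:
        return self.detection_method_categories.get(term, "unknown")

    def is_valid_method(self, term: str) -> bool:
        return term in self.detection_method_categories

    def is_valid_type(self, term: str) -> bool:
        return term in self.interaction_types


@dataclass(frozen=True)
class PipelineConfig:
    method: MethodScoreConfig
    annotation: AnnotationScoreConfig
    combine: CombineConfig
    vocabulary: Vocabulary
    small_scale_cutoff: int = 100


def _read_defaults() -> dict[str, Any]:
    with resources.files("ppiscore.data").joinpath("defaults.json").open() as fh:
        return json.load(fh)


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def _build(raw: dict[str, Any]) -> PipelineConfig:
    ms = raw["method_score"]
    an = raw["annotation_score"]
    cb = raw["combined_score"]
    vb = raw["vocabulary"]
    lr_table = an.get("lr_score_table")
    return PipelineConfig(
        method=MethodScoreConfig(
            category_scores=dict(ms["category_scores"]),
            type_scores=dict(ms["type_scores"]),
            publication_saturation=int(ms["publication_saturation"]),
            high_confidence_cutoff=float(ms["high_confidence_cutoff"]),
        ),
        annotation=AnnotationScoreConfig(
            mode=an["mode"],
            baseline_lr=float(an["baseline_lr"]),
            present_lr=dict(an["present_lr"]),
            absent_lr=dict(an["absent_lr"]) if an.get("absent_lr") else None,
            explicit_table=dict(an["explicit_table"])
            if an.get("explicit_table")
            else None,
            lr_score_table=[tuple(p) for p in lr_table] if lr_table else None,
            go_aspects=frozenset(an["go_aspects"]) if an.get("go_aspects") else None,
            high_confidence_cutoff=float(an["high_confidence_cutoff"]),
        ),
        combine=CombineConfig(
            high_confidence_cutoff=float(cb["high_confidence_cutoff"]),
            either_score_rule=bool(cb.get("either_score_rule", False)),
        ),
        vocabulary=Vocabulary(
            detection_method_categories=dict(vb["detection_method_categories"]),
            interaction_types=frozenset(vb["interaction_types"]),
            physical_types=frozenset(vb["physical_types"]),
            excluded_methods=frozenset(vb["excluded_methods"]),
        ),
        small_scale_cutoff=int(raw["evaluation"]["small_scale_cutoff"]),
    )


def default_config() -> PipelineConfig:
    return _build(_read_defaults())


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load the pipeline configuration, overlaying ``path`` on the defaults."""
    raw = _read_defaults()
    if path is not None:
        with open(path) as fh:
            raw = _deep_merge(raw, json.load(fh))
    return _build(raw)
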