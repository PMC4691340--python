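"""Annotation-based reliability score from features of the interacting proteins.

Three binary features are extracted for a protein pair from sidecar
annotation tables:

* the proteins carry Pfam domains known to bind each other (structurally
  observed domain-domain contacts) — the strongest single discriminant;
* the proteins share at least one Gene Ontology term (functional similarity);
* an interaction between homologs of the two proteins exists in the same or
  another species (an interolog).

Each feature contributes a likelihood ratio — P(feature | true interaction)
over P(feature | false) — and the ratios combine under a naive-Bayes
(conditional independence) assumption by multiplication, or through an
explicit 8-row table. With the shipped defaults an interaction with no
feature support has LR 0.163. The LR maps to a score in (0, 1) via
``lr / (1 + lr)``, so score > 0.5 exactly when LR > 1, the high-confidence
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import AnnotationScoreConfig, ConfigError, default_config
from .io import SidecarTables
from .model import BinaryInteraction, pair_key

__all__ = [
    "FeatureVector",
    "extract_features",
    "likelihood_ratio",
    "annotation_score",
    "annotation_score_for",
]

_FEATURES = AnnotationScoreConfig.FEATURES


@dataclass(frozen=True)
class FeatureVector:
    has_interacting_domains: bool
    shares_go_term: bool
    has_homologous_interaction: bool

    def as_dict(self) -> dict[str, bool]:
        return {
            "interacting_domains": self.has_interacting_domains,
            "shared_go_term": self.shares_go_term,
            "homologous_interaction": self.has_homologous_interaction,
        }

    def key(self) -> str:
        """8-way combination key, e.g. ``"101"`` (domains, GO, homology)."""
        return "".join("1" if v else "0" for v in self.as_dict().values())


def extract_features(
    interaction: BinaryInteraction | tuple[str, str],
    context: SidecarTables,
    config: AnnotationScoreConfig | None = None,
) -> FeatureVector:
    """Extract the three annotation features for a canonical protein pair.

    Proteins absent from a table contribute the empty set, so a completely
    unannotated protein yields all-false features (and hence the baseline
    likelihood ratio). Extraction is symmetric in the two proteins.
    """
    cfg = config or default_config().annotation
    a, b = interaction.pair if isinstance(interaction, BinaryInteraction) else interaction

    dom_a = context.domains.get(a, frozenset())
    dom_b = context.domains.get(b, frozenset())
    has_domains = any(
        context.has_domain_pair(d1, d2) for d1 in dom_a for d2 in dom_b
    )

    go_a = context.go_terms.get(a, frozenset())
    go_b = context.go_terms.get(b, frozenset())
    if cfg.go_aspects is not None:
        go_a = {t for t in go_a if t[1] in cfg.go_aspects}
        go_b = {t for t in go_b if t[1] in cfg.go_aspects}
    shares_go = bool({t for t, _ in go_a} & {t for t, _ in go_b})

    has_homolog = bool(context.homologs.get(pair_key(a, b)))

    return FeatureVector(
        has_interacting_domains=has_domains,
        shares_go_term=shares_go,
        has_homologous_interaction=has_homolog,
    )


def likelihood_ratio(
    features: FeatureVector, config: AnnotationScoreConfig | None = None
) -> float:
    """Combine per-feature likelihood ratios for one feature combination.

    Product mode multiplies the present-LR or absent-LR of each feature
    (naive Bayes); explicit-table mode looks up the 8-way combination.
    """
    cfg = config or default_config().annotation
    if cfg.mode == "explicit_table":
        table = cfg.explicit_table or {}
        key = features.key()
        if key not in table:
            raise ConfigError(f"explicit LR table missing combination {key!r}")
        lr = float(table[key])
        if lr <= 0:
            raise ConfigError(f"non-positive LR for combination {key!r}")
        return lr
    absent = cfg.absent_lrs()
    lr = 1.0
    for feature, present in features.as_dict().items():
        lr *= cfg.present_lr[feature] if present else absent[feature]
    return lr


def annotation_score(
    lr: float, config: AnnotationScoreConfig | None = None
) -> float:
    """Map a likelihood ratio to a score in (0, 1).

    Default mapping ``lr / (1 + lr)``: strictly increasing with s(1) = 0.5.
    An explicit LR->score breakpoint table can override it via config
    (piecewise-linear interpolation between sorted (lr, score) points).
    """
    if lr <= 0:
        raise ValueError(f"likelihood ratio must be positive, got {lr}")
    cfg = config or default_config().annotation
    if cfg.lr_score_table:
        pts = sorted(cfg.lr_score_table)
        if lr <= pts[0][0]:
            return pts[0][1]
        if lr >= pts[-1][0]:
            return pts[-1][1]
        for (x0, y0), (x1, y1) in zip(pts, pts[1:]):
            if x0 <= lr <= x1:
                return y0 + (y1 - y0) * (lr - x0) / (x1 - x0)
    return lr / (1.0 + lr)


def annotation_score_for(
    interaction: BinaryInteraction,
    context: SidecarTables,
    config: AnnotationScoreConfig | None = None,
) -> tuple[FeatureVector, float, float]:
    """Convenience: features, LR and score for one interaction."""
    cfg = config or default_config().annotation
    fv = extract_features(interaction, context, cfg)
    lr = likelihood_ratio(fv, cfg)
    return fv, lr, annotation_score(lr, cfg)
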