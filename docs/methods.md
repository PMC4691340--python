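# Methods

This note documents the models implemented in `ppiscore`, the assumptions
behind them, the tunable parameters, and the choices made where the design
was genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and integration

An interaction evidence item is a Pubmed ID with its sets of
controlled-vocabulary interaction-type and detection-method terms, the
number of associations that publication reported (its *scale*), and the
source databases that contributed it. A binary interaction is an unordered
pair of canonical accessions within one taxon, holding exactly one evidence
item per distinct Pubmed ID.

Integration runs in a fixed stage order: spoke expansion → term
normalization → physicality filter → protein/same-species filter →
identifier canonicalization → deduplication → species census threshold.
The order affects only which reason a doomed pair is rejected under, never
the surviving set; the pipeline output is invariant under permutation of
the input records and is a fixed point of re-integration.

Choices worth knowing about:

* **Spoke model.** Complexes expand to bait–prey pairs; with k ≥ 2 baits the
  C(k,2) bait–bait pairs are added. No prey–prey pairs are ever emitted
  (pure spoke). A two-participant record passes through as binary unless its
  participants are explicitly role-annotated as preys with no bait, in which
  case it is a bait-less complex fragment and is rejected like any no-bait
  complex.
* **Physicality at evidence granularity.** A pair is kept if *any* evidence
  item passes the physicality rules; failing items are pruned from kept
  pairs. An evidence item passes when its type set intersects {association,
  physical association, direct interaction} ∪ {unknown} and it retains at
  least one method other than genetic interference. "unknown" (the sentinel
  for invalid/obsolete terms) deliberately passes: such evidence is retained
  and scored poorly rather than discarded, which is why both score tables
  carry an "unknown" entry. Known non-physical types (colocalization,
  genetic interaction, predicted interaction) reject.
* **Scale conflicts.** When databases disagree on a publication's
  association count, the maximum wins — conservative, since a larger scale
  pushes evidence toward the high-throughput label used in evaluation.
* **Unmapped identifiers** reject the pair into an auditable report (the
  automated counterpart of a manual-confirmation step); the identifier
  mapping table must carry identity rows for already-canonical accessions.
* **Experiment scale sidecar.** Neither MITAB 2.5/2.7 nor PSI-MI XML carries
  per-publication association counts, so scales arrive as a
  `pubmed_scales.tsv` sidecar (pubmed → n_associations) attached during
  integration; evidence without an entry defaults to scale 1 (small-scale).
* **Self-interactions are retained**; records without a parseable taxon are
  rejected at parse time because the cross-species filter needs the taxon.
* Homology arrives as an input table of homologous interaction pairs; how
  such tables are built upstream (e.g. PSI-BLAST at stringent e-value) is
  provenance, not computation, here.

## Method-based score

Three components in [0, 1], averaged. With saturation s (default 7):

* publication: `min(n, s)/s` over n distinct publications;
* detection-method and interaction-type: count one occurrence per distinct
  (publication, category) pair — categories for methods are {biophysical,
  biochemical, protein complementation assay, imaging technique,
  post-transcriptional interference, unknown}, every sub-method inheriting
  its parent category's score; for types the categories are the type terms
  themselves — then score `min(Σ_c n_c·s_c / s, 1)`.

Below saturation this equals the frequency-weighted category mean scaled by
n/s; unlike the plain weighted mean it is *monotone*: adding evidence can
never lower a component, which a weighted mean violates once saturated
(appending a low-weight category would dilute it). The component is bounded,
frequency-sensitive, and saturates once s top-weight publications accrue.
Requiring merged evidence (unique Pubmed IDs) as a precondition — violating
it is an error, not a warning — is what makes the score immune to the same
experiment arriving from several databases.

Default category scores (config, `data/defaults.json`): biophysical 1.0,
biochemical 1.0, protein complementation assay 0.66, imaging technique 0.33,
post-transcriptional interference 0.33, unknown 0.05; type scores: direct
interaction 1.0, physical association 0.75, association 0.33, unknown 0.05.
These are stand-ins in the spirit of the community (HUPO PSI-MI) defaults,
which are not reproduced verbatim; every value is replaceable via JSON
config. Suggested high-confidence cutoff 0.485 (config).

## Annotation-based score

Three binary features per pair: an interacting Pfam domain pair (some
d₁ ∈ domains(A), d₂ ∈ domains(B) with (d₁,d₂) in the interacting-pair
table, order-invariant), a shared GO term (exact term-ID equality, no
ancestor closure; optionally restricted to chosen GO aspects), and a
homologous interaction (the homolog map contains the pair). Proteins absent
from a table contribute empty sets, so an unannotated protein yields the
all-false vector. Extraction is symmetric in the pair.

Likelihood ratios combine under conditional independence:
`LR = Π_f (present_f ? LR⁺_f : LR⁻_f)`, or through an explicit 8-row table
(both modes are provided because the original formulation is not pinned
down; product mode is the default). Shipped defaults: LR⁺ = 14 / 3 / 4 for
domains / GO / homology — domains carry the most weight, being the best
single discriminant — and LR⁻ = 0.163^(1/3) ≈ 0.5466 for each, calibrated
so the feature-less combination yields exactly the documented baseline
LR = 0.163. Any table must satisfy: baseline < 1, LR non-decreasing as
features are added.

The LR→score map is `s = LR/(1+LR)` by default: strictly increasing, with
s(1) = 0.5, so *score > 0.5 ⇔ LR > 1* for every valid table (this
equivalence is property-tested, and an explicit breakpoint table can
override the map via config, interpolated piecewise-linearly).

## Combined score and classification

`C = sqrt(A·M)`; symmetric, annihilated by either zero, and between
min(A,M) and max(A,M). High confidence is `C > 0.281` — strict, so a score
of exactly 0.281 is low confidence — while the per-score flags are
non-strict (`A ≥ 0.5`, `M ≥ 0.485`) and reported separately. The published
wording ties the three cutoffs together ambiguously; this implementation
makes the combined rule the sole criterion and leaves an `either_score_rule`
config switch (off by default) for the reading in which either individual
flag suffices. Scores are computed and classified in double precision;
serialization rounds to 6 decimals after classification.

## Evaluation

An evidence item is small-scale iff scale ≤ 100, else high-throughput.
Positives: ≥ 1 small-scale item. Negatives: all items high-throughput AND
both proteins have known, disjoint compartment annotations — a protein
without localization data cannot witness "different compartments", so it
never enters the negative set (the protocol is silent here; absence of
annotation is not evidence of separation). Positives are down-sampled
without replacement to the negative count; the seed changes only that draw,
never the negatives. ROC curves group tied scores into single steps, so the
trapezoidal AUC equals the Mann–Whitney statistic P(s⁺ > s⁻) + ½P(s⁺ = s⁻);
the implementation delegates to scikit-learn and is tested against a
brute-force pairwise oracle. Repeated balanced draws (default 20) give
mean ± sd AUCs.

## Synthetic corpus generator

The generator emulates the statistical shape of real integrated
interactomes rather than any particular release:

* ~400 interactions among 160 proteins in 3 taxa (plus a planted rare taxon
  whose 4 interactions fall below the ≥ 10 census threshold); 20% of pairs
  arrive through co-purification complexes (1–2 baits, 1–4 preys, single
  mostly-high-throughput publication); 3 source databases with 30%
  cross-database re-reporting of the same publication.
* 30% of interactions are planted spurious. Publications per interaction:
  single with probability 0.87 (true) / 0.91 (spurious) — an overall
  single-publication share of ~0.88, matching the documented shape of real
  corpora — else uniform 2–8. Each publication is small-scale with
  probability 0.4 (true) / 0.03 (spurious), so roughly three quarters of
  interactions end up supported only by high-throughput evidence.
* Detection-method categories, interaction types and the three annotation
  features are all conditioned on true/spurious status (e.g. P(interacting
  domain pair) = 0.5 vs 0.08; direct interaction more likely for true
  pairs; true pairs colocalized with probability 0.9). Deliberately, *no*
  generative choice is conditioned on experiment scale itself: the gold
  standard labels by scale, and letting any score's inputs depend on scale
  directly would leak the evaluation label into that score. 10% of proteins
  carry no annotations at all.
* Defective records are planted in exact known numbers (cross-species,
  non-protein, colocalization-only, genetic-interference, no-bait
  complexes, unmappable identifiers), each constructed to fail exactly one
  filter, so reject-reason counters are predictable.

`expected_integration` recomputes the integration outcome from the
record-level ground truth by direct application of the curation rules — a
separate, dict-based code path that never touches the parsers or the
pipeline — and is the oracle the pipeline is tested against (pair sets,
per-pair distinct-publication counts and reject counters must match
exactly, across many random configurations).

What a green evaluation run does and does not establish: the generator
plants conditional independence between the experimental profile and the
annotation features given status, which favors the naïve-Bayes combination
and the geometric mean; real corpora have correlated evidence (the same
screens populate both the interaction and the annotation databases),
shared high-throughput publications across thousands of pairs, and
ontology-structured GO annotations, none of which are emulated. The
synthetic result that the combined score outperforms either component is
therefore a consistency check of the machinery under the stated world, not
a reproduction of any published benchmark; published corpus-scale figures
require the original source-database releases and are out of scope here.

## Numerical and degenerate-input conventions

* Empty evidence gives a defined method-score floor of 0, not an error;
  every interaction in a corpus receives a full score set.
* `annotation_score` rejects LR ≤ 0; likelihood tables with non-positive
  entries are config errors.
* Pair keys are lexicographic-ordered tuples; all writers sort by pair key
  and serialize scores to 6 decimals, so outputs are byte-reproducible.
* The evidence-scale tie-break (maximum across databases) and the
  first-failing-reason attribution (indirect type before genetic method)
  are fixed conventions, documented rather than configurable.
* Seeds: corpus generation and positive-set sampling are fully determined
  by their integer seeds (`numpy.random.default_rng`).

## Known limitations

* PSI-MI XML support covers the compact 2.5 dialect only (no expanded form,
  no XML 3.0); the controlled vocabulary is a flat shipped table, not an
  ontology, so term validity is exact-name matching.
* GO sharing ignores the ontology graph; a parent/child term pair does not
  count as shared.
* The shipped likelihood ratios and category scores are documented,
  configurable stand-ins, not fitted values; conclusions about absolute
  score magnitudes should not be drawn from the defaults.
* The evaluation protocol inherits the label noise of its construction:
  interactions can be genuinely true yet enter the negative set (all-HTP
  evidence, disjoint annotations), which bounds attainable AUCs below 1.
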