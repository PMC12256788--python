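# Methods

## Scope and model

`mitotriage` screens per-sample mtDNA variant calls (rCRS coordinates,
1-based, 16,569 bp) for likely disease-causing alleles by combining a
genotype filter cascade with an HPO-based phenotype similarity score. It
consumes variant calls, sample QC metrics, a variant annotation table, a
haplogroup marker table, patient HPO profiles, a reference proband table and
an OBO ontology; it does not do read-level work (mapping, NUMT removal,
heteroplasmy quantification, sequence-based haplogroup calling), which is
the job of an upstream mtDNA pipeline.

## Ontology and information content

Only `is_a` edges are used; other OBO relationship types are ignored, which
matches standard practice for HPO similarity. Obsolete terms are retained
solely to resolve `replaced_by` pointers during profile validation
(unknown terms are dropped with a warning; obsolete terms map to their
replacement or are dropped). The root is auto-detected as the unique
parentless term, with an explicit override for ontologies with several
top-level stanzas. Ancestor closures are reflexive, so the most informative
common ancestor (MICA) of a term with itself is the term.

Information content is corpus-based and reported in nats:
`IC(t) = −ln(freq(t)/N)`, where a profile annotates `t` if it contains `t`
or any strict descendant. The log base is a free choice — Lin's ratio is
base-invariant — and is fixed at `e` for consistency with the IC values the
score table reports. Terms absent from the corpus receive the add-one
smoothed probability `1/(N+1)` so similarity never becomes infinite or
undefined; this preserves anti-monotonicity of IC along edges (an absent
child under a present parent gets `ln(N+1)`, which exceeds any present
term's IC).

**IC corpus.** The corpus is an explicit argument everywhere. The pipeline
default pools the reference profiles with the validated patient cohort
(`ic_corpus = "cohort"`). With a reference table alone — especially a small
one — annotation frequencies are too coarse to distinguish specific terms
from mid-level branch terms, which inflates chance matches between unrelated
profiles; pooling the cohort gives IC the frequency resolution that
corpus-based similarity assumes. The cost is that a patient's score depends
weakly on the rest of the cohort; `ic_corpus = "references"` restores
strictly reference-determined scores when that matters more.

## Similarity score

Term similarity is Lin's measure; 0/0 cases (both terms IC 0, e.g. the
root) return 0 rather than NaN. Profile similarity is the symmetric
best-match average; an asymmetric (patient→reference) variant is available
by configuration. A patient's phenotype similarity score is the **maximum**
profile similarity over the reference table — similarity to the closest
previously reported case — with ties broken toward the first reference in
table order. A mean aggregation is available by configuration.

Scoring uses the full validated term set; redundant ancestors are *not*
removed before scoring, because reduction changes best-match means. The
reported per-patient `n_terms` and `mean_ic` are computed on the
non-redundant reduction (no retained term is a strict ancestor of another),
which is the right basis for asking "how many independent phenotype
observations does this patient have, and how specific are they".

Two implementations coexist: direct common-ancestor enumeration
(`lin_sim`/`profile_sim`) and a precomputed term-pair matrix
(`SimilarityScorer`) for cohort-scale work; tests assert their agreement to
1e-12 against a brute-force oracle.

## Variant filter cascade

* Sample QC: `assembled_fraction ≥ 0.5` and `mean_depth ≥ 5×`, both
  inclusive. Samples present in the calls but absent from the QC table are
  a hard error.
* Haplogroup markers: each sample is assigned the haplogroup whose defining
  markers it carries at the highest fraction, counting only variants with
  heteroplasmy ≥ 0.9 (lineage markers are essentially homoplasmic, so this
  keeps low-level artifacts from driving assignment); ties break
  lexicographically. A pre-computed haplogroup column takes precedence over
  this deliberately simple classifier. Only markers of the sample's *own*
  haplogroup are excluded.
* Prioritization: heteroplasmy ≥ 1 % is mandatory (inclusive), then the
  first satisfied clause of: confirmed status → phenotype-database
  membership → reported status with allele frequency strictly < 0.2 %.
  A "reported" annotation lacking an allele frequency cannot satisfy the
  frequency clause; it is logged and fails. Unannotated variants behave as
  status "absent".

The three gates are independent predicates, so their order does not change
the survivor set; the funnel report simply applies them QC → marker →
cascade and asserts count conservation at every stage. All thresholds are
configuration with the defaults above. Variants are keyed as
`(position, ref, alt)` with shared-suffix/prefix trimming for indels on VCF
ingestion; control-region-spanning alleles are out of scope.

## Threshold calibration

The positive class is the mtDNA-disease group; nuclear-mitochondrial and
nuclear-other are pooled as negatives. The prediction rule is
`score ≥ threshold ⇒ positive`. Candidate thresholds are midpoints between
adjacent distinct scores plus ∓∞ sentinels, so each achievable confusion
table appears once. AUC uses the Mann–Whitney identity (ties 0.5) and its
95 % CI the DeLong placement-variance method with normal quantiles, clipped
to [0, 1]. Youden's J = sens + spec − 1 is maximized over candidate
thresholds with ties resolved toward the smallest threshold (the screening
use case favours sensitivity); tie detection uses a 1e-9 tolerance because
mathematically equal J values can differ by ~1e-16 in floating point while
distinct J values are at least `1/(n₁·n₂)` apart.

Tier boundaries are `low < 0.3 ≤ medium < 0.5 ≤ high`. Whether the
fixed-threshold sensitivities/specificities use `≥` or `>` is a
configuration switch (`inclusive`), defaulting to `≥` consistently with the
prediction rule.

Group comparisons use the tie-corrected Kruskal–Wallis H (scipy) followed by
Dunn's pairwise z tests on pooled midranks with the tie term
`ΣT(t³−t)/(12(N−1))`, two-sided normal p-values and Bonferroni adjustment
(`p·k`, capped at 1). In the two-group case Dunn's z² equals the
tie-corrected H, which the tests verify numerically.

## Synthetic cohorts

The generator emulates the study design the method is meant for: a
phenotype test cohort of mtDNA-disease patients versus nuclear-diagnosis
patients, plus variant tables for the genotype side.

* **References:** depth-biased random term sets (sampling probability
  proportional to DAG depth) of 6–10 terms, mutually distinct — curated
  disease annotations skew specific, and uniform sampling would make the
  matching task unrealistically easy or hard depending on DAG shape. The
  default table holds 8 profiles, scaled to the 58-term fixture ontology
  (a reference table much larger than the term universe supports makes
  accidental matches near-certain; the real setting has a term universe
  two orders of magnitude larger than its reference table).
* **mtDNA cases:** noisy copies of a random reference — each term dropped
  with probability `dropout = 0.3`; survivors replaced by a uniform strict
  ancestor (never the root) with probability `imprecision = 0.2`,
  modelling clinicians recording less specific terms; `noise_terms = 2`
  uniform random terms appended. If dropout removes everything, one
  reference term is retained, because scoring rejects empty profiles. Each
  case carries one spiked causal variant (confirmed or
  phenotype-database-annotated) with heteroplasmy uniform on [0.01, 1].
* **Nuclear patients:** 4–10 uniform random non-root terms, unrelated to
  the references by construction.
* **All samples:** a random haplogroup with its markers spiked at ≥ 0.95
  heteroplasmy (each carried with probability 0.9), Poisson(2) benign
  background variants across the heteroplasmy range, QC metrics drawn from
  the passing ranges (62–100 % assembly, 7–165×) or failing ranges for a
  configured 10 % of samples. The default group sizes are 47 / 122 / 1,338.

Everything derives from one seeded RNG in fixed order, so identical
spec + seed gives byte-identical serialized cohorts. The truth table records
group, causal variant, source reference, haplogroup and QC status per
sample.

**What this does not emulate:** real HPO release content and its annotation
frequencies, correlated phenotypes *between* nuclear patients (each draws
independently), sequencing reads, NUMT contamination, capture-kit coverage
profiles, or genuine haplogroup phylogeny. Passing tests therefore
demonstrate internal correctness and qualitative separability under the
stated noise model — not clinical performance on real cohorts.

## Pipeline policy

Patients whose phenotype records are empty after validation are kept in the
report with missing score/tier and a flag; sparse phenotyping is precisely
the failure mode that needs surfacing, and real diagnoses have been made
below any similarity threshold in such patients. The default action map is
high → review, medium → more_info, low → no_action, with `reportable`
annotations (variably penetrant LHON/SNHL-class alleles) escalating any tier
to report_back. The summary JSON echoes thresholds and policy but not file
paths, so summaries from identical inputs are byte-identical; an optional
timestamp is off by default for the same reason.

## Problem sizes

Default test and acceptance runs use the 58-term fixture ontology, 8
reference profiles, 50 mtDNA vs 500 nuclear patients (42 / 458 split,
mirroring the real cohort's nuclear-mitochondrial fraction) and 20 generator
seeds; brute-force oracle comparisons run on 200 random DAGs of ≤ 30 terms
and 500 random labeled score sets. These sizes make the whole suite run in
seconds while keeping every estimate's Monte-Carlo error far from the
asserted margins.

## Known limitations

* The haplogroup classifier is a marker-fraction heuristic, not a
  phylogenetic placement; it exists so the marker-exclusion gate is testable
  end to end and defers to upstream assignments when available.
* Scores under `ic_corpus = "cohort"` are not invariant to cohort
  composition (see above).
* DeLong's variance is asymptotic; with very few positives the CI is
  approximate, and the coverage test asserts ≥ 90 % rather than nominal
  95 % at n = 50/500.
* Indel normalization is prefix/suffix trimming only — sufficient for
  simple mtDNA indels, not a general left-alignment against the reference
  sequence.
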