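# Methods

## The scoring model

`rvescore` implements an evidence-rubric score for regulatory variants
suspected to cause rare disease by disrupting the expression of a target
gene. The model is a weighted sum of binary evidence over 24 criteria split
into two components:

* **Clinical (C)** — is there a causal link between genotype and phenotype?
  Rarity in unaffected populations, de novo occurrence, implication of the
  target gene in a similar phenotype, familial segregation, recurrence in
  unrelated probands, phenotype specificity.
* **Functional (F)** — does the variant have a damaging effect on the
  regulation of the target gene? Evolutionary conservation, predicted
  deleteriousness, overlap with transcription-factor binding regions and
  candidate cis-regulatory elements, motif disruption, patient-tissue
  expression changes, reporter and binding assays, model organisms.

Each criterion `i` receives a value `v_i ∈ {0, 1}` — 0 when the evidence
does not apply **or is unknown**, 1 when it applies — and a non-negative
weight `w_i`. The scores are

    C   = Σ_{i ∈ clinical}   v_i · w_i
    F   = Σ_{i ∈ functional} v_i · w_i
    RVE = C + F

The additivity invariant `RVE = C + F`, monotonicity under any single
0→1 flip, and the bound `0 ≤ C ≤ Σ clinical weights` (likewise for F) hold
for any rubric the loader accepts and are property-tested.

The engine is rubric-agnostic: criterion texts, weights, auto/manual modes
and binarization thresholds are data (`data/rubric_default.yaml`), not code.
Integer weights give integer scores; the engine also accepts real
non-negative weights without losing any invariant.

## The default rubric

The bundled rubric has 12 clinical criteria (max C = 17) and 12 functional
criteria (max F = 18; max RVE = 35). Six criteria — one per annotation
source — are automatic; eighteen require expert yes/no answers. The
automatic thresholds are package defaults chosen from common practice in
rare-disease variant interpretation, with units:

| criterion | source | rule | rationale |
|---|---|---|---|
| C1.1 rarity | gnomAD allele frequency | AF < 0.001 | dominant rare-disease ceiling |
| F1.1 per-base conservation | phyloP (−log p, bp-level) | ≥ 2.0 | conventional constraint cutoff |
| F1.2 element conservation | phastCons (probability) | ≥ 0.5 | conserved-element posterior majority |
| F1.3 deleteriousness | CADD (phred-scaled) | ≥ 10 | top 10% of possible SNVs |
| F1.4 TF binding | ChIP peak catalogue | ≥ 1 overlap | any observed binding |
| F1.5 regulatory element | cCRE catalogue | ≥ 1 overlap | any annotated element |

Threshold boundaries are inclusive for `ge`/`le` and exclusive for
`gt`/`lt`, exactly as the operator names say. An `absent` operator (score 1
when the allele is *missing* from a table — e.g. "never observed in
population databases") is supported by the engine but intentionally not
used in the default rubric: paired with the frequency threshold on the same
source it would make the two criteria mutually exclusive, so a variant
could never satisfy every automatic criterion at once. Users who prefer an
absence criterion can add one in a copy of the rubric file.

Weights (1 for supportive computational evidence, 2 for strong clinical or
experimental observations) are this package's documented defaults. A group
holding a locally calibrated weighting should copy `rubric_default.yaml`
and edit it; every downstream number follows the file.

## Evidence semantics and provenance

Unknown evidence scores 0, but the package distinguishes *why* a criterion
is 0 through provenance: `auto` (binarized from a measurement),
`user_answer` (explicit yes/no), `default_unknown` (never assessed), and
`user_override` (forced by the user; the pre-override value and a free-text
comment are retained). Absence of an allele from a frequency table is
reported as a `missing` measurement, never as frequency 0 — absence of
evidence and evidence of absence stay distinguishable all the way to the
report.

## Coordinates

Variants are 1-based (VCF convention); interval queries are 0-based
half-open (BED convention); `ref_span_zero_based` is the single conversion
point. Chromosome names are normalized to the `chr`-prefixed dialect, and
each annotation source declares its assembly, which must equal the
variant's label — no liftover is attempted. All queries are
strand-agnostic. For multi-base reference spans the per-base conservation
adapters report the **maximum** score over the span (the most conserved
base touched is the conservative choice for constraint evidence).

## Ranking against the reference collection

The RVE-score alone has no calibrated scale, so it is placed on the
empirical distribution of a labelled collection of published regulatory
variants (46 entries, matching the size of the curated collection in the
literature). The percentile is the ≤-count ECDF,
`100 · #{s ≤ RVE} / n`, and the strength label follows the distribution's
tertiles: below the 33.3rd percentile *low*, below the 66.7th
*intermediate*, otherwise *high*. An empty reference leaves percentile and
label unset with a logged warning rather than failing.

**The bundled reference file is synthetic.** The RVE-scores of the actual
curated collection are not redistributable from here, so
`data/reference_rve_scores_synthetic.tsv` carries 46 generated scores with
a realistic spread (range 4–30, median ≈ 15 of a maximum 35). Percentiles
and strength labels computed against it demonstrate the mechanism, not the
published calibration; clinical users must substitute a curated file via
`--reference`.

## The synthetic annotation bundles

`rvescore.fixtures.make_fixtures(seed, recipe, out_dir)` generates the six
source files, a manifest, a one-record VCF, a reference distribution and a
key file, all as a pure function of `(seed, recipe)`:

* **all-pass** — every automatic criterion is engineered to score 1: the
  planted variant carries AF below the rarity cutoff, conservation and
  deleteriousness above their cutoffs, and intervals overlapping its span;
* **no-coverage** — no source covers the planted variant at all, so every
  lookup is `missing` (the unknown → 0 rule end to end);
* **mixed** — each automatic criterion's bit is drawn at random, and the
  corresponding value is planted on the passing or failing side of its rule.

The key file records the planted bits, giving tests an oracle that does not
run through the adapters being tested. The bundles emulate the *formats and
query semantics* of the real resources — they do not emulate genome-scale
density, multi-population frequencies, overlapping transcript annotation,
or assembly quirks. Passing tests therefore demonstrate correct retrieval,
binarization, aggregation and reporting; they say nothing about the
biological aptness of any particular threshold on real data.

## Numerical and design notes

* Scores are exact integer arithmetic for integer weights; the report
  consistency check uses a 1e-9 tolerance only to accommodate real-valued
  weights.
* Interval overlap is any-overlap (≥ 1 shared base), standard BED
  semantics; results are returned sorted by (start, end, label) for
  determinism. The adapter is backed by an interval tree and is
  property-tested against a naive all-pairs scan.
* Duplicate rows for one allele in an allele table are an error naming the
  row, not a silent first-match.
* Sessions are append-only audit logs; the current evidence is always
  reproducible by replaying the log from an empty set, and snapshots
  (JSON, versioned schema) rebuild a session by replay. Overrides warn
  rather than fail on empty comments: justification is recommended, not
  required.
* Auto and manual criteria are disjoint; answers to automatic criteria are
  rejected, and step-3 overrides are the only way to change an automatic
  value.
* Reports are JSON (lossless, versioned schema), TSV (the per-criterion
  table) and markdown (human-readable); schema mismatches raise a
  versioned error rather than misparse.

## Problem sizes

The test suite and the acceptance script exercise: 1,000 random evidence
vectors over random toy rubrics against a brute-force summation oracle;
exhaustive single-flip monotonicity over all 2⁴ evidence vectors of a
4-criterion rubric; 10⁴ interval × variant pairs against a naive overlap
scan (including half-open boundary collisions); and full pipeline runs on
generated bundles with 50 background records per source. These sizes make
the whole suite run in seconds while leaving every check at full strength.

## Known limitations

* The default rubric's weights and thresholds are package defaults, not a
  published calibration; the bundled reference distribution is synthetic.
  Both are single data files designed to be replaced.
* Only single-variant, single-alternate-allele input is supported; no HGVS,
  no structural variants, no liftover, no live database queries.
* The score is an evidence summary, not a pathogenicity classification; it
  is complementary to, and separate from, ACMG-style classification.
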