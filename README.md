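# rvescore

Offline evidence aggregation and **RVE-scoring** for regulatory variants
implicated in rare disease.

Coding variants have mature classification machinery; variants in
promoters, enhancers and UTRs — which act by changing *how much* of a gene
is made rather than *what* is made — do not. `rvescore` is for clinical and
research geneticists assessing such a variant: it gathers the evidence that
the variant both (a) is causally linked to the patient's phenotype and
(b) damages the regulation of its suspected target gene, and condenses it
into an auditable score.

## The model

Evidence is a rubric of 24 yes/no criteria, each scored
`v_i ∈ {0, 1}` (0 = does not apply **or unknown**, 1 = applies) and
weighted:

```
C   = Σ_{i ∈ clinical}   v_i · w_i     (genotype–phenotype link)
F   = Σ_{i ∈ functional} v_i · w_i     (damaging regulatory effect)
RVE = C + F
```

Six criteria are filled automatically from local annotation files emulating
the standard resources — per-base conservation (phyloP, phastCons),
population allele frequency (gnomAD), combined deleteriousness (CADD),
transcription-factor binding peaks (ReMap-style BED) and candidate
cis-regulatory elements (ENCODE-style BED). The other eighteen are
expert yes/no answers. The final RVE-score is ranked against the empirical
distribution of a 46-entry reference collection of published regulatory
variants (the bundled file is a synthetic stand-in; substitute a curated
one with `--reference`) and labelled low / intermediate / high by tertile.

Everything criterion-specific — texts, weights, auto/manual modes,
thresholds — is data in `src/rvescore/data/rubric_default.yaml`, not code.
See `docs/methods.md` for the full model, defaults and limitations.

## Worked example

Generate a synthetic annotation bundle (no downloads needed), answer three
manual questions, override one criterion with a cited justification, and
score:

```bash
rvescore make-fixtures --seed 1 --recipe all-pass --out demo/bundle

cat > demo/answers.yaml <<'EOF'
C2.1: yes     # target gene implicated in a similar phenotype
C3.1: yes     # familial segregation observed
F3.1: yes     # reporter assay shows altered activity
EOF

cat > demo/overrides.yaml <<'EOF'
F4.1:
  value: 1
  comment: "zebrafish enhancer knockout recapitulates reduced expression (PMID:12345678, Fig 3)"
EOF

rvescore score --variant chr1:150000:G:A --gene GENE1 \
  --bundle demo/bundle/manifest.yaml \
  --answers demo/answers.yaml --overrides demo/overrides.yaml \
  --out demo/out
```

prints

```
RVE-score 15 (C 6, F 9); percentile 47.8; strength intermediate
```

and writes `report.json`, `report.tsv`, `report.md` and a replayable
`session.json` into `demo/out/`. Reading the numbers: the six automatic
criteria all passed on this engineered bundle (contributing C 2 + F 5), the
two clinical answers add 4, the reporter assay adds 2, and the override
adds 2 — C = 6 of a possible 17, F = 9 of 18. An RVE-score of 15 sits at
the 47.8th percentile of the bundled reference distribution: evidence
comparable to a mid-range published regulatory variant, with the
per-criterion table showing exactly which strands are still missing. A
slice of `report.md`:

```
| C1.1 Variant is rare in unaffected reference populations | clinical | 1 | 2 | 2 | auto | gnomad_af: 0.000322311 | |
| C3.1 Variant shows familial segregation with the disease | clinical | 1 | 2 | 2 | user_answer | | |
| F4.1 A cellular or animal model ... recapitulates the expression change | functional | 1 | 2 | 2 | user_override | | zebrafish enhancer knockout ... |
```

Every row carries its provenance (`auto` / `user_answer` /
`user_override` / `default_unknown`), the raw database value it was
binarized from, and any comment — so a reader can audit each 0/1 call.
`rvescore annotate` dumps the raw measurements alone, and
`rvescore report --session demo/out/session.json --out ...` re-renders a
saved session.

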