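# Default 24-criterion rubric for the Regulatory Variant Evidence (RVE) score.
#
# The rubric is pure data: the scoring engine reads criterion ids, components,
# weights, modes and threshold rules from this file and attaches no meaning of
# its own to any of them.  Clinical criteria (C*) ask whether there is a causal
# link between genotype and phenotype; functional criteria (F*) ask whether the
# variant has a damaging effect on the regulation of its target gene.  Each
# criterion is scored 0 (does not apply, or unknown) or 1 (applies), then
# multiplied by its weight.
#
# Six criteria are evaluated automatically from local annotation sources, one
# per source; the remaining eighteen require expert yes/no answers.  Weights
# and automatic thresholds are package defaults (see docs/methods.md); users
# with a locally calibrated scheme should copy this file and edit it.
version: "rvescore-default-1.0"
criteria:
  # --- Clinical component: is there a causal link between genotype and phenotype?
  - id: C1.1
    component: clinical
    description: "Variant is rare in unaffected reference populations"
    weight: 2
    mode: auto
    operator: lt
    cutoff: 0.001
    source_key: gnomad_af
  - id: C1.2
    component: clinical
    description: "Variant arose de novo in the proband"
    weight: 2
    mode: manual
  - id: C2.1
    component: clinical
    description: "Suspected target gene has been implicated in the same or a similar disease phenotype, or is otherwise relevant"
    weight: 2
    mode: manual
  - id: C2.2
    component: clinical
    description: "Suspected target gene is dosage sensitive (haploinsufficiency or triplosensitivity causes disease)"
    weight: 1
    mode: manual
  - id: C2.3
    component: clinical
    description: "Coding variants in the suspected target gene cause a similar disease phenotype"
    weight: 1
    mode: manual
  - id: C3.1
    component: clinical
    description: "Variant shows familial segregation with the disease"
    weight: 2
    mode: manual
  - id: C3.2
    component: clinical
    description: "Segregation observed across multiple informative meioses or family branches"
    weight: 1
    mode: manual
  - id: C4.1
    component: clinical
    description: "Variant observed in multiple unrelated affected individuals with a consistent phenotype"
    weight: 2
    mode: manual
  - id: C4.2
    component: clinical
    description: "Variant is statistically enriched in cases relative to controls"
    weight: 1
    mode: manual
  - id: C4.3
    component: clinical
    description: "Variant recurs de novo in unrelated probands"
    weight: 1
    mode: manual
  - id: C5.1
    component: clinical
    description: "Patient phenotype is specific and consistent with the known disease spectrum of the target gene"
    weight: 1
    mode: manual
  - id: C5.2
    component: clinical
    description: "No plausible coding variant explains the phenotype after adequate sequencing"
    weight: 1
    mode: manual
  # --- Functional component: does the variant have a damaging effect on the gene?
  - id: F1.1
    component: functional
    description: "Variant position is evolutionarily conserved (per-base constraint, phyloP)"
    weight: 1
    mode: auto
    operator: ge
    cutoff: 2.0
    source_key: phylop
  - id: F1.2
    component: functional
    description: "Variant lies in a conserved element (element-level conservation, phastCons)"
    weight: 1
    mode: auto
    operator: ge
    cutoff: 0.5
    source_key: phastcons
  - id: F1.3
    component: functional
    description: "Variant is predicted deleterious by a combined annotation score (CADD, phred scale)"
    weight: 1
    mode: auto
    operator: ge
    cutoff: 10.0
    source_key: cadd
  - id: F1.4
    component: functional
    description: "Variant overlaps an experimentally observed transcription-factor binding region (ChIP peak catalogue)"
    weight: 1
    mode: auto
    operator: present
    source_key: remap
  - id: F1.5
    component: functional
    description: "Variant overlaps an annotated candidate cis-regulatory element"
    weight: 1
    mode: auto
    operator: present
    source_key: encode
  - id: F1.6
    component: functional
    description: "Variant is predicted to create or disrupt a transcription-factor binding motif"
    weight: 1
    mode: manual
  - id: F2.1
    component: functional
    description: "Expression of the target gene is altered in patient cells or tissue"
    weight: 2
    mode: manual
  - id: F2.2
    component: functional
    description: "Allele-specific expression imbalance is observed at the target gene"
    weight: 2
    mode: manual
  - id: F3.1
    component: functional
    description: "Reporter assay demonstrates altered regulatory activity of the variant allele"
    weight: 2
    mode: manual
  - id: F3.2
    component: functional
    description: "Altered transcription-factor binding demonstrated in vitro (e.g. EMSA or equivalent)"
    weight: 2
    mode: manual
  - id: F4.1
    component: functional
    description: "A cellular or animal model of the variant recapitulates the expression change"
    weight: 2
    mode: manual
  - id: F4.2
    component: functional
    description: "A cellular or animal model of the variant recapitulates the disease phenotype"
    weight: 2
    mode: manual
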