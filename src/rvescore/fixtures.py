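"""Deterministic synthetic annotation bundles for pipeline testing.

The generator plants a single variant and constructs the six annotation
source files so that each automatic criterion of the rubric evaluates to a
chosen 0/1 bit under its own threshold rule: per-base conservation scores
above or below the cutoff, an allele-table row inside or outside the
frequency threshold (or no row at all for ``absent`` rules), intervals that
do or do not overlap the variant's reference span.  The planted truths are
written to a key file so tests can assert the exact expected evidence
without re-deriving it through the code path under test.

Everything is a pure function of (seed, recipe): identical inputs yield
byte-identical directories.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError
from .rubric import Rubric, ThresholdRule, load_default_rubric
from .variant import VariantSpec, format_variant, ref_span_zero_based

RECIPES = ("all-pass", "no-coverage", "mixed")

_FILENAMES = {
    "phylop": "phylop.tsv",
    "phastcons": "phastcons.tsv",
    "gnomad_af": "gnomad_af.tsv",
    "cadd": "cadd.tsv",
    "remap": "remap.bed",
    "encode": "encode.bed",
}

#: plausible background score ranges per source, for decoy rows
_BACKGROUND_RANGES = {
    "phylop": (-3.0, 6.0),
    "phastcons": (0.0, 1.0),
    "gnomad_af": (1e-6, 0.5),
    "cadd": (0.0, 40.0),
}

_TF_NAMES = ("CTCF", "GATA4", "TBX5", "NKX2-5", "SP1", "YY1", "MEF2C", "FOXA1")
_ELEMENT_CLASSES = ("PLS", "pELS", "dELS", "DNase-H3K4me3", "CTCF-only")


def _planted_bits(rubric: Rubric, recipe: str, rng: np.random.Generator) -> dict[str, int]:
    auto = rubric.auto_criteria()
    if recipe == "all-pass":
        return {c.id: 1 for c in auto}
    if recipe == "no-coverage":
        return {c.id: 0 for c in auto}
    if recipe == "mixed":
        return {c.id: int(rng.integers(0, 2)) for c in auto}
    raise ConfigError(f"unknown fixture recipe {recipe!r}; expected one of {RECIPES}")


def _plant_scalar(rule: ThresholdRule, bit: int, rng: np.random.Generator) -> float | None:
    """A raw value that binarizes to ``bit`` under ``rule``; None plants no record."""
    margin = float(rng.uniform(0.05, 0.5))
    if rule.operator in ("ge", "gt"):
        return rule.cutoff + margin if bit else max(rule.cutoff - margin, rule.cutoff * 0.1)
    if rule.operator in ("le", "lt"):
        value = rule.cutoff * (0.5 * float(rng.uniform(0.1, 1.0))) if bit else rule.cutoff * (1.5 + margin)
        return value
    if rule.operator == "absent":
        return None if bit else float(rng.uniform(*_BACKGROUND_RANGES.get(rule.source_key, (0, 1))))
    if rule.operator == "present":
        # handled by the interval planter; scalar sources plant any value
        return float(rng.uniform(*_BACKGROUND_RANGES.get(rule.source_key, (0, 1)))) if bit else None
    raise ConfigError(f"cannot plant a value for operator {rule.operator!r}")


def make_fixtures(
    seed: int,
    recipe: str,
    out_dir: str | Path,
    *,
    rubric: Rubric | None = None,
    assembly: str = "GRCh38",
    reference_size: int = 46,
    n_background: int = 50,
) -> Path:
    """Generate an annotation bundle, a variant file, a reference file and a key file.

    Returns the bundle directory.  The key file ``key.json`` records the
    planted variant and, per automatic criterion, the evidence bit the bundle
    was engineered to produce.
    """
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rubric = rubric or load_default_rubric()

    variant = VariantSpec(
        assembly=assembly, chrom="chr1", pos=150_000, ref="G", alt="A", gene="GENE1"
    )
    span = ref_span_zero_based(variant)
    bits = _planted_bits(rubric, recipe, rng)

    # group the auto criteria by the source they read
    by_source: dict[str, list] = {}
    for c in rubric.auto_criteria():
        by_source.setdefault(c.rule.source_key, []).append(c)

    lines_by_file: dict[str, list[str]] = {name: [] for name in _FILENAMES.values()}

    for source_key, fname in _FILENAMES.items():
        lines = lines_by_file[fname]
        kind = {"phylop": "per_base", "phastcons": "per_base", "gnomad_af": "allele",
                "cadd": "allele", "remap": "interval", "encode": "interval"}[source_key]
        criteria = by_source.get(source_key, [])
        # planted rows satisfying (or refuting) each criterion on this source
        for c in criteria:
            bit = bits[c.id]
            if kind == "per_base":
                value = _plant_scalar(c.rule, bit, rng)
                if value is not None and recipe != "no-coverage":
                    lines.append(f"{variant.chrom}\t{variant.pos}\t{value:.4f}")
            elif kind == "allele":
                value = _plant_scalar(c.rule, bit, rng)
                if value is not None and recipe != "no-coverage":
                    lines.append(
                        f"{variant.chrom}\t{variant.pos}\t{variant.ref}\t{variant.alt}\t{value:.6g}"
                    )
            else:  # interval
                if bit and recipe != "no-coverage":
                    start = int(span[0] - rng.integers(0, 30))
                    end = int(span[1] + rng.integers(0, 30))
                    label = (
                        str(rng.choice(_TF_NAMES)) if source_key == "remap"
                        else str(rng.choice(_ELEMENT_CLASSES))
                    )
                    lines.append(f"{variant.chrom}\t{start}\t{end}\t{label}")
        # background decoys well away from the planted variant
        for _ in range(n_background):
            chrom = f"chr{int(rng.integers(2, 23))}"
            pos = int(rng.integers(1, 10_000_000))
            if kind == "per_base":
                lo, hi = _BACKGROUND_RANGES[source_key]
                lines.append(f"{chrom}\t{pos}\t{float(rng.uniform(lo, hi)):.4f}")
            elif kind == "allele":
                lo, hi = _BACKGROUND_RANGES[source_key]
                ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
                lines.append(f"{chrom}\t{pos}\t{ref}\t{alt}\t{float(rng.uniform(lo, hi)):.6g}")
            else:
                length = int(rng.integers(50, 500))
                label = (
                    str(rng.choice(_TF_NAMES)) if source_key == "remap"
                    else str(rng.choice(_ELEMENT_CLASSES))
                )
                lines.append(f"{chrom}\t{pos}\t{pos + length}\t{label}")

    for fname, lines in lines_by_file.items():
        (out_dir / fname).write_text("\n".join(lines) + ("\n" if lines else ""))

    manifest = {
        "sources": {
            key: {
                "path": fname,
                "assembly": assembly,
                "version_label": f"synthetic-{recipe}-seed{seed}",
            }
            for key, fname in _FILENAMES.items()
        }
    }
    (out_dir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))

    # single-record VCF for the planted variant
    vcf_lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={variant.chrom}>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
        f"{variant.chrom}\t{variant.pos}\t.\t{variant.ref}\t{variant.alt}\t.\tPASS\t.",
    ]
    (out_dir / "variant.vcf").write_text("\n".join(vcf_lines) + "\n")

    # synthetic reference distribution of RVE-scores
    ref_scores = rng.integers(0, 36, size=reference_size)
    ref_lines = ["variant_label\trve_score"] + [
        f"SYNREF_{i + 1:03d}\t{int(s)}" for i, s in enumerate(ref_scores)
    ]
    (out_dir / "reference_synthetic.tsv").write_text("\n".join(ref_lines) + "\n")

    key = {
        "seed": seed,
        "recipe": recipe,
        "variant": format_variant(variant),
        "gene": variant.gene,
        "assembly": assembly,
        "expected_auto_evidence": {cid: bits[cid] for cid in sorted(bits)},
    }
    (out_dir / "key.json").write_text(json.dumps(key, indent=2, sort_keys=True) + "\n")
    return out_dir
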