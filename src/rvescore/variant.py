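"""Variant representation and coordinate conventions.

Variants are 1-based (VCF convention); every interval query in the package
uses 0-based half-open coordinates (BED convention).  The single conversion
point between the two is :func:`ref_span_zero_based`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

from .errors import InputError

_ALLELE_RE = re.compile(r"^[ACGTN]+$", re.IGNORECASE)


def normalize_chrom(name: str) -> str:
    """Normalize a chromosome name to the 'chr'-prefixed dialect.

    Accepts both '1' and 'chr1'; mitochondrial 'MT' maps to 'chrM'.
    """
    name = name.strip()
    if not name:
        raise InputError("empty chromosome name")
    if name.lower().startswith("chr"):
        name = name[3:]
    if name.upper() == "MT":
        name = "M"
    return f"chr{name}"


@dataclass(frozen=True)
class VariantSpec:
    """The assessed variant and its suspected target gene.

    ``pos`` is the 1-based position of the first reference base; the
    reference span is [pos, pos + len(ref) - 1] in 1-based inclusive
    coordinates.
    """

    assembly: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise InputError(f"position must be >= 1 (1-based), got {self.pos}")
        if not self.ref or not self.alt:
            raise InputError("ref and alt alleles must be non-empty")
        if not _ALLELE_RE.match(self.ref):
            raise InputError(f"reference allele {self.ref!r} is not a DNA string")
        if not _ALLELE_RE.match(self.alt):
            raise InputError(f"alternate allele {self.alt!r} is not a DNA string")
        if self.ref.upper() == self.alt.upper():
            raise InputError("ref and alt alleles must differ")
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        object.__setattr__(self, "ref", self.ref.upper())
        object.__setattr__(self, "alt", self.alt.upper())


def format_variant(v: VariantSpec) -> str:
    """Render a spec back to the ``chrom:pos:ref:alt`` CLI form."""
    return f"{v.chrom}:{v.pos}:{v.ref}:{v.alt}"


def _parse_colon_string(text: str, gene: str, assembly: str) -> VariantSpec:
    parts = text.strip().split(":")
    if len(parts) != 4:
        raise InputError(
            f"variant string {text!r} must have the form chrom:pos:ref:alt"
        )
    chrom, pos_s, ref, alt = parts
    try:
        pos = int(pos_s)
    except ValueError as exc:
        raise InputError(f"variant position {pos_s!r} is not an integer") from exc
    return VariantSpec(assembly=assembly, chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene)


def _parse_vcf_file(path: Path, gene: str, assembly: str) -> VariantSpec:
    from cyvcf2 import VCF

    records = []
    for rec in VCF(str(path)):
        records.append(rec)
        if len(records) > 1:
            raise InputError(f"VCF {path} contains more than one record; one variant expected")
    if not records:
        raise InputError(f"VCF {path} contains no records")
    rec = records[0]
    if len(rec.ALT) != 1:
        raise InputError(
            f"VCF record at {rec.CHROM}:{rec.POS} is multi-allelic; one alternate allele expected"
        )
    return VariantSpec(
        assembly=assembly, chrom=rec.CHROM, pos=rec.POS, ref=rec.REF, alt=rec.ALT[0], gene=gene
    )


def parse_variant(text: str, gene: str, assembly: str) -> VariantSpec:
    """Parse a variant from a ``chrom:pos:ref:alt`` string or a one-record VCF file path."""
    candidate = Path(text)
    if candidate.suffix.lower() in {".vcf", ".gz"} or candidate.is_file():
        if not candidate.is_file():
            raise InputError(f"VCF file not found: {text}")
        return _parse_vcf_file(candidate, gene, assembly)
    return _parse_colon_string(text, gene, assembly)


def ref_span_zero_based(v: VariantSpec) -> tuple[int, int]:
    """The reference span as a 0-based half-open interval [start, end)."""
    start = v.pos - 1
    return start, start + len(v.ref)
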