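"""Offline annotation adapters.

Each of the six annotation resources the scoring workflow consults is a local
file with a small declared schema, registered in a YAML bundle manifest:

* ``phylop`` / ``phastcons`` — per-base conservation score TSVs
  (chrom, pos[1-based], score);
* ``gnomad_af`` / ``cadd`` — allele tables (chrom, pos, ref, alt, value):
  population allele frequency and combined deleteriousness score;
* ``remap`` / ``encode`` — BED3+ interval sets with a feature label in
  column 4 (transcription-factor name for binding-peak catalogues, element
  class for candidate cis-regulatory elements).

All files are plain TSV/BED text, 0-based half-open for intervals.  Absence
of a record is reported as a ``missing`` measurement, never silently as a
zero: the scoring layer decides what absence means per criterion.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import pandas as pd
import yaml
from intervaltree import IntervalTree

from .errors import ConfigError, SourceFormatError
from .rubric import Rubric
from .variant import VariantSpec, normalize_chrom, ref_span_zero_based

#: the six resources and the kind of adapter that reads each
SOURCE_KINDS: dict[str, str] = {
    "phylop": "per_base_score",
    "phastcons": "per_base_score",
    "gnomad_af": "allele_table",
    "cadd": "allele_table",
    "remap": "interval_set",
    "encode": "interval_set",
}


@dataclass(frozen=True)
class AnnotationSource:
    source_key: str
    kind: str
    assembly: str
    path: Path
    version_label: str = ""

    def __post_init__(self) -> None:
        if self.source_key not in SOURCE_KINDS:
            raise ConfigError(
                f"unknown source_key {self.source_key!r}; expected one of {sorted(SOURCE_KINDS)}"
            )
        expected = SOURCE_KINDS[self.source_key]
        if self.kind != expected:
            raise ConfigError(
                f"source {self.source_key!r} must have kind {expected!r}, got {self.kind!r}"
            )


@dataclass(frozen=True)
class Measurement:
    """The raw value an adapter extracted for one variant from one source."""

    source_key: str
    status: str  # "found" | "missing"
    value: float | None = None
    features: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.status not in ("found", "missing"):
            raise ConfigError(f"measurement status must be found/missing, got {self.status!r}")
        if self.status == "missing" and (self.value is not None or self.features is not None):
            raise ConfigError("missing measurement must not carry a value or features")
        if self.features is not None and self.value != len(self.features):
            raise ConfigError("interval measurement value must equal the overlap count")


def load_bundle(manifest_path: str | Path) -> dict[str, AnnotationSource]:
    """Read a bundle manifest mapping source_key -> {path, assembly, version_label}."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise ConfigError(f"bundle manifest not found: {manifest_path}")
    try:
        raw = yaml.safe_load(manifest_path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse bundle manifest {manifest_path}: {exc}") from exc
    if not isinstance(raw, dict) or "sources" not in raw:
        raise ConfigError(f"bundle manifest {manifest_path} must be a mapping with 'sources'")
    bundle: dict[str, AnnotationSource] = {}
    for key, entry in raw["sources"].items():
        if key in bundle:
            raise ConfigError(f"duplicate source_key {key!r} in manifest")
        path = Path(entry["path"])
        if not path.is_absolute():
            path = manifest_path.parent / path
        if not path.exists():
            raise ConfigError(f"source {key!r}: file not found: {path}")
        bundle[key] = AnnotationSource(
            source_key=key,
            kind=SOURCE_KINDS.get(key, "?"),
            assembly=str(entry["assembly"]),
            path=path,
            version_label=str(entry.get("version_label", "")),
        )
    return bundle


def _check_assembly(source: AnnotationSource, v: VariantSpec) -> None:
    if source.assembly != v.assembly:
        raise ConfigError(
            f"assembly mismatch: source {source.source_key!r} is {source.assembly!r}, "
            f"variant is {v.assembly!r}"
        )


@lru_cache(maxsize=32)
def _read_per_base_table(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None, names=["chrom", "pos", "score"],
            dtype={"chrom": str, "pos": int, "score": float},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise SourceFormatError(f"cannot parse per-base score table {path}: {exc}") from exc
    df["chrom"] = df["chrom"].map(normalize_chrom)
    return df


def lookup_per_base(source: AnnotationSource, v: VariantSpec) -> Measurement:
    """Score at the variant's reference base; max over the span for multi-base refs.

    Taking the maximum over a multi-base span reports the most conserved base
    touched by the variant — the conservative choice for evidence of constraint.
    """
    _check_assembly(source, v)
    df = _read_per_base_table(source.path)
    lo, hi = v.pos, v.pos + len(v.ref) - 1  # 1-based inclusive
    hit = df[(df["chrom"] == v.chrom) & (df["pos"] >= lo) & (df["pos"] <= hi)]
    if hit.empty:
        return Measurement(source_key=source.source_key, status="missing")
    return Measurement(source_key=source.source_key, status="found", value=float(hit["score"].max()))


@lru_cache(maxsize=32)
def _read_allele_table(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chrom", "pos", "ref", "alt", "value"],
            dtype={"chrom": str, "pos": int, "ref": str, "alt": str, "value": float},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise SourceFormatError(f"cannot parse allele table {path}: {exc}") from exc
    df["chrom"] = df["chrom"].map(normalize_chrom)
    df["ref"] = df["ref"].str.upper()
    df["alt"] = df["alt"].str.upper()
    dup = df.duplicated(subset=["chrom", "pos", "ref", "alt"], keep=False)
    if dup.any():
        row = df[dup].iloc[0]
        raise SourceFormatError(
            f"duplicate allele row in {path}: {row['chrom']}:{row['pos']}:{row['ref']}:{row['alt']}"
        )
    return df


def lookup_allele(source: AnnotationSource, v: VariantSpec) -> Measurement:
    """Exact (chrom, pos, ref, alt) lookup; no match is reported as missing."""
    _check_assembly(source, v)
    df = _read_allele_table(source.path)
    hit = df[
        (df["chrom"] == v.chrom) & (df["pos"] == v.pos) & (df["ref"] == v.ref) & (df["alt"] == v.alt)
    ]
    if hit.empty:
        return Measurement(source_key=source.source_key, status="missing")
    return Measurement(
        source_key=source.source_key, status="found", value=float(hit["value"].iloc[0])
    )


@lru_cache(maxsize=32)
def _read_interval_trees(path: Path) -> dict[str, IntervalTree]:
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None, usecols=[0, 1, 2, 3],
            names=["chrom", "start", "end", "feature"],
            dtype={"chrom": str, "start": int, "end": int, "feature": str},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise SourceFormatError(f"cannot parse interval set {path}: {exc}") from exc
    if (df["end"] <= df["start"]).any():
        bad = df[df["end"] <= df["start"]].iloc[0]
        raise SourceFormatError(
            f"interval with end <= start in {path}: {bad['chrom']}:{bad['start']}-{bad['end']}"
        )
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in df.groupby(df["chrom"].map(normalize_chrom)):
        trees[chrom] = IntervalTree.from_tuples(
            zip(sub["start"], sub["end"], sub["feature"])
        )
    return trees


def overlap_intervals(source: AnnotationSource, v: VariantSpec) -> Measurement:
    """All features whose 0-based half-open interval intersects the reference span."""
    _check_assembly(source, v)
    trees = _read_interval_trees(source.path)
    start, end = ref_span_zero_based(v)
    tree = trees.get(v.chrom)
    hits = sorted(tree.overlap(start, end), key=lambda iv: (iv.begin, iv.end, iv.data)) if tree else []
    if not hits:
        return Measurement(source_key=source.source_key, status="missing")
    features = tuple(str(iv.data) for iv in hits)
    return Measurement(
        source_key=source.source_key, status="found", value=float(len(features)),
        features=features,
    )


_LOOKUPS = {
    "per_base_score": lookup_per_base,
    "allele_table": lookup_allele,
    "interval_set": overlap_intervals,
}


def lookup(source: AnnotationSource, v: VariantSpec) -> Measurement:
    """Dispatch to the adapter matching the source kind."""
    return _LOOKUPS[source.kind](source, v)


def gather_auto_evidence(
    bundle: dict[str, AnnotationSource], v: VariantSpec, rubric: Rubric
) -> dict[str, Measurement]:
    """One raw measurement per auto criterion; manual criteria are not touched."""
    measurements: dict[str, Measurement] = {}
    for criterion in rubric.auto_criteria():
        key = criterion.rule.source_key
        if key not in bundle:
            raise ConfigError(
                f"criterion {criterion.id} reads source {key!r}, absent from the bundle"
            )
        measurements[criterion.id] = lookup(bundle[key], v)
    return measurements
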