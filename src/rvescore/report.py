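"""Structured score reports.

A report carries everything a reader needs to audit a score: a header with
the variant, the C-, F- and RVE-scores and the rank against the reference
collection; one table row per rubric criterion with its 0/1 value, weight,
contribution, raw measurement, provenance and comment; and metadata tying
the numbers to the rubric and annotation source versions that produced them.
Reports are written as JSON (lossless, versioned schema), TSV (the table)
or markdown (human-readable).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

from . import __version__
from .annotation import Measurement
from .errors import ReportSchemaError, ValidationError
from .scoring import ScoreResult
from .workflow import Session, _measurement_from_dict, _measurement_to_dict

REPORT_SCHEMA_VERSION = 1

FORMATS = ("json", "tsv", "markdown")


@dataclass(frozen=True)
class ReportRow:
    criterion_id: str
    component: str
    description: str
    value: int
    weight: float
    contribution: float
    provenance: str
    raw: Measurement | None = None
    comment: str | None = None


@dataclass(frozen=True)
class Report:
    header: dict
    rows: tuple[ReportRow, ...]
    metadata: dict

    def __post_init__(self) -> None:
        total = sum(r.contribution for r in self.rows)
        if abs(total - self.header["rve_score"]) > 1e-9:
            raise ValidationError(
                f"report header RVE-score {self.header['rve_score']} does not equal "
                f"the sum of table contributions {total}"
            )


def build_report(result: ScoreResult, session: Session, *, timestamp: str | None = None) -> Report:
    """Assemble the report for a finalized session.

    The C- and F-scores appear separately in the header so the clinical and
    functional strands of the argument can be judged on their own.
    """
    rows = []
    for criterion in session.rubric:
        ev = session.evidence.get(criterion.id)
        value = ev.value if ev is not None else 0
        rows.append(
            ReportRow(
                criterion_id=criterion.id,
                component=criterion.component,
                description=criterion.description,
                value=value,
                weight=criterion.weight,
                contribution=result.contributions[criterion.id],
                provenance=ev.provenance if ev is not None else "default_unknown",
                raw=ev.raw if ev is not None else None,
                comment=ev.comment if ev is not None else None,
            )
        )
    header = {
        "variant": f"{session.variant.chrom}:{session.variant.pos}:"
                   f"{session.variant.ref}:{session.variant.alt}",
        "assembly": session.variant.assembly,
        "gene": session.variant.gene,
        "c_score": result.c_score,
        "f_score": result.f_score,
        "rve_score": result.rve_score,
        "percentile": result.percentile,
        "strength_label": result.strength_label,
    }
    metadata = {
        "rubric_version": session.rubric.version,
        "source_versions": dict(session.source_versions),
        "tool_version": __version__,
        "timestamp": timestamp
        or datetime.now(timezone.utc).isoformat(timespec="seconds"),
    }
    return Report(header=header, rows=tuple(rows), metadata=metadata)


def _row_to_dict(row: ReportRow) -> dict:
    d = asdict(row)
    d["raw"] = _measurement_to_dict(row.raw)
    return d


def _format_raw(raw: Measurement | None) -> str:
    if raw is None:
        return ""
    if raw.status == "missing":
        return f"{raw.source_key}: no record"
    if raw.features is not None:
        return f"{raw.source_key}: {int(raw.value)} overlap(s) [{', '.join(raw.features)}]"
    return f"{raw.source_key}: {raw.value:g}"


def write_report(report: Report, path: str | Path, fmt: str) -> Path:
    """Serialize a report; JSON is lossless, TSV carries the table, markdown both."""
    path = Path(path)
    if fmt == "json":
        payload = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "header": report.header,
            "rows": [_row_to_dict(r) for r in report.rows],
            "metadata": report.metadata,
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
    elif fmt == "tsv":
        lines = ["criterion_id\tcomponent\tdescription\tvalue\tweight\tcontribution"
                 "\tprovenance\traw\tcomment"]
        for r in report.rows:
            lines.append(
                "\t".join(
                    [
                        r.criterion_id, r.component, r.description, str(r.value),
                        f"{r.weight:g}", f"{r.contribution:g}", r.provenance,
                        _format_raw(r.raw), r.comment or "",
                    ]
                )
            )
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "markdown":
        h = report.header
        pct = "n/a" if h["percentile"] is None else f"{h['percentile']:.1f}"
        label = h["strength_label"] or "n/a"
        lines = [
            f"# Regulatory variant evidence report — {h['variant']} ({h['gene']})",
            "",
            f"- Assembly: {h['assembly']}",
            f"- **RVE-score: {h['rve_score']:g}** "
            f"(C-score {h['c_score']:g}, F-score {h['f_score']:g})",
            f"- Rank vs reference collection: {pct} percentile — strength **{label}**",
            f"- Rubric: {report.metadata['rubric_version']}; "
            f"tool {report.metadata['tool_version']}; {report.metadata['timestamp']}",
            "",
            "| criterion | component | value | weight | contribution | provenance | raw | comment |",
            "|---|---|---|---|---|---|---|---|",
        ]
        for r in report.rows:
            lines.append(
                f"| {r.criterion_id} {r.description} | {r.component} | {r.value} "
                f"| {r.weight:g} | {r.contribution:g} | {r.provenance} "
                f"| {_format_raw(r.raw)} | {r.comment or ''} |"
            )
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValidationError(f"unknown report format {fmt!r}; expected one of {FORMATS}")
    return path


def read_report(path: str | Path) -> Report:
    """Read back a JSON report, field-for-field identical to what was written."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ReportSchemaError(f"cannot parse report {path}: {exc}") from exc
    if not isinstance(payload, dict) or "schema_version" not in payload:
        raise ReportSchemaError(f"report {path} has no schema_version field")
    if payload["schema_version"] != REPORT_SCHEMA_VERSION:
        raise ReportSchemaError(
            f"report {path} has schema version {payload['schema_version']!r}; "
            f"this build reads version {REPORT_SCHEMA_VERSION}"
        )
    rows = tuple(
        ReportRow(
            criterion_id=r["criterion_id"], component=r["component"],
            description=r["description"], value=r["value"], weight=r["weight"],
            contribution=r["contribution"], provenance=r["provenance"],
            raw=_measurement_from_dict(r.get("raw")), comment=r.get("comment"),
        )
        for r in payload["rows"]
    )
    return Report(header=payload["header"], rows=rows, metadata=payload["metadata"])
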