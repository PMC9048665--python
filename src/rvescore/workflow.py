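"""The three-step scoring session.

Step 1 fills the automatic criteria from the annotation bundle, step 2
applies the user's yes/no answers to the manual criteria, step 3 applies
explicit overrides (with comments, intended for citations of evidence the
databases do not hold).  Every change is appended to an audit log; the final
evidence set is always reproducible by replaying that log from an empty set.
Finalization aggregates the evidence into scores and ranks them against the
reference distribution without mutating the session.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .annotation import AnnotationSource, Measurement, gather_auto_evidence
from .errors import ValidationError
from .rubric import Rubric
from .scoring import (
    EvidenceSet,
    EvidenceValue,
    ReferenceDistribution,
    ScoreResult,
    binarize,
    compute_scores,
    rank_against_reference,
)
from .variant import VariantSpec

logger = logging.getLogger(__name__)

SESSION_SCHEMA_VERSION = 1

ANSWER_VALUES = frozenset({"yes", "no", "unanswered"})


@dataclass(frozen=True)
class AuditEntry:
    criterion_id: str
    old_value: int | None
    new_value: int
    provenance: str
    comment: str | None
    step: int
    raw: Measurement | None = None


@dataclass
class Session:
    """One scoring run: variant, rubric, current evidence and its audit trail."""

    variant: VariantSpec
    rubric: Rubric
    evidence: EvidenceSet = None  # type: ignore[assignment]
    audit: list[AuditEntry] = field(default_factory=list)
    completed_steps: set[int] = field(default_factory=set)
    source_versions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.evidence is None:
            self.evidence = EvidenceSet(self.rubric)

    def _apply(self, entry: AuditEntry) -> None:
        self.audit.append(entry)
        self.evidence[entry.criterion_id] = EvidenceValue(
            criterion_id=entry.criterion_id,
            value=entry.new_value,
            provenance=entry.provenance,
            raw=entry.raw,
            comment=entry.comment,
            previous_value=entry.old_value if entry.provenance == "user_override" else None,
        )


def step1_auto(session: Session, bundle: dict[str, AnnotationSource]) -> Session:
    """Fill every auto criterion from the bundle (idempotent; replays are audited)."""
    measurements = gather_auto_evidence(bundle, session.variant, session.rubric)
    for criterion in session.rubric.auto_criteria():
        m = measurements[criterion.id]
        value = binarize(m, criterion.rule)
        old = session.evidence[criterion.id].value if criterion.id in session.evidence else None
        session._apply(
            AuditEntry(
                criterion_id=criterion.id, old_value=old, new_value=value,
                provenance="auto", comment=None, step=1, raw=m,
            )
        )
        logger.debug(
            "criterion %s: source=%s status=%s value=%s rule=%s%s -> evidence %d",
            criterion.id, m.source_key, m.status, m.value,
            criterion.rule.operator,
            "" if criterion.rule.cutoff is None else f" {criterion.rule.cutoff}",
            value,
        )
    session.source_versions = {k: s.version_label for k, s in sorted(bundle.items())}
    session.completed_steps.add(1)
    return session


def step2_manual(session: Session, answers: dict[str, str]) -> Session:
    """Apply yes/no answers to manual criteria; unanswered criteria default to 0."""
    if 1 not in session.completed_steps:
        raise ValidationError("step 2 requires step 1 (automatic evidence) to have run")
    manual_ids = {c.id for c in session.rubric.manual_criteria()}
    for cid, answer in answers.items():
        if cid not in session.rubric:
            raise ValidationError(f"answer keyed to unknown criterion {cid!r}")
        if cid not in manual_ids:
            raise ValidationError(f"criterion {cid} is automatic; answers apply to manual criteria only")
        if answer not in ANSWER_VALUES:
            raise ValidationError(f"answer for {cid} must be yes/no/unanswered, got {answer!r}")
    for criterion in session.rubric.manual_criteria():
        answer = answers.get(criterion.id, "unanswered")
        if answer == "yes":
            value, provenance = 1, "user_answer"
        elif answer == "no":
            value, provenance = 0, "user_answer"
        else:
            value, provenance = 0, "default_unknown"
        old = session.evidence[criterion.id].value if criterion.id in session.evidence else None
        session._apply(
            AuditEntry(
                criterion_id=criterion.id, old_value=old, new_value=value,
                provenance=provenance, comment=None, step=2,
            )
        )
    session.completed_steps.add(2)
    return session


def step3_override(session: Session, overrides: dict[str, tuple[int, str]]) -> Session:
    """Force per-criterion values, retaining the previous value and comment in the audit.

    Overriding without strong documented evidence is discouraged; every
    override emits a warning, and an empty comment a second one.
    """
    if 2 not in session.completed_steps:
        raise ValidationError("step 3 requires steps 1 and 2 to have run")
    for cid, (forced, comment) in overrides.items():
        if cid not in session.rubric:
            raise ValidationError(f"override keyed to unknown criterion {cid!r}")
        if forced not in (0, 1):
            raise ValidationError(f"override for {cid} must be 0 or 1, got {forced!r}")
    for cid, (forced, comment) in overrides.items():
        old_ev = session.evidence.get(cid)
        old = old_ev.value if old_ev is not None else None
        raw = old_ev.raw if old_ev is not None else None
        logger.warning(
            "override: criterion %s forced %s -> %d (justify with strong evidence)",
            cid, old, forced,
        )
        if not comment:
            logger.warning("override for %s has no comment; a justification is recommended", cid)
        session._apply(
            AuditEntry(
                criterion_id=cid, old_value=old if old is not None else 0, new_value=forced,
                provenance="user_override", comment=comment or None, step=3, raw=raw,
            )
        )
    session.completed_steps.add(3)
    return session


def finalize(session: Session, reference: ReferenceDistribution) -> ScoreResult:
    """Aggregate and rank; pure with respect to the session."""
    if 1 not in session.completed_steps:
        raise ValidationError("finalize requires step 1 to have run")
    if len(reference) == 0:
        logger.warning("empty reference distribution; percentile and strength left unset")
    result = compute_scores(session.evidence, session.rubric)
    return rank_against_reference(result, reference)


def replay_audit(
    variant: VariantSpec, rubric: Rubric, audit: list[AuditEntry]
) -> EvidenceSet:
    """Rebuild the evidence set implied by an audit log, from empty."""
    session = Session(variant=variant, rubric=rubric)
    for entry in audit:
        session._apply(entry)
    return session.evidence


# ---------------------------------------------------------------------------
# session snapshots (JSON)

def _measurement_to_dict(m: Measurement | None) -> dict | None:
    if m is None:
        return None
    return {
        "source_key": m.source_key, "status": m.status, "value": m.value,
        "features": list(m.features) if m.features is not None else None,
    }


def _measurement_from_dict(d: dict | None) -> Measurement | None:
    if d is None:
        return None
    return Measurement(
        source_key=d["source_key"], status=d["status"], value=d["value"],
        features=tuple(d["features"]) if d.get("features") is not None else None,
    )


def save_session(session: Session, path: str | Path) -> None:
    payload = {
        "schema_version": SESSION_SCHEMA_VERSION,
        "variant": asdict(session.variant),
        "rubric_version": session.rubric.version,
        "completed_steps": sorted(session.completed_steps),
        "source_versions": session.source_versions,
        "audit": [
            {
                "criterion_id": e.criterion_id, "old_value": e.old_value,
                "new_value": e.new_value, "provenance": e.provenance,
                "comment": e.comment, "step": e.step,
                "raw": _measurement_to_dict(e.raw),
            }
            for e in session.audit
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_session(path: str | Path, rubric: Rubric) -> Session:
    """Rebuild a session from a snapshot by replaying its audit log."""
    payload = json.loads(Path(path).read_text())
    if payload.get("schema_version") != SESSION_SCHEMA_VERSION:
        raise ValidationError(
            f"session snapshot {path} has schema version {payload.get('schema_version')!r}; "
            f"this build reads version {SESSION_SCHEMA_VERSION}"
        )
    if payload.get("rubric_version") != rubric.version:
        raise ValidationError(
            f"session snapshot was recorded with rubric {payload.get('rubric_version')!r}, "
            f"not {rubric.version!r}"
        )
    variant = VariantSpec(**payload["variant"])
    session = Session(variant=variant, rubric=rubric)
    for e in payload["audit"]:
        session._apply(
            AuditEntry(
                criterion_id=e["criterion_id"], old_value=e["old_value"],
                new_value=e["new_value"], provenance=e["provenance"],
                comment=e["comment"], step=e["step"],
                raw=_measurement_from_dict(e.get("raw")),
            )
        )
    session.completed_steps = set(payload["completed_steps"])
    session.source_versions = dict(payload.get("source_versions", {}))
    return session
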