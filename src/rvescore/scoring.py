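"""Binarization, weighted aggregation and reference ranking.

Every criterion is scored 0 (the evidence does not apply, or is unknown) or
1 (the evidence applies); the clinical score C, functional score F and total
RVE-score are weighted sums

    C = sum over clinical criteria of value * weight
    F = sum over functional criteria of value * weight
    RVE = C + F.

The RVE-score is then placed on the empirical distribution of a labelled
reference collection of published regulatory variants to indicate whether
the accumulated evidence is low, intermediate or high relative to variants
the field has accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

from .annotation import Measurement
from .errors import ConfigError, ValidationError
from .rubric import COMPARISON_OPERATORS, Rubric, ThresholdRule, max_scores

PROVENANCES = frozenset({"auto", "user_answer", "user_override", "default_unknown"})

#: size of the curated reference collection the bundled distribution emulates
REFERENCE_EXPECTED_SIZE = 46


@dataclass(frozen=True)
class EvidenceValue:
    criterion_id: str
    value: int
    provenance: str
    raw: Measurement | None = None
    comment: str | None = None
    previous_value: int | None = None  # set when provenance == user_override

    def __post_init__(self) -> None:
        if self.value not in (0, 1):
            raise ValidationError(
                f"evidence for {self.criterion_id} must be 0 or 1, got {self.value!r}"
            )
        if self.provenance not in PROVENANCES:
            raise ValidationError(f"unknown provenance {self.provenance!r}")
        if self.provenance == "user_override" and self.previous_value is None:
            raise ValidationError(
                f"override for {self.criterion_id} must retain the pre-override value"
            )


class EvidenceSet(dict):
    """Mapping criterion_id -> EvidenceValue, validated against a rubric."""

    def __init__(self, rubric: Rubric, values: dict[str, EvidenceValue] | None = None):
        super().__init__()
        self.rubric = rubric
        for cid, ev in (values or {}).items():
            self[cid] = ev

    def __setitem__(self, cid: str, ev: EvidenceValue) -> None:
        if cid not in self.rubric:
            raise ValidationError(f"evidence key {cid!r} is not a rubric criterion")
        if ev.criterion_id != cid:
            raise ValidationError(f"evidence keyed {cid!r} carries criterion_id {ev.criterion_id!r}")
        super().__setitem__(cid, ev)


@dataclass(frozen=True)
class ScoreResult:
    c_score: float
    f_score: float
    rve_score: float
    contributions: dict[str, float]
    percentile: float | None = None
    strength_label: str | None = None


@dataclass(frozen=True)
class ReferenceDistribution:
    """Labelled RVE-scores of a curated collection of published regulatory variants."""

    entries: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        for label, score in self.entries:
            if score < 0:
                raise ValidationError(f"reference entry {label!r} has a negative score")

    @property
    def scores(self) -> tuple[float, ...]:
        return tuple(score for _, score in self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_tsv(
        cls, path: str | Path, *, expected_size: int | None = REFERENCE_EXPECTED_SIZE
    ) -> "ReferenceDistribution":
        """Load a (variant_label, rve_score) TSV; size-checked against the curated collection."""
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"reference distribution file not found: {path}")
        df = pd.read_csv(path, sep="\t", comment="#")
        if list(df.columns) != ["variant_label", "rve_score"]:
            raise ConfigError(
                f"reference file {path} must have columns variant_label, rve_score"
            )
        entries = tuple((str(r.variant_label), float(r.rve_score)) for r in df.itertuples())
        if expected_size is not None and len(entries) != expected_size:
            raise ValidationError(
                f"reference distribution must have {expected_size} entries, "
                f"found {len(entries)} in {path}"
            )
        return cls(entries=entries)


def binarize(m: Measurement, rule: ThresholdRule) -> int:
    """Apply a threshold rule to a raw measurement, yielding 0 or 1.

    Unknown or missing evidence scores 0 under comparison operators; the
    ``absent``/``present`` operators score on the found/missing status itself.
    Boundaries are inclusive for ge/le and exclusive for gt/lt.
    """
    if m.source_key != rule.source_key:
        raise ConfigError(
            f"rule reads source {rule.source_key!r} but measurement is from {m.source_key!r}"
        )
    if rule.operator == "absent":
        return 1 if m.status == "missing" else 0
    if rule.operator == "present":
        return 1 if m.status == "found" else 0
    if m.status != "found" or m.value is None:
        return 0
    value, cutoff = m.value, rule.cutoff
    if rule.operator == "ge":
        return 1 if value >= cutoff else 0
    if rule.operator == "gt":
        return 1 if value > cutoff else 0
    if rule.operator == "le":
        return 1 if value <= cutoff else 0
    if rule.operator == "lt":
        return 1 if value < cutoff else 0
    raise ConfigError(f"unhandled operator {rule.operator!r}")  # pragma: no cover


def compute_scores(evidence: EvidenceSet, rubric: Rubric) -> ScoreResult:
    """Aggregate an evidence set into C-, F- and RVE-scores.

    Criteria with no recorded evidence contribute 0 (unknown evidence does
    not apply).  Contributions are value * weight per criterion, in rubric
    order.
    """
    for cid in evidence:
        if cid not in rubric:
            raise ValidationError(f"evidence key {cid!r} is not a rubric criterion")
    contributions: dict[str, float] = {}
    c_score = 0.0
    f_score = 0.0
    for criterion in rubric:
        ev = evidence.get(criterion.id)
        value = ev.value if ev is not None else 0
        contribution = value * criterion.weight
        contributions[criterion.id] = contribution
        if criterion.component == "clinical":
            c_score += contribution
        else:
            f_score += contribution
    return ScoreResult(
        c_score=c_score, f_score=f_score, rve_score=c_score + f_score,
        contributions=contributions,
    )


#: strength-label cut points on the percentile scale (tertiles of the reference)
_TERTILES = (100.0 / 3.0, 200.0 / 3.0)


def rank_against_reference(
    result: ScoreResult, reference: ReferenceDistribution
) -> ScoreResult:
    """Attach an ECDF percentile and a low/intermediate/high label to a result.

    percentile = 100 * (# reference scores <= rve_score) / |reference|.
    The label follows the reference tertiles: below the 33.3rd percentile is
    low, below the 66.7th intermediate, otherwise high.  An empty reference
    leaves both fields unset.
    """
    if len(reference) == 0:
        return result
    scores = reference.scores
    pct = 100.0 * sum(1 for s in scores if s <= result.rve_score) / len(scores)
    if pct < _TERTILES[0]:
        label = "low"
    elif pct < _TERTILES[1]:
        label = "intermediate"
    else:
        label = "high"
    return replace(result, percentile=pct, strength_label=label)
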