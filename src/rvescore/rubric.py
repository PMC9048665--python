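"""The scoring rubric: 24 weighted 0/1 evidence criteria in two components.

A rubric partitions its criteria into a *clinical* component (is there a
causal link between genotype and phenotype?) and a *functional* component
(does the variant have a damaging effect on the regulation of its target
gene?).  Criteria are either *auto* — binarized from an annotation source by
a threshold rule — or *manual* — answered yes/no by the user.  The engine is
rubric-agnostic: everything criterion-specific lives in the config file.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterator

import math
import yaml

from .errors import ConfigError, ValidationError

OPERATORS = frozenset({"ge", "gt", "le", "lt", "absent", "present"})
COMPARISON_OPERATORS = frozenset({"ge", "gt", "le", "lt"})
COMPONENTS = frozenset({"clinical", "functional"})
MODES = frozenset({"auto", "manual"})

#: number of criteria the published scheme defines; enforced on production loads
DEFAULT_CRITERION_COUNT = 24

_COMPONENT_PREFIX = {"clinical": "C", "functional": "F"}


@dataclass(frozen=True)
class ThresholdRule:
    """Binarization rule an auto criterion applies to one annotation source.

    ``ge``/``gt``/``le``/``lt`` compare the raw measurement to ``cutoff``
    (inclusive for ge/le, exclusive for gt/lt); ``present`` scores 1 when the
    source yields any value (for interval sources, at least one overlap);
    ``absent`` scores 1 when it yields none (e.g. an allele never seen in a
    population database).
    """

    operator: str
    source_key: str
    cutoff: float | None = None

    def __post_init__(self) -> None:
        if self.operator not in OPERATORS:
            raise ValidationError(
                f"unknown operator {self.operator!r}; expected one of {sorted(OPERATORS)}"
            )
        if self.operator in COMPARISON_OPERATORS:
            if self.cutoff is None or not math.isfinite(self.cutoff):
                raise ValidationError(
                    f"operator {self.operator!r} requires a finite cutoff, got {self.cutoff!r}"
                )
        if not self.source_key:
            raise ValidationError("threshold rule needs a non-empty source_key")


@dataclass(frozen=True)
class Criterion:
    """One evidence criterion: id, component, weight, and how it is evaluated."""

    id: str
    component: str
    description: str
    weight: float
    mode: str
    rule: ThresholdRule | None = None

    def __post_init__(self) -> None:
        if self.component not in COMPONENTS:
            raise ValidationError(
                f"criterion {self.id}: component must be clinical or functional, got {self.component!r}"
            )
        if self.mode not in MODES:
            raise ValidationError(f"criterion {self.id}: mode must be auto or manual")
        if not self.id or not self.id[0] == _COMPONENT_PREFIX[self.component]:
            raise ValidationError(
                f"criterion {self.id!r}: id must start with "
                f"{_COMPONENT_PREFIX[self.component]!r} for component {self.component}"
            )
        if self.weight < 0:
            raise ValidationError(f"criterion {self.id}: weight must be non-negative")
        if self.mode == "auto" and self.rule is None:
            raise ValidationError(f"criterion {self.id}: auto mode requires a threshold rule")
        if self.mode == "manual" and self.rule is not None:
            raise ValidationError(f"criterion {self.id}: manual mode must not carry a rule")


@dataclass(frozen=True)
class Rubric:
    """An ordered, validated collection of criteria."""

    criteria: tuple[Criterion, ...]
    version: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for c in self.criteria:
            if c.id in seen:
                raise ValidationError(f"duplicate criterion id {c.id!r}")
            seen.add(c.id)
        for component in COMPONENTS:
            if not any(c.component == component for c in self.criteria):
                raise ValidationError(f"rubric has no {component} criteria")

    def __iter__(self) -> Iterator[Criterion]:
        return iter(self.criteria)

    def __len__(self) -> int:
        return len(self.criteria)

    def __getitem__(self, criterion_id: str) -> Criterion:
        for c in self.criteria:
            if c.id == criterion_id:
                return c
        raise KeyError(criterion_id)

    def __contains__(self, criterion_id: str) -> bool:
        return any(c.id == criterion_id for c in self.criteria)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(c.id for c in self.criteria)

    def clinical(self) -> tuple[Criterion, ...]:
        return tuple(c for c in self.criteria if c.component == "clinical")

    def functional(self) -> tuple[Criterion, ...]:
        return tuple(c for c in self.criteria if c.component == "functional")

    def auto_criteria(self) -> tuple[Criterion, ...]:
        return tuple(c for c in self.criteria if c.mode == "auto")

    def manual_criteria(self) -> tuple[Criterion, ...]:
        return tuple(c for c in self.criteria if c.mode == "manual")


def _parse_criterion(record: dict, index: int) -> Criterion:
    if not isinstance(record, dict):
        raise ConfigError(f"criterion #{index + 1}: expected a mapping, got {type(record).__name__}")
    try:
        cid = str(record["id"])
        component = str(record["component"])
        description = str(record.get("description", ""))
        weight = float(record["weight"])
        mode = str(record["mode"])
    except KeyError as exc:
        raise ConfigError(f"criterion #{index + 1}: missing required key {exc.args[0]!r}") from exc
    rule = None
    if mode == "auto":
        try:
            operator = str(record["operator"])
            source_key = str(record["source_key"])
        except KeyError as exc:
            raise ConfigError(
                f"criterion {cid}: auto mode requires key {exc.args[0]!r}"
            ) from exc
        cutoff = record.get("cutoff")
        rule = ThresholdRule(
            operator=operator,
            source_key=source_key,
            cutoff=None if cutoff is None else float(cutoff),
        )
    elif any(k in record for k in ("operator", "cutoff", "source_key")):
        raise ConfigError(f"criterion {cid}: manual mode must not carry threshold keys")
    return Criterion(
        id=cid, component=component, description=description, weight=weight, mode=mode, rule=rule
    )


def load_rubric(path: str | Path, *, enforce_count: bool = True) -> Rubric:
    """Load and validate a rubric config file.

    Parameters
    ----------
    path
        YAML file with a ``version`` label and a ``criteria`` list, one record
        per criterion (keys: id, component, description, weight, mode, and for
        auto criteria operator / cutoff / source_key).
    enforce_count
        When True (production default) the rubric must contain exactly
        :data:`DEFAULT_CRITERION_COUNT` criteria.  Tests disable this to drive
        the engine with small toy rubrics.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"rubric file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}" if mark is not None else ""
        raise ConfigError(f"cannot parse rubric file {path}{where}: {exc}") from exc
    if not isinstance(raw, dict) or "criteria" not in raw:
        raise ConfigError(f"rubric file {path} must be a mapping with a 'criteria' list")
    records = raw["criteria"]
    if not isinstance(records, list):
        raise ConfigError(f"rubric file {path}: 'criteria' must be a list")
    criteria = tuple(_parse_criterion(rec, i) for i, rec in enumerate(records))
    if enforce_count and len(criteria) != DEFAULT_CRITERION_COUNT:
        raise ValidationError(
            f"rubric must contain exactly {DEFAULT_CRITERION_COUNT} criteria, "
            f"found {len(criteria)} in {path}"
        )
    return Rubric(criteria=criteria, version=str(raw.get("version", "")))


def default_rubric_path() -> Path:
    """Path of the bundled default rubric data file."""
    return Path(resources.files("rvescore").joinpath("data/rubric_default.yaml"))


def load_default_rubric() -> Rubric:
    return load_rubric(default_rubric_path())


def max_scores(rubric: Rubric) -> tuple[float, float]:
    """Upper bounds of the clinical and functional scores (sum of weights)."""
    max_c = sum(c.weight for c in rubric.clinical())
    max_f = sum(c.weight for c in rubric.functional())
    return max_c, max_f
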