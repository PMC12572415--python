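"""Structured radiology-report data model and JSON-lines interchange format.

A radiology report is modeled as two free-text sections (``findings`` and
``impression``) plus the structured layer the downstream classifier consumes:
entities (observations, clinical findings and their modifiers), binary
relations between them, and a five-level diagnostic-certainty label on each
observation / clinical-finding entity.

Offsets are 0-based, half-open and count Unicode code points of the raw
section text, so Japanese text round-trips exactly.
"""

from __future__ import annotations

import json
import unicodedata
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

from pydantic import BaseModel, ConfigDict, Field, ValidationError

SCHEMA_VERSION = "1.0"

SectionName = Literal["findings", "impression"]
SECTION_NAMES: tuple[str, ...] = ("findings", "impression")

EntityKind = Literal[
    "observation",
    "clinical_finding",
    "anatomical_location_modifier",
    "change_modifier",
    "follow_up",
    "other_modifier",
]

#: Entity kinds that carry a diagnostic certainty and are classified downstream.
FINDING_KINDS: frozenset[str] = frozenset({"observation", "clinical_finding"})

#: Five-level diagnostic certainty scale; "denial" marks negated findings.
CertaintyLabel = Literal["definite", "likely", "may_represent", "unlikely", "denial"]
CERTAINTY_LABELS: tuple[str, ...] = (
    "definite",
    "likely",
    "may_represent",
    "unlikely",
    "denial",
)

RelationType = Literal["modifies", "recommends_follow_up"]


class Section(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: SectionName
    text: str = ""


class Span(BaseModel):
    """Half-open [start, end) code-point offsets into the owning section text."""

    model_config = ConfigDict(extra="forbid")

    start: int
    end: int

    def slice(self, text: str) -> str:
        return text[self.start : self.end]


class Entity(BaseModel):
    model_config = ConfigDict(extra="forbid")

    id: str
    kind: EntityKind
    section: SectionName
    span: Span
    surface: str
    certainty: Optional[CertaintyLabel] = None


class Relation(BaseModel):
    """Directed relation from a modifier/follow-up entity to a finding entity."""

    model_config = ConfigDict(extra="forbid")

    head: str
    tail: str
    type: RelationType


class StructuredReport(BaseModel):
    model_config = ConfigDict(extra="forbid")

    report_id: str
    sections: list[Section]
    entities: list[Entity] = Field(default_factory=list)
    relations: list[Relation] = Field(default_factory=list)
    metadata: dict = Field(default_factory=dict)

    def section_text(self, name: str) -> str:
        for section in self.sections:
            if section.name == name:
                return section.text
        raise KeyError(name)

    def entity_by_id(self, entity_id: str) -> Entity:
        for entity in self.entities:
            if entity.id == entity_id:
                return entity
        raise KeyError(entity_id)

    def finding_entities(self) -> list[Entity]:
        return [e for e in self.entities if e.kind in FINDING_KINDS]


class Violation(BaseModel):
    """One violated invariant; collected (not raised) by :func:`validate_report`."""

    model_config = ConfigDict(extra="forbid")

    report_id: str
    field: str
    message: str

    def __str__(self) -> str:  # TSV row for the CLI
        return f"{self.report_id}\t{self.field}\t{self.message}"


class CorpusParseError(ValueError):
    """A JSON-lines record could not be parsed; names the 1-based line number."""


class CorpusValidationError(ValueError):
    """A record violates the report schema; names the report_id and field."""

    def __init__(self, report_id: str, detail: str):
        self.report_id = report_id
        super().__init__(f"report {report_id!r}: {detail}")


def validate_report(report: StructuredReport) -> list[Violation]:
    """Check all cross-field invariants; return one Violation per breach.

    Structural constraints (enum membership, field types) are enforced by the
    pydantic models themselves; this validator covers everything that needs
    more than one field: span bounds, surface consistency, id uniqueness,
    relation endpoint resolution, and certainty placement.
    """
    violations: list[Violation] = []
    rid = report.report_id

    def bad(field: str, message: str) -> None:
        violations.append(Violation(report_id=rid, field=field, message=message))

    section_texts: dict[str, str] = {}
    for section in report.sections:
        if section.name in section_texts:
            bad("sections", f"duplicate section {section.name!r}")
        section_texts[section.name] = section.text

    seen_ids: set[str] = set()
    entity_by_id: dict[str, Entity] = {}
    for entity in report.entities:
        if entity.id in seen_ids:
            bad(f"entities[{entity.id}].id", "duplicate entity id")
        seen_ids.add(entity.id)
        entity_by_id[entity.id] = entity

        text = section_texts.get(entity.section)
        if text is None:
            bad(f"entities[{entity.id}].section",
                f"references missing section {entity.section!r}")
        else:
            span = entity.span
            if not (0 <= span.start < span.end <= len(text)):
                bad(f"entities[{entity.id}].span",
                    f"span [{span.start}, {span.end}) out of bounds for "
                    f"section of length {len(text)}")
            elif span.slice(text) != entity.surface:
                bad(f"entities[{entity.id}].surface",
                    f"surface {entity.surface!r} != section slice "
                    f"{span.slice(text)!r}")
        if entity.certainty is not None and entity.kind not in FINDING_KINDS:
            bad(f"entities[{entity.id}].certainty",
                f"certainty not allowed on kind {entity.kind!r}")

    for i, relation in enumerate(report.relations):
        head = entity_by_id.get(relation.head)
        tail = entity_by_id.get(relation.tail)
        if head is None:
            bad(f"relations[{i}].head", f"unresolved entity id {relation.head!r}")
        if tail is None:
            bad(f"relations[{i}].tail", f"unresolved entity id {relation.tail!r}")
        if tail is not None and tail.kind not in FINDING_KINDS:
            bad(f"relations[{i}].tail",
                f"tail kind {tail.kind!r} is not a finding entity")
        if head is not None:
            if (relation.type == "recommends_follow_up") != (head.kind == "follow_up"):
                bad(f"relations[{i}].type",
                    f"type {relation.type!r} inconsistent with head kind "
                    f"{head.kind!r}")
    return violations


def _report_from_record(record: dict, line_no: int, fmt: str) -> StructuredReport:
    if not isinstance(record, dict):
        raise CorpusParseError(f"line {line_no}: record is not a JSON object")
    rid = str(record.get("report_id", f"<line {line_no}>"))
    if fmt == "raw_text":
        sections = [
            Section(name=name, text=record.get(name, "") or "")
            for name in SECTION_NAMES
        ]
        return StructuredReport(
            report_id=rid,
            sections=sections,
            metadata=record.get("metadata", {}) or {},
        )
    record = {k: v for k, v in record.items() if k != "schema_version"}
    try:
        report = StructuredReport(**record)
    except ValidationError as exc:
        first = exc.errors()[0]
        field = ".".join(str(p) for p in first["loc"])
        raise CorpusValidationError(rid, f"field {field}: {first['msg']}") from exc
    violations = validate_report(report)
    if violations:
        first_v = violations[0]
        raise CorpusValidationError(rid, f"field {first_v.field}: {first_v.message}")
    return report


def read_reports(
    path: str | Path, format: Literal["raw_text", "structured"] = "structured"
) -> list[StructuredReport]:
    """Read a JSON-lines corpus; one report per line, order preserved.

    ``raw_text`` lines look like ``{"report_id": ..., "findings": ...,
    "impression": ...}`` and yield reports with empty entity/relation lists.
    ``structured`` lines are full serialized :class:`StructuredReport` objects
    and are validated on read.
    """
    path = Path(path)
    reports: list[StructuredReport] = []
    with path.open(encoding="utf-8") as handle:
        for line_no, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            try:
                record = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusParseError(f"line {line_no}: malformed JSON ({exc.msg})")
            reports.append(_report_from_record(record, line_no, format))
    return reports


def write_reports(reports: Iterable[StructuredReport], path: str | Path) -> None:
    """Write reports as UTF-8 JSON-lines (NFC-normalized, non-ASCII preserved)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        for report in reports:
            record = {"schema_version": SCHEMA_VERSION, **report.model_dump()}
            line = json.dumps(record, ensure_ascii=False, separators=(",", ":"))
            handle.write(unicodedata.normalize("NFC", line) + "\n")


def raw_report(
    report_id: str,
    findings: str = "",
    impression: str = "",
    metadata: Optional[dict] = None,
) -> StructuredReport:
    """Convenience constructor for an unstructured (entity-free) report."""
    return StructuredReport(
        report_id=report_id,
        sections=[
            Section(name="findings", text=findings),
            Section(name="impression", text=impression),
        ],
        metadata=metadata or {},
    )


def write_raw_reports(reports: Sequence[StructuredReport], path: str | Path) -> None:
    """Write the raw-text (sections-only) JSON-lines form."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        for report in reports:
            record = {
                "report_id": report.report_id,
                **{s.name: s.text for s in report.sections},
                "metadata": report.metadata,
            }
            line = json.dumps(record, ensure_ascii=False, separators=(",", ":"))
            handle.write(unicodedata.normalize("NFC", line) + "\n")
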