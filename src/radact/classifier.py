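"""Four-pattern classification of cancer-suspicious findings.

Each observation / clinical-finding entity is coded against the dictionary and
then pushed through a fixed sequence of rules:

1.  Findings whose certainty is "denial" (explicitly negated) are excluded.
2.  Findings without a dictionary concept, or whose concept has no malignancy
    code, are "not applicable".
3.  **P1** — malignancy code "malignant" (explicit suspicion of malignancy).
4.  **P2** — malignancy code "indeterminate" (malignancy cannot be ruled out).
5.  **P3** — malignancy code "possible"/"benign" with a related follow-up
    recommendation.
6.  **P4** — malignancy code "possible"/"benign" with a related change modifier
    whose status is "new" or "increasing" (growing or newly appeared lesion).
7.  Anything else is "not applicable".

Findings coded to a non-neoplastic ICD-10 disease (outside C00–D48, e.g.
pneumonia) are excluded from P3/P4 even when those criteria are met; P1/P2
malignancy codes are inherently neoplastic, so the screen applies only there.

P1 maps to the "high actionable" label, P2–P4 to "low actionable", and
"not applicable" to "no actionable". Labels aggregate per anatomical location
(maximum under high > low > no) and then to the whole report (high if any
location is high, else low if any is low, else no).

The precedence is sequential: a malignant finding that is also growing is P1,
not P4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from pydantic import BaseModel, ConfigDict

from .lexicon import (
    DEFAULT_LOCATION_VOCABULARY,
    FindingConcept,
    Lexicon,
    is_neoplastic,
)
from .report_model import Entity, StructuredReport

Pattern = str  # "P1" | "P2" | "P3" | "P4" | "not_applicable"
ActionableLabel = str  # "high" | "low" | "no"

PATTERNS: tuple[str, ...] = ("P1", "P2", "P3", "P4", "not_applicable")
ACTIONABLE_LABELS: tuple[str, ...] = ("high", "low", "no")

#: pattern -> actionable level (a bijection up to the P2–P4 grouping).
PATTERN_TO_ACTIONABLE: dict[str, str] = {
    "P1": "high",
    "P2": "low",
    "P3": "low",
    "P4": "low",
    "not_applicable": "no",
}

_LABEL_RANK = {"no": 0, "low": 1, "high": 2}


def max_label(a: ActionableLabel, b: ActionableLabel) -> ActionableLabel:
    return a if _LABEL_RANK[a] >= _LABEL_RANK[b] else b


@dataclass
class CodedEntity:
    """A finding entity with its dictionary codes and related modifiers."""

    entity: Entity
    finding_concept: Optional[FindingConcept]
    location_codes: list[str] = field(default_factory=lambda: ["other"])
    change_statuses: list[str] = field(default_factory=list)
    has_follow_up: bool = False


class PatternAssignment(BaseModel):
    model_config = ConfigDict(extra="forbid")

    entity_id: str
    pattern: Pattern
    actionable: ActionableLabel
    locations: list[str]
    triggering_rule: str


class ActionableResult(BaseModel):
    model_config = ConfigDict(extra="forbid")

    report_id: str
    location_labels: dict[str, ActionableLabel]
    report_label: ActionableLabel
    assignments: list[PatternAssignment]


def resolve_locations(
    modifier_organ_codes: Sequence[str],
    finding_concept: Optional[FindingConcept],
    vocabulary: Sequence[str] = DEFAULT_LOCATION_VOCABULARY,
) -> list[str]:
    """Union of modifier organ codes and the finding's intrinsic organ.

    Organ codes outside the configured vocabulary fall back to the reserved
    code "other", as does a finding with no resolvable location at all.
    """
    organs: list[str] = []
    candidates = list(modifier_organ_codes)
    if finding_concept is not None and finding_concept.organ_code is not None:
        candidates.append(finding_concept.organ_code)
    for organ in candidates:
        mapped = organ if organ in vocabulary else "other"
        if mapped not in organs:
            organs.append(mapped)
    return organs or ["other"]


def code_entities(
    report: StructuredReport,
    lexicon: Lexicon,
    vocabulary: Sequence[str] | None = None,
) -> list[CodedEntity]:
    """Dictionary-code every finding entity and collect its related modifiers."""
    vocabulary = tuple(vocabulary or lexicon.location_vocabulary)
    entity_by_id = {e.id: e for e in report.entities}
    coded: list[CodedEntity] = []
    for entity in report.finding_entities():
        concept = lexicon.lookup(entity.surface, "finding")
        modifier_organs: list[str] = []
        statuses: list[str] = []
        has_follow_up = False
        for relation in report.relations:
            if relation.tail != entity.id:
                continue
            head = entity_by_id[relation.head]
            if relation.type == "recommends_follow_up":
                has_follow_up = True
            elif head.kind == "anatomical_location_modifier":
                location = lexicon.lookup(head.surface, "anatomical_location")
                modifier_organs.append(location.organ_code if location else "other")
            elif head.kind == "change_modifier":
                change = lexicon.lookup(head.surface, "change")
                if change is not None:
                    statuses.append(change.status_code)
        coded.append(
            CodedEntity(
                entity=entity,
                finding_concept=concept,
                location_codes=resolve_locations(modifier_organs, concept, vocabulary),
                change_statuses=statuses,
                has_follow_up=has_follow_up,
            )
        )
    return coded


def _assignment(coded: CodedEntity, pattern: str, rule: str) -> PatternAssignment:
    return PatternAssignment(
        entity_id=coded.entity.id,
        pattern=pattern,
        actionable=PATTERN_TO_ACTIONABLE[pattern],
        locations=list(coded.location_codes),
        triggering_rule=rule,
    )


def classify_entity(coded: CodedEntity) -> PatternAssignment:
    """Apply the rule sequence of the module docstring to one coded entity."""
    certainty = coded.entity.certainty or "definite"
    if certainty == "denial":
        return _assignment(coded, "not_applicable", "negated finding (certainty=denial)")

    concept = coded.finding_concept
    if concept is None:
        return _assignment(coded, "not_applicable", "no dictionary concept")
    if concept.malignancy_code is None:
        return _assignment(coded, "not_applicable", "concept has no malignancy code")

    malignancy = concept.malignancy_code
    if malignancy == "malignant":
        return _assignment(coded, "P1", "malignancy code 'malignant'")
    if malignancy == "indeterminate":
        return _assignment(coded, "P2", "malignancy code 'indeterminate'")

    # malignancy in {possible, benign} from here on
    if coded.has_follow_up:
        if is_neoplastic(concept):
            return _assignment(
                coded, "P3", f"malignancy '{malignancy}' + follow-up recommended"
            )
        return _assignment(
            coded,
            "not_applicable",
            f"non-neoplastic disease code {concept.icd10_code} (P3 criteria met)",
        )
    growing = [s for s in coded.change_statuses if s in ("new", "increasing")]
    if growing:
        if is_neoplastic(concept):
            return _assignment(
                coded, "P4", f"malignancy '{malignancy}' + change status '{growing[0]}'"
            )
        return _assignment(
            coded,
            "not_applicable",
            f"non-neoplastic disease code {concept.icd10_code} (P4 criteria met)",
        )
    return _assignment(coded, "not_applicable", "no pattern rule fired")


def label_locations(
    assignments: Sequence[PatternAssignment],
    vocabulary: Sequence[str] = DEFAULT_LOCATION_VOCABULARY,
) -> dict[str, ActionableLabel]:
    """Per-location maximum of the assignment labels (high > low > no)."""
    labels: dict[str, str] = {organ: "no" for organ in vocabulary}
    for assignment in assignments:
        for organ in assignment.locations:
            organ = organ if organ in labels else "other"
            labels[organ] = max_label(labels[organ], assignment.actionable)
    return labels


def aggregate_report(location_labels: dict[str, ActionableLabel]) -> ActionableLabel:
    """High if any location is high; else low if any is low; else no."""
    values = list(location_labels.values())
    if "high" in values:
        return "high"
    if "low" in values:
        return "low"
    return "no"


def classify_report(
    report: StructuredReport,
    lexicon: Lexicon,
    vocabulary: Sequence[str] | None = None,
) -> ActionableResult:
    """Code, classify and aggregate one structured report."""
    vocabulary = tuple(vocabulary or lexicon.location_vocabulary)
    coded = code_entities(report, lexicon, vocabulary)
    assignments = [classify_entity(c) for c in coded]
    location_labels = label_locations(assignments, vocabulary)
    return ActionableResult(
        report_id=report.report_id,
        location_labels=location_labels,
        report_label=aggregate_report(location_labels),
        assignments=assignments,
    )
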