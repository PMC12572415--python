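"""Deterministic reference structurer: raw report text -> structured report.

Turns the two free-text sections of a report into entities, relations and
certainty labels using only the lexicon and a cue table, so that raw-text
corpora can flow through the downstream classifier. Reports structured by an
external system (e.g. trained extraction models) bypass this module entirely —
the classifier consumes any valid :class:`~radact.report_model.StructuredReport`.

The rules are intentionally simple and fully reproducible:

* entity tagging is greedy longest-match, left-to-right, over the
  NFKC-normalized text (ties broken leftmost-first);
* modifiers relate to every finding entity in the same sentence;
* follow-up recommendations attach to diagnosis-level (clinical_finding)
  entities when any are in scope, otherwise to observation entities — first in
  their own sentence, then in the immediately preceding sentence, mirroring the
  common style of stating the recommendation right after the suspected
  diagnosis;
* certainty is the most guarded cue found in the sentence
  (denial > unlikely > may_represent > likely > definite), defaulting to
  "definite" when no cue is present.
"""

from __future__ import annotations

import unicodedata
from importlib import resources
from typing import Optional, Sequence

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .lexicon import Lexicon, normalize
from .report_model import (
    CertaintyLabel,
    Entity,
    Relation,
    Span,
    StructuredReport,
    SectionName,
    validate_report,
)

#: Lower index = more guarded; the winning cue is the minimum over a sentence.
_CERTAINTY_PRIORITY = ("denial", "unlikely", "may_represent", "likely", "definite")


class CertaintyCue(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    pattern: str
    label: CertaintyLabel
    scope: str = "same_sentence"


class StructurerConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    certainty_cues: list[CertaintyCue] = Field(min_length=1)
    follow_up_surfaces: list[str] = Field(default_factory=list)
    sentence_delimiters: str = Field(default="。．.!?！？\n", min_length=1)


def default_config() -> StructurerConfig:
    """Load the packaged cue table and follow-up surfaces."""
    text = (resources.files("radact") / "data" / "cues.yaml").read_text("utf-8")
    return StructurerConfig(**yaml.safe_load(text))


def load_config(path) -> StructurerConfig:
    with open(path, encoding="utf-8") as handle:
        return StructurerConfig(**yaml.safe_load(handle))


def split_sentences(section_text: str, config: StructurerConfig) -> list[Span]:
    """Partition text into sentence spans; delimiters stay with their sentence."""
    spans: list[Span] = []
    start = 0
    for i, char in enumerate(section_text):
        if char in config.sentence_delimiters:
            spans.append(Span(start=start, end=i + 1))
            start = i + 1
    if start < len(section_text):
        spans.append(Span(start=start, end=len(section_text)))
    return spans


def _char_normalize(char: str) -> str:
    folded = unicodedata.normalize("NFKC", char).lower()
    return unicodedata.normalize("NFKC", folded)


def _normalized_view(text: str) -> tuple[str, list[int]]:
    """Per-code-point normalized copy plus a map norm index -> original index."""
    pieces: list[str] = []
    norm_to_orig: list[int] = []
    for i, char in enumerate(text):
        piece = _char_normalize(char)
        pieces.append(piece)
        norm_to_orig.extend([i] * len(piece))
    return "".join(pieces), norm_to_orig


def tag_entities(
    section_text: str,
    lexicon: Lexicon,
    config: StructurerConfig,
    section: SectionName = "findings",
    id_prefix: str = "e",
) -> list[Entity]:
    """Greedy longest-match dictionary tagging over the normalized text.

    Candidates are all lexicon surfaces plus the configured follow-up
    surfaces. Matches never overlap; on equal length the leftmost (and, at the
    same position, the lexicon) candidate wins. Matches must align with
    original code-point boundaries so spans/surfaces always slice the raw text.
    """
    candidates: list[tuple[str, str, Optional[str]]] = []
    for entry in lexicon.surfaces:
        kind = {
            "finding": entry.finding_kind or "observation",
            "anatomical_location": "anatomical_location_modifier",
            "change": "change_modifier",
        }[entry.entity_kind]
        candidates.append((entry.normalized, kind, entry.concept_id))
    for surface in config.follow_up_surfaces:
        candidates.append((normalize(surface), "follow_up", None))
    candidates.sort(key=lambda c: -len(c[0]))

    norm_text, norm_to_orig = _normalized_view(section_text)
    n = len(norm_text)

    def orig_boundary(j: int) -> bool:  # j is a norm index or n
        return j == 0 or j == n or norm_to_orig[j] != norm_to_orig[j - 1]

    entities: list[Entity] = []
    i = 0
    while i < n:
        if not orig_boundary(i):
            i += 1
            continue
        hit = None
        for pattern, kind, _concept in candidates:
            j = i + len(pattern)
            if j <= n and norm_text.startswith(pattern, i) and orig_boundary(j):
                hit = (j, kind)
                break
        if hit is None:
            i += 1
            continue
        j, kind = hit
        start = norm_to_orig[i]
        end = norm_to_orig[j - 1] + 1
        entities.append(
            Entity(
                id=f"{id_prefix}{len(entities)}",
                kind=kind,
                section=section,
                span=Span(start=start, end=end),
                surface=section_text[start:end],
            )
        )
        i = j
    return entities


def _sentence_index(entity: Entity, sentences: Sequence[Span]) -> int:
    for idx, span in enumerate(sentences):
        if span.start <= entity.span.start < span.end:
            return idx
    raise ValueError(f"entity {entity.id} outside all sentence spans")


def _follow_up_targets(finding_group: list[Entity]) -> list[Entity]:
    clinical = [e for e in finding_group if e.kind == "clinical_finding"]
    return clinical if clinical else list(finding_group)


def link_relations(entities: Sequence[Entity], sentences: Sequence[Span]) -> list[Relation]:
    """Sentence-scoped relation linking (with one-sentence lookback for
    orphan follow-up recommendations)."""
    by_sentence: dict[int, list[Entity]] = {}
    for entity in entities:
        by_sentence.setdefault(_sentence_index(entity, sentences), []).append(entity)

    relations: list[Relation] = []
    for idx, group in sorted(by_sentence.items()):
        findings = [e for e in group if e.kind in ("observation", "clinical_finding")]
        for entity in group:
            if entity.kind in (
                "anatomical_location_modifier",
                "change_modifier",
                "other_modifier",
            ):
                for finding in findings:
                    relations.append(
                        Relation(head=entity.id, tail=finding.id, type="modifies")
                    )
            elif entity.kind == "follow_up":
                targets = _follow_up_targets(findings)
                if not targets and idx - 1 in by_sentence:
                    previous = [
                        e
                        for e in by_sentence[idx - 1]
                        if e.kind in ("observation", "clinical_finding")
                    ]
                    targets = _follow_up_targets(previous)
                for finding in targets:
                    relations.append(
                        Relation(
                            head=entity.id,
                            tail=finding.id,
                            type="recommends_follow_up",
                        )
                    )
    return relations


def assign_certainty(
    entities: Sequence[Entity],
    section_text: str,
    sentences: Sequence[Span],
    config: StructurerConfig,
) -> list[Entity]:
    """Fill certainty on finding entities from the cues in their sentence."""
    sentence_labels: list[str] = []
    for span in sentences:
        norm_sentence = normalize(span.slice(section_text))
        label = "definite"
        best = len(_CERTAINTY_PRIORITY)
        for cue in config.certainty_cues:
            if normalize(cue.pattern) in norm_sentence:
                rank = _CERTAINTY_PRIORITY.index(cue.label)
                if rank < best:
                    best = rank
                    label = cue.label
        sentence_labels.append(label)

    result: list[Entity] = []
    for entity in entities:
        if entity.kind in ("observation", "clinical_finding"):
            label = sentence_labels[_sentence_index(entity, sentences)]
            result.append(entity.model_copy(update={"certainty": label}))
        else:
            result.append(entity)
    return result


def structure_report(
    raw: StructuredReport,
    lexicon: Lexicon,
    config: Optional[StructurerConfig] = None,
) -> StructuredReport:
    """Run tagging, certainty assignment and relation linking per section."""
    config = config or default_config()
    entities: list[Entity] = []
    relations: list[Relation] = []
    for section in raw.sections:
        sentences = split_sentences(section.text, config)
        tagged = tag_entities(
            section.text,
            lexicon,
            config,
            section=section.name,
            id_prefix=f"{section.name}-e",
        )
        tagged = assign_certainty(tagged, section.text, sentences, config)
        relations.extend(link_relations(tagged, sentences))
        entities.extend(tagged)
    structured = StructuredReport(
        report_id=raw.report_id,
        sections=list(raw.sections),
        entities=entities,
        relations=relations,
        metadata=dict(raw.metadata),
    )
    violations = validate_report(structured)
    if violations:  # structurer output must always be schema-valid
        raise RuntimeError(f"structurer produced invalid report: {violations[0]}")
    return structured
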