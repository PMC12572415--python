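"""Synthetic gold-labeled radiology-report corpora.

Generates short Japanese-style CT report fixtures in the four cancer-suspicious
writing patterns (explicit malignancy; indeterminate tumor; benign/possible
finding with a follow-up recommendation; growing or new lesion) plus
non-actionable reports, in both raw-text and pre-structured form, with gold
labels per anatomical location.

Gold labels and the structured form are assigned **by template construction**,
never by running the structurer or classifier, so closed-loop tests are a
genuine check of the pipeline rather than a tautology.

Noise channels reproduce the documented error-inducing writing styles:

* ``hedged_malignancy`` — a benign diagnosis followed by a "malignancy must be
  excluded" remark; readers label it low actionable, the rules fire P1 (high).
* ``non_neoplastic_swap`` — a follow-up recommendation for a lesion attributed
  to a non-neoplastic disease; readers keep it low actionable, the rules
  exclude it (no).
* ``unknown_surface`` — the lesion term is absent from the dictionary; the
  rules cannot code it (no).
* ``impression_only`` — the benign diagnosis appears only in the impression
  while the findings section shows a growing lesion; readers integrate the two
  sections (no), the rules process sections independently (low).

Every channel makes the prediction diverge from gold, so increasing noise
degrades recall in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from typing import Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .classifier import aggregate_report
from .lexicon import DEFAULT_LOCATION_VOCABULARY, Lexicon
from .report_model import (
    Entity,
    Relation,
    Section,
    Span,
    StructuredReport,
    validate_report,
)

#: Japanese surface per generatable organ (must stay within the seed lexicon).
LOCATION_SURFACES: dict[str, str] = {
    "lung": "肺",
    "thyroid": "甲状腺",
    "uterus": "子宮",
    "ovary": "卵巣",
    "liver": "肝臓",
    "pancreas": "膵臓",
    "breast": "乳房",
    "kidney": "腎臓",
}

CLASS_NAMES: tuple[str, ...] = ("high", "low_p2", "low_p3", "low_p4", "no")


class NoiseConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    hedged_malignancy: float = Field(default=0.0, ge=0.0, le=1.0)
    non_neoplastic_swap: float = Field(default=0.0, ge=0.0, le=1.0)
    unknown_surface: float = Field(default=0.0, ge=0.0, le=1.0)
    impression_only: float = Field(default=0.0, ge=0.0, le=1.0)


class GeneratorConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_reports: int = Field(default=100, ge=0)
    #: Probability of each report class; defaults approximate the prevalence
    #: of actionable findings in multi-institutional CT report collections
    #: (roughly 23% high, 9% low split across the three low patterns, 68% no).
    class_mix: dict[str, float] = Field(
        default_factory=lambda: {
            "high": 0.233,
            "low_p2": 0.031,
            "low_p3": 0.030,
            "low_p4": 0.030,
            "no": 0.676,
        }
    )
    locations: tuple[str, ...] = tuple(LOCATION_SURFACES)
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    seed: int = 0
    emit: Literal["raw", "structured", "both"] = "both"

    @model_validator(mode="after")
    def _check(self):
        if set(self.class_mix) != set(CLASS_NAMES):
            raise ValueError(f"class_mix must cover exactly {CLASS_NAMES}")
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mix sums to {total}, expected 1")
        if any(p < 0 for p in self.class_mix.values()):
            raise ValueError("class_mix probabilities must be non-negative")
        for organ in self.locations:
            if organ not in LOCATION_SURFACES:
                raise ValueError(f"no template surface for location {organ!r}")
        return self


@dataclass(frozen=True)
class GoldRecord:
    report_id: str
    report_label: str
    location_labels: dict[str, str]
    patterns: tuple[str, ...]  # intended pattern per actionable sentence

    def as_dict(self) -> dict:
        return {
            "report_id": self.report_id,
            "report_label": self.report_label,
            "location_labels": dict(self.location_labels),
            "patterns": list(self.patterns),
        }


@dataclass(frozen=True)
class _EntitySpec:
    section: str
    surface: str
    kind: str
    certainty: Optional[str] = None
    in_lexicon: bool = True  # skip the coverage check for deliberate unknowns


@dataclass(frozen=True)
class _Template:
    findings: str
    impression: str
    entities: tuple[_EntitySpec, ...]
    relations: tuple[tuple[int, int, str], ...]  # (head idx, tail idx, type)
    gold_locations: dict[str, str]  # sparse; absent organs are "no"
    patterns: tuple[str, ...]
    gloss: str


class GenerationError(ValueError):
    """A template surface is missing from the lexicon."""


def _template_high(organ: str) -> _Template:
    loc = LOCATION_SURFACES[organ]
    return _Template(
        findings=f"{loc}の腫瘤は悪性を疑う。",
        impression="",
        entities=(
            _EntitySpec("findings", loc, "anatomical_location_modifier"),
            _EntitySpec("findings", "腫瘤", "observation", "likely"),
            _EntitySpec("findings", "悪性", "clinical_finding", "likely"),
        ),
        relations=((0, 1, "modifies"), (0, 2, "modifies")),
        gold_locations={organ: "high"},
        patterns=("P1",),
        gloss=f"A mass in the {organ} is suspicious for malignancy.",
    )


def _template_low_p2(organ: str) -> _Template:
    loc = LOCATION_SURFACES[organ]
    return _Template(
        findings=f"{loc}に腫瘍を認める。",
        impression="",
        entities=(
            _EntitySpec("findings", loc, "anatomical_location_modifier"),
            _EntitySpec("findings", "腫瘍", "clinical_finding", "definite"),
        ),
        relations=((0, 1, "modifies"),),
        gold_locations={organ: "low"},
        patterns=("P2",),
        gloss=f"A tumor is seen in the {organ}.",
    )


def _template_low_p3(organ: str) -> _Template:
    loc = LOCATION_SURFACES[organ]
    return _Template(
        findings=f"{loc}に低吸収域を認める。経過観察をお願いします。",
        impression="",
        entities=(
            _EntitySpec("findings", loc, "anatomical_location_modifier"),
            _EntitySpec("findings", "低吸収域", "observation", "definite"),
            _EntitySpec("findings", "経過観察", "follow_up"),
        ),
        relations=((0, 1, "modifies"), (2, 1, "recommends_follow_up")),
        gold_locations={organ: "low"},
        patterns=("P3",),
        gloss=(
            f"A hypoattenuating lesion is seen in the {organ}. "
            "Follow-up is requested."
        ),
    )


def _template_low_p4(organ: str) -> _Template:
    loc = LOCATION_SURFACES[organ]
    return _Template(
        findings=f"{loc}の結節は増大しています。",
        impression="",
        entities=(
            _EntitySpec("findings", loc, "anatomical_location_modifier"),
            _EntitySpec("findings", "結節", "observation", "definite"),
            _EntitySpec("findings", "増大", "change_modifier"),
        ),
        relations=((0, 1, "modifies"), (2, 1, "modifies")),
        gold_locations={organ: "low"},
        patterns=("P4",),
        gloss=f"A nodule in the {organ} has increased in size.",
    )


def _template_no(organ: str, variant: int) -> _Template:
    loc = LOCATION_SURFACES[organ]
    if variant == 0:
        return _Template(
            findings="特記すべき異常を認めません。",
            impression="",
            entities=(),
            relations=(),
            gold_locations={},
            patterns=(),
            gloss="No remarkable abnormality.",
        )
    if variant == 1:
        return _Template(
            findings=f"{loc}に嚢胞を認める。",
            impression="",
            entities=(
                _EntitySpec("findings", loc, "anatomical_location_modifier"),
                _EntitySpec("findings", "嚢胞", "observation", "definite"),
            ),
            relations=((0, 1, "modifies"),),
            gold_locations={},
            patterns=(),
            gloss=f"A cyst is seen in the {organ}.",
        )
    if variant == 2:
        return _Template(
            findings=f"{loc}の結節は不変です。",
            impression="",
            entities=(
                _EntitySpec("findings", loc, "anatomical_location_modifier"),
                _EntitySpec("findings", "結節", "observation", "definite"),
                _EntitySpec("findings", "不変", "change_modifier"),
            ),
            relations=((0, 1, "modifies"), (2, 1, "modifies")),
            gold_locations={},
            patterns=(),
            gloss=f"The nodule in the {organ} is unchanged.",
        )
    return _Template(
        findings="肺癌を認めません。",
        impression="",
        entities=(_EntitySpec("findings", "肺癌", "clinical_finding", "denial"),),
        relations=(),
        gold_locations={},
        patterns=(),
        gloss="No evidence of lung cancer.",
    )


def _template_hedged_malignancy() -> _Template:
    return _Template(
        findings="多発子宮筋腫が疑われます。悪性の除外が必要です。",
        impression="多発子宮筋腫の疑い。",
        entities=(
            _EntitySpec("findings", "子宮筋腫", "clinical_finding", "likely"),
            _EntitySpec("findings", "悪性", "clinical_finding", "definite"),
            _EntitySpec("impression", "子宮筋腫", "clinical_finding", "likely"),
        ),
        relations=(),
        gold_locations={"uterus": "low"},
        patterns=(),
        gloss=(
            "Multiple uterine fibroids are suspected. "
            "Exclusion of malignancy is necessary."
        ),
    )


def _template_non_neoplastic_swap() -> _Template:
    return _Template(
        findings="左肺下葉の多発結節は肺クリプトコッカス症を疑います。追加のフォローください。",
        impression="多発結節",
        entities=(
            _EntitySpec("findings", "左肺下葉", "anatomical_location_modifier"),
            _EntitySpec("findings", "多発結節", "observation", "likely"),
            _EntitySpec("findings", "肺クリプトコッカス症", "clinical_finding", "likely"),
            _EntitySpec("findings", "フォロー", "follow_up"),
            _EntitySpec("impression", "多発結節", "observation", "definite"),
        ),
        relations=(
            (0, 1, "modifies"),
            (0, 2, "modifies"),
            (3, 2, "recommends_follow_up"),
        ),
        gold_locations={"lung": "low"},
        patterns=(),
        gloss=(
            "Multiple nodules in the left lower lobe probably suggest pulmonary "
            "cryptococcosis. Additional follow-up is recommended."
        ),
    )


def _template_unknown_surface(organ: str) -> _Template:
    loc = LOCATION_SURFACES[organ]
    return _Template(
        findings=f"{loc}に腫瘤性病変を認める。",
        impression="",
        entities=(
            _EntitySpec("findings", loc, "anatomical_location_modifier"),
            _EntitySpec("findings", "腫瘤性病変", "observation", "definite",
                        in_lexicon=False),
        ),
        relations=((0, 1, "modifies"),),
        gold_locations={organ: "low"},
        patterns=(),
        gloss=f"A mass-like lesion is seen in the {organ}.",
    )


def _template_impression_only() -> _Template:
    return _Template(
        findings="両肺に見られる多発小結節は増大しています。",
        impression="非結核性抗酸菌症を疑います。",
        entities=(
            _EntitySpec("findings", "両肺", "anatomical_location_modifier"),
            _EntitySpec("findings", "小結節", "observation", "definite"),
            _EntitySpec("findings", "増大", "change_modifier"),
            _EntitySpec("impression", "非結核性抗酸菌症", "clinical_finding", "likely"),
        ),
        relations=((0, 1, "modifies"), (2, 1, "modifies")),
        gold_locations={},
        patterns=(),
        gloss=(
            "Multiple small nodules in both lungs are increasing in size. / "
            "Suspected nontuberculous mycobacterial lung disease."
        ),
    )


def _build_structured(report_id: str, template: _Template, metadata: dict) -> StructuredReport:
    sections = [
        Section(name="findings", text=template.findings),
        Section(name="impression", text=template.impression),
    ]
    texts = {"findings": template.findings, "impression": template.impression}
    cursors = {"findings": 0, "impression": 0}
    entities: list[Entity] = []
    for i, spec in enumerate(template.entities):
        start = texts[spec.section].index(spec.surface, cursors[spec.section])
        end = start + len(spec.surface)
        cursors[spec.section] = end
        entities.append(
            Entity(
                id=f"t{i}",
                kind=spec.kind,
                section=spec.section,
                span=Span(start=start, end=end),
                surface=spec.surface,
                certainty=spec.certainty,
            )
        )
    relations = [
        Relation(head=f"t{h}", tail=f"t{t}", type=rtype)
        for h, t, rtype in template.relations
    ]
    report = StructuredReport(
        report_id=report_id,
        sections=sections,
        entities=entities,
        relations=relations,
        metadata=metadata,
    )
    violations = validate_report(report)
    if violations:
        raise GenerationError(f"template produced invalid report: {violations[0]}")
    return report


def _gold(
    report_id: str,
    template: _Template,
    vocabulary: Sequence[str],
) -> GoldRecord:
    labels = {organ: "no" for organ in vocabulary}
    labels.update(template.gold_locations)
    return GoldRecord(
        report_id=report_id,
        report_label=aggregate_report(labels),
        location_labels=labels,
        patterns=template.patterns,
    )


@dataclass
class GeneratedCorpus:
    raw: list[StructuredReport] = dataclass_field(default_factory=list)
    structured: list[StructuredReport] = dataclass_field(default_factory=list)
    gold: list[GoldRecord] = dataclass_field(default_factory=list)


def _check_coverage(templates: Sequence[_Template], lexicon: Lexicon) -> None:
    kind_map = {
        "observation": "finding",
        "clinical_finding": "finding",
        "anatomical_location_modifier": "anatomical_location",
        "change_modifier": "change",
    }
    for template in templates:
        for spec in template.entities:
            if not spec.in_lexicon or spec.kind not in kind_map:
                continue
            if lexicon.lookup(spec.surface, kind_map[spec.kind]) is None:
                raise GenerationError(
                    f"template surface {spec.surface!r} ({spec.kind}) missing "
                    "from the lexicon"
                )


def generate_corpus(config: GeneratorConfig, lexicon: Lexicon) -> GeneratedCorpus:
    """Sample a reproducible gold-labeled corpus from the template library."""
    rng = np.random.default_rng(config.seed)
    classes = list(CLASS_NAMES)
    probs = np.array([config.class_mix[c] for c in classes], dtype=float)
    vocabulary = lexicon.location_vocabulary

    corpus = GeneratedCorpus()
    templates_used: list[_Template] = []
    for i in range(config.n_reports):
        report_id = f"synth-{config.seed}-{i:05d}"
        cls = classes[int(rng.choice(len(classes), p=probs))]
        organ = config.locations[int(rng.integers(len(config.locations)))]
        noise = config.noise
        if cls == "high":
            template = _template_high(organ)
        elif cls == "low_p2":
            if rng.random() < noise.unknown_surface:
                template = _template_unknown_surface(organ)
            elif rng.random() < noise.hedged_malignancy:
                template = _template_hedged_malignancy()
            else:
                template = _template_low_p2(organ)
        elif cls == "low_p3":
            if rng.random() < noise.non_neoplastic_swap:
                template = _template_non_neoplastic_swap()
            elif rng.random() < noise.hedged_malignancy:
                template = _template_hedged_malignancy()
            else:
                template = _template_low_p3(organ)
        elif cls == "low_p4":
            if rng.random() < noise.hedged_malignancy:
                template = _template_hedged_malignancy()
            else:
                template = _template_low_p4(organ)
        else:  # "no"
            if rng.random() < noise.impression_only:
                template = _template_impression_only()
            else:
                template = _template_no(organ, int(rng.integers(4)))
        templates_used.append(template)

        metadata = {"gloss": template.gloss, "intended_class": cls}
        structured = _build_structured(report_id, template, metadata)
        if config.emit in ("raw", "both"):
            corpus.raw.append(
                StructuredReport(
                    report_id=report_id,
                    sections=list(structured.sections),
                    metadata=dict(metadata),
                )
            )
        if config.emit in ("structured", "both"):
            corpus.structured.append(structured)
        corpus.gold.append(_gold(report_id, template, vocabulary))

    _check_coverage(templates_used, lexicon)
    return corpus


@dataclass(frozen=True)
class WorkedExample:
    """A curated fixture sentence with its gold label and the label the rule
    set is documented to produce (they differ for the error-style examples)."""

    report_id: str
    findings: str
    impression: str
    gold_report_label: str
    gold_locations: dict[str, str]
    expected_prediction: str
    note: str

    def raw_report(self) -> StructuredReport:
        return StructuredReport(
            report_id=self.report_id,
            sections=[
                Section(name="findings", text=self.findings),
                Section(name="impression", text=self.impression),
            ],
            metadata={"note": self.note},
        )


def worked_examples() -> list[WorkedExample]:
    """Nine curated reports: one per writing pattern (P1–P4) plus five
    error-style reports where the documented prediction diverges from gold."""
    return [
        WorkedExample(
            "example-p1", "肺癌を疑う。", "", "high", {"lung": "high"}, "high",
            "P1: explicit suspicion of malignancy (suspected lung cancer)",
        ),
        WorkedExample(
            "example-p2", "卵巣腫瘍を疑う。", "", "low", {"ovary": "low"}, "low",
            "P2: indeterminate tumor (suspected ovarian tumor)",
        ),
        WorkedExample(
            "example-p3",
            "甲状腺に低吸収域を認める。追加検査をご検討ください。",
            "", "low", {"thyroid": "low"}, "low",
            "P3: possible finding with follow-up recommendation",
        ),
        WorkedExample(
            "example-p4", "肺結節が増大しています。", "", "low", {"lung": "low"}, "low",
            "P4: possible finding increasing in size",
        ),
        WorkedExample(
            "error-1",
            "左肺下葉の多発結節は肺クリプトコッカス症を疑います。追加のフォローください。",
            "多発結節", "low", {"lung": "low"}, "no",
            "followed-up lesion attributed to a non-neoplastic disease: the "
            "non-neoplastic screen excludes it (false negative)",
        ),
        WorkedExample(
            "error-2",
            "両肺に見られる多発小結節は増大しています。",
            "非結核性抗酸菌症を疑います。", "no", {}, "low",
            "benign diagnosis stated only in the impression: sections are "
            "processed independently (false positive)",
        ),
        WorkedExample(
            "error-3",
            "両肺のすりガラス結節は悪化しています。",
            "間質性肺炎を疑います。", "no", {}, "low",
            "worsening nodules explained by interstitial pneumonia in the "
            "impression only (false positive)",
        ),
        WorkedExample(
            "error-4",
            "左肺下葉の結節は炎症後変化を疑います。しかし、転移の鑑別は困難です。",
            "左肺結節:炎症後変化を疑います。", "low", {"lung": "low"}, "high",
            "hedged mention of metastasis triggers P1 although the overall "
            "context is benign (false positive at high)",
        ),
        WorkedExample(
            "error-5",
            "多発子宮筋腫が疑われます。悪性の除外が必要です。",
            "多発子宮筋腫の疑い。", "low", {"uterus": "low"}, "high",
            "'exclusion of malignancy' phrasing triggers P1 although readers "
            "label it low actionable",
        ),
    ]
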