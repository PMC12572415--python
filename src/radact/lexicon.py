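"""Concept dictionary: surface table plus finding / location / change concepts.

The dictionary has two layers. The *surface* table maps words and phrases as
they appear in reports to concept ids; the three *concept* tables standardize
them. Finding concepts carry an optional ICD-10 disease code and a malignancy
code (possible | benign | indeterminate | malignant) expressing the term's
intrinsic likelihood of malignancy; anatomical-location concepts carry an
organ code and body-part code; change concepts carry a lesion-course status
code (increasing | decreasing | new | unchanged).

Lookup is exact string matching on NFKC-normalized, lower-cased surfaces —
no fuzzy matching, one concept per (surface, kind).
"""

from __future__ import annotations

import csv
import json
import re
import unicodedata
from importlib import resources
from pathlib import Path
from typing import Literal, Optional, Union

from pydantic import BaseModel, ConfigDict

SurfaceKind = Literal["finding", "anatomical_location", "change"]

MalignancyCode = Literal["possible", "benign", "indeterminate", "malignant"]
MALIGNANCY_CODES: tuple[str, ...] = ("possible", "benign", "indeterminate", "malignant")

StatusCode = Literal["increasing", "decreasing", "new", "unchanged"]
STATUS_CODES: tuple[str, ...] = ("increasing", "decreasing", "new", "unchanged")

#: Default anatomical-location vocabulary ("other" is the reserved fallback
#: for findings whose location cannot be resolved).
DEFAULT_LOCATION_VOCABULARY: tuple[str, ...] = (
    "lung",
    "breast",
    "pancreas",
    "liver",
    "kidney",
    "thyroid",
    "uterus",
    "ovary",
    "stomach",
    "lymph_node",
    "other",
)

_ICD10_RE = re.compile(r"^[A-Z]\d{2}(\.\d{1,2})?$")


class LexiconError(ValueError):
    """Raised when a lexicon file violates the dictionary schema."""


def normalize(text: str) -> str:
    """NFKC-normalize, lower-case and strip a surface string.

    Applied identically to dictionary surfaces and report text before
    matching, so full-width/half-width variants and letter case never defeat
    an exact match. A second NFKC pass makes the function idempotent even for
    characters whose lower-case form re-composes.
    """
    folded = unicodedata.normalize("NFKC", text).lower()
    return unicodedata.normalize("NFKC", folded).strip()


class SurfaceEntry(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    surface: str
    entity_kind: SurfaceKind
    concept_id: str
    #: For finding surfaces only: whether the reference structurer should tag
    #: the surface as an observation term or a diagnosis-level clinical finding.
    finding_kind: Optional[Literal["observation", "clinical_finding"]] = None

    @property
    def normalized(self) -> str:
        return normalize(self.surface)


class FindingConcept(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    concept_id: str
    preferred_label: str
    icd10_code: Optional[str] = None
    malignancy_code: Optional[MalignancyCode] = None
    #: Intrinsic organ of the term itself (e.g. lung cancer -> lung), used when
    #: no anatomical-location modifier is present.
    organ_code: Optional[str] = None


class LocationConcept(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    concept_id: str
    preferred_label: str
    organ_code: str
    body_part_code: str


class ChangeConcept(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    concept_id: str
    preferred_label: str
    status_code: StatusCode


ConceptRecord = Union[FindingConcept, LocationConcept, ChangeConcept]


class Lexicon:
    """Validated surface + concept tables with exact normalized lookup."""

    def __init__(
        self,
        surfaces: list[SurfaceEntry],
        finding_concepts: dict[str, FindingConcept],
        location_concepts: dict[str, LocationConcept],
        change_concepts: dict[str, ChangeConcept],
        location_vocabulary: tuple[str, ...] = DEFAULT_LOCATION_VOCABULARY,
    ):
        self.finding_concepts = dict(finding_concepts)
        self.location_concepts = dict(location_concepts)
        self.change_concepts = dict(change_concepts)
        self.location_vocabulary = tuple(location_vocabulary)
        if "other" not in self.location_vocabulary:
            raise LexiconError("location vocabulary must include the reserved code 'other'")

        self.surfaces: list[SurfaceEntry] = []
        self._index: dict[tuple[str, str], SurfaceEntry] = {}
        tables: dict[str, dict] = {
            "finding": self.finding_concepts,
            "anatomical_location": self.location_concepts,
            "change": self.change_concepts,
        }
        for entry in surfaces:
            key = (entry.normalized, entry.entity_kind)
            if not key[0]:
                raise LexiconError(f"surface {entry.surface!r} empty after normalization")
            if key in self._index:
                raise LexiconError(
                    f"duplicate surface {entry.surface!r} (normalized "
                    f"{key[0]!r}) for kind {entry.entity_kind!r}"
                )
            if entry.concept_id not in tables[entry.entity_kind]:
                raise LexiconError(
                    f"surface {entry.surface!r}: dangling concept_id "
                    f"{entry.concept_id!r} not in the {entry.entity_kind} table"
                )
            self._index[key] = entry
            self.surfaces.append(entry)

        for concept in self.finding_concepts.values():
            if concept.icd10_code is not None and not _ICD10_RE.match(concept.icd10_code):
                raise LexiconError(
                    f"concept {concept.concept_id}: malformed ICD-10 code "
                    f"{concept.icd10_code!r}"
                )
        for concept in self.location_concepts.values():
            if concept.organ_code not in self.location_vocabulary:
                raise LexiconError(
                    f"concept {concept.concept_id}: organ code "
                    f"{concept.organ_code!r} not in the location vocabulary"
                )

    def lookup(self, surface: str, kind: SurfaceKind) -> Optional[ConceptRecord]:
        """Exact match on the normalized surface; None for unknown surfaces."""
        entry = self._index.get((normalize(surface), kind))
        if entry is None:
            return None
        table = {
            "finding": self.finding_concepts,
            "anatomical_location": self.location_concepts,
            "change": self.change_concepts,
        }[kind]
        return table[entry.concept_id]

    def lookup_entry(self, surface: str, kind: SurfaceKind) -> Optional[SurfaceEntry]:
        return self._index.get((normalize(surface), kind))

    def __contains__(self, key: tuple[str, str]) -> bool:
        surface, kind = key
        return (normalize(surface), kind) in self._index


def is_neoplastic(concept: FindingConcept) -> bool:
    """True unless the concept's ICD-10 code falls outside the neoplasm chapter.

    The neoplasm chapter spans C00–D48 inclusive, compared by code prefix.
    A missing disease code does NOT trigger exclusion: only terms positively
    coded as non-neoplastic disease (e.g. pneumonia, J18) are screened out of
    the follow-up / growth patterns.
    """
    code = concept.icd10_code
    if code is None:
        return True
    if not _ICD10_RE.match(code):
        raise LexiconError(f"malformed ICD-10 code {code!r}")
    letter, number = code[0], int(code[1:3])
    if letter == "C":
        return True
    if letter == "D":
        return number <= 48
    return False


def _read_table(path: Path) -> list[dict]:
    if path.suffix == ".json":
        rows = json.loads(path.read_text(encoding="utf-8"))
        if not isinstance(rows, list):
            raise LexiconError(f"{path.name}: expected a JSON array of rows")
        return rows
    with path.open(encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        return [
            {k: (v if v != "" else None) for k, v in row.items()}
            for row in reader
        ]


def _find_table(directory: Path, stem: str) -> Path:
    for suffix in (".tsv", ".json"):
        candidate = directory / f"{stem}{suffix}"
        if candidate.exists():
            return candidate
    raise LexiconError(f"missing lexicon table {stem}.tsv/.json in {directory}")


def load_lexicon(
    path: str | Path,
    location_vocabulary: tuple[str, ...] = DEFAULT_LOCATION_VOCABULARY,
) -> Lexicon:
    """Load a lexicon directory holding surfaces + three concept tables.

    Expected files (TSV with header row, or equivalent JSON arrays):
    ``surfaces``, ``finding_concepts``, ``location_concepts``,
    ``change_concepts``.
    """
    directory = Path(path)
    if not directory.is_dir():
        raise LexiconError(f"lexicon path {directory} is not a directory")

    def build(stem: str, model):
        records = []
        for i, row in enumerate(_read_table(_find_table(directory, stem)), start=2):
            try:
                records.append(model(**row))
            except Exception as exc:
                raise LexiconError(f"{stem} row {i}: {exc}") from exc
        return records

    surfaces = build("surfaces", SurfaceEntry)
    findings = {c.concept_id: c for c in build("finding_concepts", FindingConcept)}
    locations = {c.concept_id: c for c in build("location_concepts", LocationConcept)}
    changes = {c.concept_id: c for c in build("change_concepts", ChangeConcept)}
    return Lexicon(surfaces, findings, locations, changes, location_vocabulary)


def seed_lexicon_path() -> Path:
    """Directory of the seed lexicon shipped with the package."""
    return Path(resources.files("radact") / "data")


def load_seed_lexicon() -> Lexicon:
    """Load the packaged seed lexicon covering the built-in fixtures/templates."""
    return load_lexicon(seed_lexicon_path())
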