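"""Pattern classification, location resolution and label aggregation."""

import itertools

import numpy as np
import pytest

from radact.classifier import (
    ACTIONABLE_LABELS,
    PATTERN_TO_ACTIONABLE,
    PATTERNS,
    CodedEntity,
    aggregate_report,
    classify_entity,
    classify_report,
    code_entities,
    label_locations,
    resolve_locations,
)
from radact.lexicon import DEFAULT_LOCATION_VOCABULARY, FindingConcept
from radact.report_model import Entity, Span, raw_report
from radact.structurer import structure_report

# ---------------------------------------------------------------------------
# grid fixtures


def make_coded(
    certainty="definite",
    malignancy="possible",
    icd10=None,
    has_follow_up=False,
    statuses=(),
    concept_present=True,
    locations=("lung",),
) -> CodedEntity:
    entity = Entity(
        id="e0",
        kind="clinical_finding",
        section="findings",
        span=Span(start=0, end=1),
        surface="x",
        certainty=certainty,
    )
    concept = None
    if concept_present:
        concept = FindingConcept(
            concept_id="X",
            preferred_label="x",
            icd10_code=icd10,
            malignancy_code=malignancy,
        )
    return CodedEntity(
        entity=entity,
        finding_concept=concept,
        location_codes=list(locations),
        change_statuses=list(statuses),
        has_follow_up=has_follow_up,
    )


def oracle_pattern(certainty, malignancy, neoplastic, has_follow_up, statuses):
    """Hand-written truth table, kept declarative and independent of the
    implementation: first matching row wins."""
    growing = any(s in ("new", "increasing") for s in statuses)
    rows = [
        (certainty == "denial", "not_applicable"),
        (malignancy is None, "not_applicable"),
        (malignancy == "malignant", "P1"),
        (malignancy == "indeterminate", "P2"),
        (has_follow_up and neoplastic, "P3"),
        (has_follow_up and not neoplastic, "not_applicable"),
        (growing and neoplastic, "P4"),
        (growing and not neoplastic, "not_applicable"),
        (True, "not_applicable"),
    ]
    for condition, pattern in rows:
        if condition:
            return pattern
    raise AssertionError("unreachable")


GRID = list(
    itertools.product(
        ["definite", "likely", "may_represent", "unlikely", "denial"],
        # (concept_present, malignancy, icd10/neoplastic): absent concept,
        # concept without malignancy code, and each malignancy with a
        # neoplastic, absent, and non-neoplastic disease code
        [(False, None, None)]
        + [(True, None, None)]
        + [
            (True, m, icd)
            for m in ("possible", "benign", "indeterminate", "malignant")
            for icd in (None, "C34", "J18")
        ],
        [False, True],
        [(), ("new",), ("increasing",), ("decreasing",), ("unchanged",),
         ("unchanged", "increasing")],
    )
)


class TestClassifyEntityGrid:
    def test_matches_truth_table_oracle_exhaustively(self):
        assert len(GRID) >= 400
        for certainty, (present, malignancy, icd10), follow, statuses in GRID:
            coded = make_coded(
                certainty=certainty,
                malignancy=malignancy,
                icd10=icd10,
                has_follow_up=follow,
                statuses=statuses,
                concept_present=present,
            )
            neoplastic = icd10 in (None, "C34")
            expected = oracle_pattern(
                certainty, malignancy if present else None, neoplastic, follow, statuses
            )
            got = classify_entity(coded)
            assert got.pattern == expected, (
                f"certainty={certainty} present={present} malignancy={malignancy} "
                f"icd10={icd10} follow={follow} statuses={statuses}: "
                f"{got.pattern} != {expected}"
            )
            assert got.actionable == PATTERN_TO_ACTIONABLE[expected]

    def test_denial_never_yields_a_pattern(self):
        for _, concept_case, follow, statuses in GRID:
            present, malignancy, icd10 = concept_case
            coded = make_coded(
                certainty="denial",
                malignancy=malignancy,
                icd10=icd10,
                has_follow_up=follow,
                statuses=statuses,
                concept_present=present,
            )
            assert classify_entity(coded).pattern == "not_applicable"

    def test_pattern_actionable_mapping_is_total(self):
        assert set(PATTERN_TO_ACTIONABLE) == set(PATTERNS)
        assert set(PATTERN_TO_ACTIONABLE.values()) == set(ACTIONABLE_LABELS)


class TestClassifyEntityExamples:
    @pytest.mark.parametrize(
        "kwargs, pattern",
        [
            # suspected lung cancer: explicit malignancy
            (dict(malignancy="malignant", icd10="C34", certainty="likely"), "P1"),
            # suspected ovarian tumor: indeterminate
            (dict(malignancy="indeterminate", certainty="likely"), "P2"),
            # hypoattenuating lesion + follow-up recommendation
            (dict(malignancy="possible", has_follow_up=True), "P3"),
            # growing lung nodule
            (dict(malignancy="possible", statuses=("increasing",)), "P4"),
            # negated malignancy
            (dict(malignancy="malignant", certainty="denial"), "not_applicable"),
            # followed-up cryptococcosis: non-neoplastic screen
            (
                dict(malignancy="possible", icd10="B45", has_follow_up=True),
                "not_applicable",
            ),
            # stable nodule, nothing recommended
            (dict(malignancy="possible", statuses=("unchanged",)), "not_applicable"),
            # malignant AND growing: precedence picks P1
            (dict(malignancy="malignant", statuses=("increasing",)), "P1"),
        ],
    )
    def test_rule_examples(self, kwargs, pattern):
        assert classify_entity(make_coded(**kwargs)).pattern == pattern


class TestResolveLocations:
    def test_modifier_organ_used(self):
        assert resolve_locations(["lung"], None) == ["lung"]

    def test_intrinsic_organ_from_concept(self):
        concept = FindingConcept(
            concept_id="X", preferred_label="lung cancer", organ_code="lung"
        )
        assert resolve_locations([], concept) == ["lung"]

    def test_unknown_organ_falls_back_to_other(self):
        assert resolve_locations(["spleen-hilum"], None) == ["other"]
        assert resolve_locations([], None) == ["other"]

    def test_union_of_multiple_organs(self):
        assert resolve_locations(["lung", "liver", "lung"], None) == ["lung", "liver"]


class TestLabelLocations:
    def test_max_per_location(self):
        assignments = [
            classify_entity(make_coded(malignancy="malignant", locations=("lung",))),
            classify_entity(
                make_coded(malignancy="possible", has_follow_up=True,
                           locations=("thyroid",))
            ),
        ]
        labels = label_locations(assignments)
        assert labels["lung"] == "high"
        assert labels["thyroid"] == "low"
        assert all(
            labels[o] == "no"
            for o in DEFAULT_LOCATION_VOCABULARY
            if o not in ("lung", "thyroid")
        )

    def test_empty_assignments_all_no(self):
        labels = label_locations([])
        assert set(labels.values()) == {"no"}

    def test_random_sets_match_max_oracle(self):
        rng = np.random.default_rng(11)
        organs = ("lung", "liver", "thyroid", "other")
        cases = [
            ("malignant", dict()),
            ("possible", dict(has_follow_up=True)),
            ("possible", dict(statuses=("unchanged",))),
        ]
        for _ in range(50):
            assignments = []
            for _ in range(rng.integers(0, 6)):
                malignancy, kwargs = cases[rng.integers(len(cases))]
                locs = tuple(
                    rng.choice(organs, size=rng.integers(1, 3), replace=False)
                )
                assignments.append(
                    classify_entity(
                        make_coded(malignancy=malignancy, locations=locs, **kwargs)
                    )
                )
            got = label_locations(assignments, organs)
            rank = {"no": 0, "low": 1, "high": 2}
            expected = {
                organ: max(
                    (a.actionable for a in assignments if organ in a.locations),
                    key=rank.get,
                    default="no",
                )
                for organ in organs
            }
            assert got == expected


class TestAggregateReport:
    @pytest.mark.parametrize(
        "labels, expected",
        [
            ({"lung": "high", "liver": "low"}, "high"),
            ({"lung": "low"}, "low"),
            ({}, "no"),
            ({"lung": "no", "liver": "no"}, "no"),
        ],
    )
    def test_rules(self, labels, expected):
        assert aggregate_report(labels) == expected

    def test_exhaustive_up_to_four_locations(self):
        for k in range(5):
            for combo in itertools.product(ACTIONABLE_LABELS, repeat=k):
                labels = {f"organ{i}": label for i, label in enumerate(combo)}
                expected = (
                    "high" if "high" in combo else "low" if "low" in combo else "no"
                )
                assert aggregate_report(labels) == expected

    def test_adding_assignment_never_lowers_report_label(self):
        rank = {"no": 0, "low": 1, "high": 2}
        extra = classify_entity(make_coded(malignancy="possible", has_follow_up=True,
                                           locations=("liver",)))
        base_sets = [
            [],
            [classify_entity(make_coded(malignancy="malignant"))],
            [classify_entity(make_coded(malignancy="possible",
                                        statuses=("unchanged",)))],
        ]
        for base in base_sets:
            before = aggregate_report(label_locations(base))
            after = aggregate_report(label_locations(base + [extra]))
            assert rank[after] >= rank[before]


class TestCodeEntitiesAndReport:
    def test_multi_entity_sentence_coding(self, lexicon, config):
        text = "右上葉に増大する3cm大の結節を認め、肺癌を疑う。"
        report = structure_report(raw_report("r", findings=text), lexicon, config)
        coded = {c.entity.surface: c for c in code_entities(report, lexicon)}
        nodule = coded["結節"]
        assert nodule.finding_concept.malignancy_code == "possible"
        assert nodule.location_codes == ["lung"]
        assert nodule.change_statuses == ["increasing"]
        cancer = coded["肺癌"]
        assert "lung" in cancer.location_codes

    def test_finding_without_location_is_other(self, lexicon, config):
        report = structure_report(raw_report("r", findings="腫瘤を認める。"),
                                  lexicon, config)
        (coded,) = code_entities(report, lexicon)
        assert coded.location_codes == ["other"]

    def test_followed_up_lesion_with_location(self, lexicon, config):
        text = "甲状腺に低吸収域を認める。追加検査をご検討ください。"
        report = structure_report(raw_report("r", findings=text), lexicon, config)
        coded = {c.entity.surface: c for c in code_entities(report, lexicon)}
        lesion = coded["低吸収域"]
        assert lesion.has_follow_up
        assert lesion.location_codes == ["thyroid"]

    def test_blank_report_is_no_actionable(self, lexicon):
        result = classify_report(raw_report("empty"), lexicon)
        assert result.report_label == "no"
        assert set(result.location_labels.values()) == {"no"}

    def test_report_label_invariant_to_entity_and_relation_order(self, lexicon, config):
        text = "甲状腺に低吸収域を認める。追加検査をご検討ください。"
        report = structure_report(
            raw_report("r", findings=text, impression="肺癌を疑う。"), lexicon, config
        )
        base = classify_report(report, lexicon)
        shuffled = report.model_copy(
            update={
                "entities": list(reversed(report.entities)),
                "relations": list(reversed(report.relations)),
                "sections": list(reversed(report.sections)),
            }
        )
        permuted = classify_report(shuffled, lexicon)
        assert permuted.report_label == base.report_label
        assert permuted.location_labels == base.location_labels
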