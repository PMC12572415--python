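# Methods

## Problem and scope

`radact` detects cancer-suspicious findings in free-text radiology reports and
grades them as *high*, *low* or *no actionable*, per anatomical location and
per report. It targets the reporting style of Japanese chest/abdomen CT
reports (short declarative sentences, the diagnosis often hedged with 疑う /
"suspected", recommendations in their own sentence), but nothing in the rule
engine is language-specific beyond the dictionary and cue tables.

The package deliberately separates three layers:

1. **Interchange model** (`report_model`) — a validated, versioned JSON-lines
   schema for structured reports. Any upstream system (including trained
   entity/relation/certainty extractors) can produce this format; the
   classifier consumes it as-is.
2. **Reference structurer** (`structurer`) — a deterministic dictionary/cue
   implementation of the structuring step so that raw text can flow through
   the pipeline without any trained model. It is a *reference*, not a claim
   of state-of-the-art extraction accuracy.
3. **Classifier + evaluation + generator** — the actual contribution: the
   four-pattern rule engine, actionable aggregation, metrics, and a synthetic
   corpus generator for controlled experiments.

## Information model

Sections are restricted to `findings` and `impression`; the classification
rules are defined only on these two, and report headers / problem lists are
out of scope. Entity spans are 0-based half-open **code-point** offsets into
the raw section text — byte offsets are fragile for Japanese — and the
invariant `surface == text[start:end]` is checked by the validator, as are id
uniqueness, relation endpoint resolution, and the restriction of certainty
labels to observation/clinical-finding entities.

Certainty uses the five-level scale definite / likely / may_represent /
unlikely / denial. Only *denial* has special downstream semantics (exclusion);
missing certainty on input is treated as *definite*. This is the conservative
default: the exclusion rule only needs to catch negations, and defaulting to
anything weaker could only suppress detections and lower recall.

## Dictionary

Three concept tables stand behind a single surface table
(`src/radact/data/*.tsv`, UTF-8 TSV with header; JSON accepted too):

* **finding concepts** — optional ICD-10 code, optional malignancy code
  (possible | benign | indeterminate | malignant), optional intrinsic organ
  (lung cancer → lung) used when no location modifier is present;
* **location concepts** — organ code (validated against the location
  vocabulary) and body-part code;
* **change concepts** — status code (increasing | decreasing | new |
  unchanged).

Matching is exact on normalized surfaces: NFKC, lower-case, strip (a second
NFKC pass after lower-casing keeps the function idempotent). No fuzzy
matching, and one concept per (surface, kind) is enforced at load. Note that
NFKC may lengthen a string (compatibility ligatures expand), so no length
bound is assumed anywhere.

**Neoplasm screen.** "Non-neoplastic disease code" is operationalized as an
ICD-10 code outside the neoplasm chapter C00–D48 (prefix comparison). A
missing code does *not* trigger exclusion — only a positive non-neoplastic
coding (pneumonia J18, cryptococcosis B45, …) screens a finding out of the
P3/P4 branches. P1/P2 malignancy codes are inherently neoplastic, so the
screen is not applied there.

The seed lexicon (47 surfaces, 18/14/5 concepts) covers every surface used by
the built-in fixtures and generator templates. Malignancy codes are fixed per
term (e.g. 結節/nodule → possible, 腫瘍/tumor → indeterminate,
子宮筋腫/uterine fibroid → benign+D25, 肺癌 → malignant+C34); the
possible-vs-indeterminate boundary is a per-term editorial decision
documented by the table itself, not a contextual judgment.

The default location vocabulary is lung, breast, pancreas, liver, kidney,
thyroid, uterus, ovary, stomach, lymph_node plus the reserved fallback
`other`; a user-supplied vocabulary can replace it (the reserved code is
required).

## Reference structurer

* **Sentence splitting** cuts after any of 。．.!?！？ or newline; spans
  partition the text exactly.
* **Tagging** is greedy longest-match, left-to-right, over a per-code-point
  NFKC/lower view of the text with an offset map back to the original
  (matches must align with original code-point boundaries). Ties between
  equally long candidates go to the leftmost, then to dictionary surfaces
  over follow-up surfaces. Matches never overlap.
* **Relations**: every location/change/other modifier modifies every finding
  entity in its sentence. Follow-up recommendations attach to
  **clinical-finding entities preferentially**, falling back to observations,
  searched first in the recommendation's own sentence and then in the
  immediately preceding sentence of the same section. The preference reflects
  how recommendations are written — "…疑います。追加のフォローください。"
  refers to the suspected diagnosis, not to each co-mentioned observation —
  and it is what makes the documented behavior on followed-up non-neoplastic
  diagnoses reproducible: attaching the recommendation to the co-occurring
  nodule as well would convert those reports into P3 detections.
* **Certainty**: the most guarded cue phrase found in the sentence wins
  (denial > unlikely > may_represent > likely > definite); no cue means
  definite. Cues are full phrases (認めません, ありません, 疑います, …), not
  single characters, because a spurious *denial* is the costliest mistake —
  it silently suppresses a finding.

Sections are processed independently; information is never integrated across
findings and impression. This is a known, deliberate limitation (see the
`impression_only` noise channel below).

## Classification

The rule sequence (see the README table) is evaluated in fixed order, so
precedence is P1 > P2 > P3 > P4: a malignant *and* growing lesion is P1.
Pattern→label mapping is fixed: P1 → high, P2–P4 → low, not-applicable → no.

Locations are the union of related modifier organs and the concept's
intrinsic organ, with `other` for anything unresolvable; a multi-location
finding contributes its pattern to every resolved location (union semantics
is the only order-independent choice). Location labels are the per-location
maximum under high > low > no; the report label is high/low/no by the
any-high / else-any-low / else-no rule. Report-level outputs are therefore
invariant to entity, relation and section order.

"Unlikely" and "may represent" findings pass through like any non-denial
certainty — the rules branch only on denial.

## Evaluation

* Per-class precision/recall/F1 by direct counting; division by zero yields
  0; macro averages run over exactly the three classes, counting absent
  classes as 0.
* **Bootstrap**: percentile intervals (not BCa — the simplest defensible
  choice, flagged here) over whole reports resampled with replacement,
  default 1000 iterations at 95%, seeded (default 42) and reproducible.
  Location-level bootstrap also resamples *reports*, keeping the
  (report × location) items of a report together.
* **Paired deltas** resample the shared report ids jointly and report the
  percentile CI of metric(A) − metric(B); "significant" means the interval
  excludes 0. Paired (not independent) resampling is used because both
  systems are evaluated on the same reports.
* **Cohen's kappa** from the standard formula with marginal-frequency chance
  agreement; the degenerate p_e = 1 case returns 1 for perfect agreement.
* Location-level evaluation scores every (report, location) pair strictly;
  with a single-location vocabulary it reduces exactly to report-level
  evaluation (property-tested).

scikit-learn implements these metrics too; it is used in the tests as an
independent oracle, never as the implementation.

## Synthetic generator

Templates instantiate one short report per draw: a class is sampled from
`class_mix` (default ≈ 23% high, 3×3% low, 68% no, approximating the
prevalence of actionable findings in multi-institutional CT collections), a
location from the template vocabulary, and a template variant. Gold labels
and the pre-structured form are fixed **by template construction**, never by
running the structurer or classifier — so the closed-loop property (noise-free
corpus → macro-F1 = 1.0 through the pipeline, raw and structured paths) is a
genuine end-to-end check, not a tautology.

Four noise channels reproduce documented error-inducing writing styles, each
replacing an eligible draw with a report whose gold label (what a reader
would assign) diverges from what the rules produce:

| channel | eligible class | gold | prediction | mechanism |
|---|---|---|---|---|
| hedged_malignancy | low | low | high | "悪性の除外が必要" fires P1 |
| non_neoplastic_swap | low (P3) | low | no | followed-up cryptococcosis excluded by the ICD screen |
| unknown_surface | low (P2) | low | no | lesion term absent from the dictionary |
| impression_only | no | no | low | benign diagnosis only in the impression; sections are independent |

All channels push prediction away from gold, so macro recall degrades
monotonically in expectation as noise rises (tested at three levels).

Japanese surfaces are authoritative; each report carries an English gloss in
its metadata for readability only. The generator makes no claim of
statistical fidelity to real report length or vocabulary distributions —
passing closed-loop tests shows the pipeline's rules and plumbing are
correct, not that real-world extraction is solved.

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` use 200–1000-report synthetic
corpora, 400–1000 bootstrap iterations, an exhaustive 840-cell rule grid, and
3^k (k ≤ 4) aggregation enumeration; the whole suite runs in seconds. All
randomness flows through `numpy.random.default_rng` seeds; the acceptance
script derives its generator and bootstrap seeds from the single `--seed`
argument. Metrics are plain floating-point ratios; the only tolerance used in
testing is 1e-12 against the reference metric implementation.

## Known limitations

* The reference structurer is intentionally simple: no coreference, no
  syntax, no cross-section integration, cue lists rather than a trained
  certainty model.
* The classifier cannot down-weight "unlikely" findings or read context
  beyond its modifiers; hedged-malignancy phrasings produce high-actionable
  false positives by design (that behavior is part of the documented rule
  semantics and is exercised by the error-style fixtures).
* Longitudinal reasoning (suppressing repeat notifications for a known
  lesion) is out of scope.
* The ICD-10 boundary for "non-neoplastic" (outside C00–D48) and the
  percentile bootstrap are this package's documented operationalizations of
  otherwise under-specified choices.
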