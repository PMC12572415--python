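# radact

Rule-based detection of cancer-suspicious **actionable findings** in free-text
radiology reports, with anatomical-location resolution and a full evaluation
harness.

Findings that suggest cancer need reliable, timely communication to the
referring physician, but they are buried in free-text CT reports and busy
clinicians overlook them. `radact` flags such findings automatically while
staying fully interpretable: every label comes with the rule that fired.

## The method

A report's *findings* and *impression* sections are structured into

* **entities** — observations (結節 / nodule), clinical findings
  (肺癌 / lung cancer), anatomical-location modifiers (右上葉 / right upper
  lobe), change modifiers (増大 / increased) and follow-up recommendations;
* **relations** between modifiers/recommendations and the findings they
  qualify; and
* a five-level **diagnostic certainty** per finding
  (definite, likely, may represent, unlikely, denial).

Entities are coded against a dictionary whose finding concepts carry an
ICD-10 disease code and a **malignancy code** (possible | benign |
indeterminate | malignant), location concepts an organ code, and change
concepts a status code (increasing | decreasing | new | unchanged). Each
non-negated finding is then classified by a fixed rule sequence into one of
four cancer-suspicious writing patterns or "not applicable":

| Pattern | Rule | Label |
|---|---|---|
| P1 | malignancy code = malignant | high actionable |
| P2 | malignancy code = indeterminate | low actionable |
| P3 | possible/benign finding + follow-up recommended | low actionable |
| P4 | possible/benign finding + new or increasing | low actionable |
| — | otherwise (incl. denial-certainty and non-neoplastic ICD-10 for P3/P4) | no actionable |

Labels are resolved to anatomical locations (from location modifiers or the
finding's intrinsic organ, `other` as fallback), maximized per location
(high > low > no), and aggregated per report (high if any location is high,
else low if any is low, else no).

The evaluation module provides per-class and macro precision/recall/F1,
percentile-bootstrap 95% CIs (1000 iterations), paired system deltas and
Cohen's kappa, at both report and strict (report × location) level. A
synthetic generator emits gold-labeled Japanese-style report corpora — in raw
text and pre-structured form — covering the four writing patterns plus the
documented error-inducing styles (hedged malignancy, non-neoplastic
follow-up, out-of-dictionary lesion terms, impression-only diagnoses).

## Worked example

```python
from radact import load_seed_lexicon, raw_report, structure_report, classify_report

lexicon = load_seed_lexicon()
report = raw_report(
    "example",
    findings="右上葉に増大する3cm大の結節を認め、肺癌を疑う。",
    impression="甲状腺に低吸収域を認める。追加検査をご検討ください。",
)
result = classify_report(structure_report(report, lexicon), lexicon)
print("report label:", result.report_label)
for a in result.assignments:
    print(f"  {a.entity_id}: {a.pattern} ({a.triggering_rule}) @ {a.locations}")
```

prints

```
report label: high
  findings-e2: P4 (malignancy 'possible' + change status 'increasing') @ ['lung']
  findings-e3: P1 (malignancy code 'malignant') @ ['lung']
  impression-e1: P3 (malignancy 'possible' + follow-up recommended) @ ['thyroid']
```

The growing nodule fires P4 and the suspected lung cancer fires P1 (both at
the lung), the followed-up thyroid lesion fires P3, so the lung is labeled
high actionable, the thyroid low actionable, and the report overall high
actionable.

The same pipeline is available on the command line:

```bash
radact simulate --out corpus/ --n 100 --seed 3      # raw.jsonl, structured.jsonl, gold.jsonl
radact structure --in corpus/raw.jsonl --out corpus/structured.jsonl
radact classify  --in corpus/structured.jsonl --out corpus/pred.jsonl
radact evaluate  --gold corpus/gold.jsonl --pred corpus/pred.jsonl --level report
```

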