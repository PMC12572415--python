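"""Evaluation harness: per-class and macro precision/recall/F1, percentile
bootstrap confidence intervals, paired system deltas, and Cohen's kappa.

Conventions:

* metrics are computed over the three actionable classes (high, low, no);
  a class absent from both gold and prediction contributes 0 to the macro
  mean and a division by zero yields 0;
* confidence intervals are percentile bootstrap over reports resampled with
  replacement (default 1000 iterations, 95% level), seeded and reproducible;
* location-level evaluation scores every (report, anatomical location) pair
  as one item — strict agreement at the location level;
* report-level labels derive from the location labels by the same
  aggregation rule the classifier uses, so both levels evaluate from one
  data structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .classifier import ACTIONABLE_LABELS, aggregate_report

CLASSES: tuple[str, ...] = ACTIONABLE_LABELS  # ("high", "low", "no")


@dataclass(frozen=True)
class EvalItem:
    """Gold and predicted location-label maps for one report."""

    report_id: str
    gold: dict[str, str]
    pred: dict[str, str]


@dataclass(frozen=True)
class LabeledCorpus:
    items: tuple[EvalItem, ...]

    def __post_init__(self):
        for item in self.items:
            if set(item.gold) != set(item.pred):
                raise ValueError(
                    f"report {item.report_id}: gold and predicted location "
                    "vocabularies differ"
                )

    def __len__(self) -> int:
        return len(self.items)

    def report_pairs(self) -> tuple[list[str], list[str]]:
        gold = [aggregate_report(i.gold) for i in self.items]
        pred = [aggregate_report(i.pred) for i in self.items]
        return gold, pred

    def location_pairs(self) -> tuple[list[str], list[str]]:
        gold: list[str] = []
        pred: list[str] = []
        for item in self.items:
            for organ in sorted(item.gold):
                gold.append(item.gold[organ])
                pred.append(item.pred[organ])
        return gold, pred


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def prf(
    gold: Sequence[str], pred: Sequence[str], positive_class: str
) -> tuple[float, float, float]:
    """Precision, recall and F1 for one class; zero denominators yield 0."""
    if len(gold) != len(pred):
        raise ValueError(f"length mismatch: {len(gold)} gold vs {len(pred)} predicted")
    tp = sum(1 for g, p in zip(gold, pred) if g == positive_class and p == positive_class)
    fp = sum(1 for g, p in zip(gold, pred) if g != positive_class and p == positive_class)
    fn = sum(1 for g, p in zip(gold, pred) if g == positive_class and p != positive_class)
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    f1 = _safe_div(2 * precision * recall, precision + recall)
    return precision, recall, f1


def macro_metrics(
    gold: Sequence[str],
    pred: Sequence[str],
    classes: Sequence[str] = CLASSES,
) -> tuple[float, float, float]:
    """Unweighted mean of per-class P/R/F1 (absent classes count as 0)."""
    triples = [prf(gold, pred, c) for c in classes]
    return tuple(float(np.mean([t[i] for t in triples])) for i in range(3))


def macro_f1(gold: Sequence[str], pred: Sequence[str]) -> float:
    return macro_metrics(gold, pred)[2]


def cohens_kappa(labels_a: Sequence[str], labels_b: Sequence[str]) -> float:
    """Chance-corrected agreement: (p_o - p_e) / (1 - p_e).

    p_e comes from the product of the two raters' marginal label frequencies.
    Perfect agreement with degenerate marginals (p_e = 1) returns 1.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError("label vectors differ in length")
    n = len(labels_a)
    if n == 0:
        raise ValueError("empty label vectors")
    p_o = sum(1 for a, b in zip(labels_a, labels_b) if a == b) / n
    labels = set(labels_a) | set(labels_b)
    p_e = sum(
        (sum(1 for a in labels_a if a == lab) / n)
        * (sum(1 for b in labels_b if b == lab) / n)
        for lab in labels
    )
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1 - p_e)


MetricFn = Callable[[Sequence[str], Sequence[str]], float]


def _pairs(corpus: LabeledCorpus, level: str) -> Callable[[LabeledCorpus], tuple]:
    if level == "report":
        return LabeledCorpus.report_pairs
    if level == "location":
        return LabeledCorpus.location_pairs
    raise ValueError(f"unknown evaluation level {level!r}")


def _item_pairs(corpus: LabeledCorpus, eval_level: str) -> list[list[tuple[str, str]]]:
    """Per-report (gold, pred) label pairs at the requested level, so bootstrap
    resamples of whole reports can be gathered without rebuilding corpora."""
    if eval_level == "report":
        return [
            [(aggregate_report(i.gold), aggregate_report(i.pred))]
            for i in corpus.items
        ]
    if eval_level == "location":
        return [
            [(i.gold[organ], i.pred[organ]) for organ in sorted(i.gold)]
            for i in corpus.items
        ]
    raise ValueError(f"unknown evaluation level {eval_level!r}")


def bootstrap_ci(
    corpus: LabeledCorpus,
    metric: MetricFn = macro_f1,
    n_iter: int = 1000,
    level: float = 0.95,
    seed: int = 42,
    eval_level: str = "report",
) -> tuple[float, float]:
    """Percentile bootstrap CI for a metric; reports resampled with replacement."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if not corpus.items:
        raise ValueError("empty corpus")
    per_item = _item_pairs(corpus, eval_level)
    rng = np.random.default_rng(seed)
    n = len(corpus)
    stats = np.empty(n_iter)
    for it in range(n_iter):
        idx = rng.integers(0, n, size=n)
        gold = [pair[0] for i in idx for pair in per_item[i]]
        pred = [pair[1] for i in idx for pair in per_item[i]]
        stats[it] = metric(gold, pred)
    alpha = (1 - level) / 2
    lower, upper = np.quantile(stats, [alpha, 1 - alpha])
    return float(lower), float(upper)


@dataclass(frozen=True)
class PairedDelta:
    delta: float
    lower: float
    upper: float
    significant: bool  # CI excludes zero

    def as_tuple(self) -> tuple[float, float, float]:
        return self.delta, self.lower, self.upper


def paired_delta(
    corpus_a: LabeledCorpus,
    corpus_b: LabeledCorpus,
    metric: MetricFn = macro_f1,
    n_iter: int = 1000,
    level: float = 0.95,
    seed: int = 42,
    eval_level: str = "report",
) -> PairedDelta:
    """Bootstrap CI for metric(A) - metric(B) on jointly resampled reports."""
    ids_a = [i.report_id for i in corpus_a.items]
    ids_b = [i.report_id for i in corpus_b.items]
    if ids_a != ids_b:
        raise ValueError("paired corpora must cover the same report ids in order")
    pairs = _pairs(corpus_a, eval_level)
    per_item_a = _item_pairs(corpus_a, eval_level)
    per_item_b = _item_pairs(corpus_b, eval_level)
    rng = np.random.default_rng(seed)
    n = len(corpus_a)
    deltas = np.empty(n_iter)
    for it in range(n_iter):
        idx = rng.integers(0, n, size=n)
        gold_a = [p[0] for i in idx for p in per_item_a[i]]
        pred_a = [p[1] for i in idx for p in per_item_a[i]]
        gold_b = [p[0] for i in idx for p in per_item_b[i]]
        pred_b = [p[1] for i in idx for p in per_item_b[i]]
        deltas[it] = metric(gold_a, pred_a) - metric(gold_b, pred_b)
    alpha = (1 - level) / 2
    lower, upper = np.quantile(deltas, [alpha, 1 - alpha])
    gold_a, pred_a = pairs(corpus_a)
    gold_b, pred_b = pairs(corpus_b)
    point = metric(gold_a, pred_a) - metric(gold_b, pred_b)
    significant = lower > 0 or upper < 0
    return PairedDelta(float(point), float(lower), float(upper), significant)


@dataclass
class EvaluationReport:
    """Per-class and macro metrics with bootstrap CIs, in Table form."""

    level: str
    per_class: dict[str, dict]  # label -> {precision, recall, f1, support}
    macro: dict  # {precision, recall, f1}
    ci: dict  # metric name -> (lower, upper)
    n_items: int
    n_bootstrap: int
    seed: int
    classes: tuple[str, ...] = CLASSES

    def as_dict(self) -> dict:
        return {
            "level": self.level,
            "per_class": self.per_class,
            "macro": self.macro,
            "ci": {k: list(v) for k, v in self.ci.items()},
            "n_items": self.n_items,
            "n_bootstrap": self.n_bootstrap,
            "seed": self.seed,
        }

    def as_table(self) -> str:
        rows = [f"{'Label':<16}{'Precision':<12}{'Recall':<12}{'F1-score':<12}{'N':>6}"]
        for label in self.classes:
            m = self.per_class[label]
            rows.append(
                f"{label + ' actionable':<16}{m['precision']:<12.3f}"
                f"{m['recall']:<12.3f}{m['f1']:<12.3f}{m['support']:>6d}"
            )
        lo, hi = self.ci.get("macro_f1", (float("nan"), float("nan")))
        rows.append(
            f"{'Total (macro)':<16}{self.macro['precision']:<12.3f}"
            f"{self.macro['recall']:<12.3f}{self.macro['f1']:<12.3f}{self.n_items:>6d}"
        )
        rows.append(f"macro F1 95% CI: ({lo:.3f}, {hi:.3f})  "
                    f"[{self.n_bootstrap} bootstrap iterations, seed {self.seed}]")
        return "\n".join(rows)


def _evaluate(
    corpus: LabeledCorpus,
    eval_level: str,
    n_bootstrap: int,
    seed: int,
    ci_level: float,
) -> EvaluationReport:
    gold, pred = _pairs(corpus, eval_level)(corpus)
    per_class = {}
    for label in CLASSES:
        p, r, f1 = prf(gold, pred, label)
        per_class[label] = {
            "precision": p,
            "recall": r,
            "f1": f1,
            "support": sum(1 for g in gold if g == label),
        }
    mp, mr, mf = macro_metrics(gold, pred)
    ci = {}
    if n_bootstrap > 0:
        ci["macro_f1"] = bootstrap_ci(
            corpus, macro_f1, n_bootstrap, ci_level, seed, eval_level
        )
        ci["macro_precision"] = bootstrap_ci(
            corpus,
            lambda g, p: macro_metrics(g, p)[0],
            n_bootstrap, ci_level, seed, eval_level,
        )
        ci["macro_recall"] = bootstrap_ci(
            corpus,
            lambda g, p: macro_metrics(g, p)[1],
            n_bootstrap, ci_level, seed, eval_level,
        )
    return EvaluationReport(
        level=eval_level,
        per_class=per_class,
        macro={"precision": mp, "recall": mr, "f1": mf},
        ci=ci,
        n_items=len(gold),
        n_bootstrap=n_bootstrap,
        seed=seed,
    )


def evaluate_report_level(
    corpus: LabeledCorpus,
    n_bootstrap: int = 1000,
    seed: int = 42,
    ci_level: float = 0.95,
) -> EvaluationReport:
    """Report-level metrics (one item per report)."""
    return _evaluate(corpus, "report", n_bootstrap, seed, ci_level)


def evaluate_location_level(
    corpus: LabeledCorpus,
    n_bootstrap: int = 1000,
    seed: int = 42,
    ci_level: float = 0.95,
) -> EvaluationReport:
    """Location-level metrics (one item per report x anatomical location)."""
    return _evaluate(corpus, "location", n_bootstrap, seed, ci_level)


def corpus_from_label_maps(
    gold: dict[str, dict[str, str]],
    pred: dict[str, dict[str, str]],
) -> LabeledCorpus:
    """Build a LabeledCorpus from {report_id: {organ: label}} maps."""
    if set(gold) != set(pred):
        raise ValueError("gold and predicted corpora cover different report ids")
    items = tuple(
        EvalItem(report_id=rid, gold=dict(gold[rid]), pred=dict(pred[rid]))
        for rid in sorted(gold)
    )
    return LabeledCorpus(items=items)
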