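"""Scoring: span matching, class metrics with the na column, error analysis.

Matching is lenient: any character-span overlap between a gold and a system
annotation counts.  Pairing is greedy one-to-one by maximal overlap (ties
broken by earliest system start); unmatched gold annotations are *missed*,
unmatched system annotations are *added*.

Two metric families are derived from a match:

* span-based P/R/F1 — TP = matched pairs, FP = added, FN = missed;
* class-based metrics over the DATE/DURATION type confusion, where a gold
  annotation with no overlapping system annotation lands in the ``na``
  column and counts as a false negative for its class, while system-only
  annotations are excluded entirely.  Per-class scores are combined by a
  gold-support weighted average; class accuracy is the agreement rate over
  matched pairs (the na column has no prediction to agree with).

Error analysis buckets every discrepancy into value / label / missed /
added categories; a value error is only counted when the label was correct.
Percentile bootstrap confidence intervals resample documents with
replacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from clintern.corpus_io import TimexAnnotation

__all__ = [
    "MatchResult", "TypeConfusion", "ErrorReport",
    "match_pairs", "span_prf", "class_metrics", "confusion_from_pairs",
    "error_breakdown", "select_difficult_files", "bootstrap_ci",
    "canonical_value",
]

CLASSES = ("DATE", "DURATION")


@dataclass
class MatchResult:
    matched: list[tuple[TimexAnnotation, TimexAnnotation]]
    missed: list[TimexAnnotation]
    added: list[TimexAnnotation]


def _overlap(a: TimexAnnotation, b: TimexAnnotation) -> int:
    return min(a.end, b.end) - max(a.start, b.start)


def match_pairs(gold: list[TimexAnnotation],
                system: list[TimexAnnotation]) -> MatchResult:
    """Greedy one-to-one lenient matching by maximal overlap."""
    pairs = [
        (g_i, s_i, _overlap(g, s))
        for g_i, g in enumerate(gold)
        for s_i, s in enumerate(system)
        if _overlap(g, s) > 0
    ]
    # maximal overlap first; ties by earliest system start, then gold start
    pairs.sort(key=lambda t: (-t[2], system[t[1]].start, gold[t[0]].start))
    used_g: set[int] = set()
    used_s: set[int] = set()
    matched = []
    for g_i, s_i, _ in pairs:
        if g_i in used_g or s_i in used_s:
            continue
        used_g.add(g_i)
        used_s.add(s_i)
        matched.append((gold[g_i], system[s_i]))
    missed = [g for i, g in enumerate(gold) if i not in used_g]
    added = [s for i, s in enumerate(system) if i not in used_s]
    return MatchResult(matched=matched, missed=missed, added=added)


def span_prf(match: MatchResult) -> tuple[float, float, float]:
    """Span-based precision, recall, F1 (empty denominators give 0)."""
    tp, fp, fn = len(match.matched), len(match.added), len(match.missed)
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


# ---------------------------------------------------------------------------
# Class-based metrics over the 2x(2+na) confusion

@dataclass
class TypeConfusion:
    """Gold type × {predicted DATE, predicted DURATION, na} counts."""

    counts: dict[str, dict[str, int]] = field(
        default_factory=lambda: {c: {"DATE": 0, "DURATION": 0, "na": 0}
                                 for c in CLASSES})

    @classmethod
    def from_rows(cls, date_row: tuple[int, int, int],
                  duration_row: tuple[int, int, int]) -> "TypeConfusion":
        cm = cls()
        for cls_name, row in zip(CLASSES, (date_row, duration_row)):
            for col, n in zip(("DATE", "DURATION", "na"), row):
                if n < 0:
                    raise ValueError("confusion counts must be >= 0")
                cm.counts[cls_name][col] = int(n)
        return cm

    def add(self, gold_type: str, predicted: str | None) -> None:
        self.counts[gold_type][predicted if predicted is not None else "na"] += 1

    def gold_total(self, cls_name: str) -> int:
        return sum(self.counts[cls_name].values())

    @property
    def total(self) -> int:
        return sum(self.gold_total(c) for c in CLASSES)


def confusion_from_pairs(
    doc_pairs: list[tuple[list[TimexAnnotation], list[TimexAnnotation]]],
) -> TypeConfusion:
    """Build the DATE/DURATION confusion from per-document (gold, system) sets.

    Gold annotations of other types are ignored; matched system predictions
    outside {DATE, DURATION} count as a miss of the correct class (they fall
    in the opposite-class column only if DATE/DURATION, else na).
    """
    cm = TypeConfusion()
    for gold, system in doc_pairs:
        match = match_pairs(gold, system)
        matched_gold = {id(g): s for g, s in match.matched}
        for g in gold:
            if g.ttype.value not in CLASSES:
                continue
            s = matched_gold.get(id(g))
            if s is None:
                cm.add(g.ttype.value, None)
            elif s.ttype.value in CLASSES:
                cm.add(g.ttype.value, s.ttype.value)
            else:
                cm.add(g.ttype.value, None)
    return cm


def class_metrics(cm: TypeConfusion) -> dict:
    """Per-class and gold-support-weighted P/R/F1 plus matched-pair accuracy.

    na counts as a false negative for its gold class; system-only
    annotations never enter the matrix, so precision denominators are the
    predicted-column totals.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    per_class = {}
    for c in CLASSES:
        other = CLASSES[1 - CLASSES.index(c)]
        tp = cm.counts[c][c]
        fp = cm.counts[other][c]
        fn = cm.counts[c][other] + cm.counts[c]["na"]
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * p * r / (p + r) if p + r else 0.0
        per_class[c] = {"precision": p, "recall": r, "f1": f1,
                        "support": cm.gold_total(c)}
    total_w = sum(per_class[c]["support"] for c in CLASSES)
    weighted = {
        m: sum(per_class[c][m] * per_class[c]["support"] for c in CLASSES) / total_w
        for m in ("precision", "recall", "f1")
    }
    matched_total = sum(cm.counts[c][k] for c in CLASSES for k in CLASSES)
    agreement = sum(cm.counts[c][c] for c in CLASSES)
    accuracy = agreement / matched_total if matched_total else 0.0
    return {"per_class": per_class, "weighted": weighted, "accuracy": accuracy}


# ---------------------------------------------------------------------------
# Error-category analysis

def canonical_value(value: str) -> str:
    """ISO canonicalization before string comparison of values."""
    v = value.strip()
    if v.upper().startswith("P"):
        return v.upper()
    # drop an explicit seconds field of :00 in date-times
    if len(v) >= 19 and v[16] == ":" and v.endswith(":00"):
        v = v[:16]
    return v


@dataclass
class ErrorReport:
    total_errors: int
    value_errors: int
    label_errors: int
    missed: int
    added: int
    value_rel_share: float      # fraction of value errors on RelIV phrases
    label_rel_share: float

    def percentages(self) -> dict[str, float]:
        t = self.total_errors or 1
        return {
            "value_pct": 100.0 * self.value_errors / t,
            "label_pct": 100.0 * self.label_errors / t,
            "missed_pct": 100.0 * self.missed / t,
            "added_pct": 100.0 * self.added / t,
        }


def _ann_key(doc_index: int, ann: TimexAnnotation) -> tuple:
    return (doc_index, ann.start, ann.end)


def error_breakdown(
    gold_sets: list[list[TimexAnnotation]],
    system_sets: list[list[TimexAnnotation]],
    reliv_sets: list[list[TimexAnnotation]] | None = None,
) -> ErrorReport:
    """Categorize all discrepancies across parallel per-document sets.

    A matched pair contributes a *label error* when types differ, and a
    *value error* only when the label was correct but the canonicalized
    values differ (empty gold values are not compared).  The RelIV shares
    are the fraction of value/label errors whose gold annotation belongs to
    the relative/implicit/vague subset.
    """
    if len(gold_sets) != len(system_sets):
        raise ValueError("gold and system document lists must align")
    reliv_keys: set[tuple] = set()
    if reliv_sets is not None:
        for di, anns in enumerate(reliv_sets):
            reliv_keys.update(_ann_key(di, a) for a in anns)

    value_errors = label_errors = missed = added = 0
    value_rel = label_rel = 0
    for di, (gold, system) in enumerate(zip(gold_sets, system_sets)):
        match = match_pairs(gold, system)
        missed += len(match.missed)
        added += len(match.added)
        for g, s in match.matched:
            if g.ttype != s.ttype:
                label_errors += 1
                if _ann_key(di, g) in reliv_keys:
                    label_rel += 1
            elif g.value and canonical_value(g.value) != canonical_value(s.value):
                value_errors += 1
                if _ann_key(di, g) in reliv_keys:
                    value_rel += 1

    total = value_errors + label_errors + missed + added
    return ErrorReport(
        total_errors=total,
        value_errors=value_errors,
        label_errors=label_errors,
        missed=missed,
        added=added,
        value_rel_share=value_rel / value_errors if value_errors else 0.0,
        label_rel_share=label_rel / label_errors if label_errors else 0.0,
    )


def select_difficult_files(per_file_metrics: dict[str, dict[str, float]],
                           threshold: float = 0.75) -> list[str]:
    """Files whose min(precision, recall, value accuracy) <= threshold."""
    out = []
    for name, m in per_file_metrics.items():
        low = min(m["precision"], m["recall"], m["value_accuracy"])
        if low <= threshold:
            out.append(name)
    return sorted(out)


# ---------------------------------------------------------------------------
# Bootstrap

def bootstrap_ci(documents: list, metric, B: int = 1000, seed: int = 0,
                 level: float = 0.95) -> tuple[float, float, float]:
    """Percentile bootstrap over documents for any corpus-level metric.

    ``metric`` takes a list of per-document items and returns a float; the
    point estimate is the metric on the full list.
    """
    if len(documents) < 2:
        raise ValueError("bootstrap requires at least 2 documents")
    if B < 100:
        raise ValueError("B must be >= 100")
    rng = np.random.default_rng(seed)
    point = float(metric(documents))
    replicates = np.empty(B)
    n = len(documents)
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        replicates[b] = metric([documents[i] for i in idx])
    alpha = (1.0 - level) / 2.0
    low, high = np.quantile(replicates, [alpha, 1.0 - alpha])
    return point, float(low), float(high)
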