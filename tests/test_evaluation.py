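"""Span matching, class metrics with na, error analysis, bootstrap."""

import numpy as np
import pytest

from clintern.corpus_io import TimexAnnotation, TimexType
from clintern.evaluation import (
    ErrorReport, MatchResult, TypeConfusion, bootstrap_ci, canonical_value,
    class_metrics, confusion_from_pairs, error_breakdown, match_pairs,
    select_difficult_files, span_prf,
)
from clintern.synthetic_corpus import GeneratorConfig, generate_corpus, generate_system_run


def ann(start, end, ttype=TimexType.DATE, value="", ann_id=None):
    return TimexAnnotation(ann_id=ann_id or f"a{start}", start=start, end=end,
                           text="x" * (end - start), ttype=ttype, value=value)


class TestMatchPairs:
    def test_overlapping_spans_match(self):
        m = match_pairs([ann(10, 20)], [ann(15, 25)])
        assert len(m.matched) == 1 and not m.missed and not m.added

    def test_disjoint_spans(self):
        m = match_pairs([ann(10, 20)], [ann(30, 40)])
        assert not m.matched and len(m.missed) == 1 and len(m.added) == 1

    def test_two_system_spans_one_gold(self):
        # maximal-overlap assignment: the larger-overlap span wins the pair
        gold = [ann(10, 30)]
        system = [ann(10, 15), ann(14, 30)]
        m = match_pairs(gold, system)
        assert len(m.matched) == 1 and len(m.added) == 1
        assert m.matched[0][1].start == 14  # 16-char overlap beats 5

    def test_tie_broken_by_earliest_system_start(self):
        gold = [ann(10, 20)]
        system = [ann(15, 20), ann(10, 15)]
        m = match_pairs(gold, system)
        assert m.matched[0][1].start == 10

    def test_one_to_one(self):
        gold = [ann(0, 10), ann(12, 22)]
        system = [ann(5, 15)]  # overlaps both
        m = match_pairs(gold, system)
        assert len(m.matched) == 1 and len(m.missed) == 1 and not m.added


class TestSpanPRF:
    def test_direct_arithmetic(self):
        m = MatchResult(matched=[(None, None)] * 8, missed=[None] * 2,
                        added=[None] * 2)
        assert span_prf(m) == (0.8, 0.8, pytest.approx(0.8))

    def test_perfect(self):
        m = MatchResult(matched=[(None, None)], missed=[], added=[])
        assert span_prf(m) == (1.0, 1.0, 1.0)

    def test_empty_system_convention(self):
        m = MatchResult(matched=[], missed=[None] * 3, added=[])
        assert span_prf(m) == (0.0, 0.0, 0.0)

    def test_swapping_gold_and_system_swaps_p_and_r(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            gold = [ann(s, s + int(rng.integers(2, 8)))
                    for s in rng.choice(200, size=6, replace=False)]
            system = [ann(s, s + int(rng.integers(2, 8)))
                      for s in rng.choice(200, size=4, replace=False)]
            p1, r1, _ = span_prf(match_pairs(gold, system))
            p2, r2, _ = span_prf(match_pairs(system, gold))
            assert p1 == pytest.approx(r2) and r1 == pytest.approx(p2)


def oracle_class_metrics(date_row, dur_row):
    """Independent per-item tally of the 2x(2+na) confusion."""
    items = []
    for gold, row in (("DATE", date_row), ("DURATION", dur_row)):
        for pred, n in zip(("DATE", "DURATION", None), row):
            items.extend([(gold, pred)] * n)
    out = {}
    for c in ("DATE", "DURATION"):
        tp = sum(1 for g, p in items if g == c and p == c)
        fp = sum(1 for g, p in items if g != c and p == c)
        fn = sum(1 for g, p in items if g == c and p != c)
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * p * r / (p + r) if p + r else 0.0
        out[c] = (p, r, f1, sum(1 for g, _ in items if g == c))
    total_w = out["DATE"][3] + out["DURATION"][3]
    weighted = tuple(
        (out["DATE"][i] * out["DATE"][3] + out["DURATION"][i] * out["DURATION"][3])
        / total_w for i in range(3))
    matched = [(g, p) for g, p in items if p is not None]
    acc = (sum(1 for g, p in matched if g == p) / len(matched)) if matched else 0.0
    return out, weighted, acc


class TestClassMetrics:
    def test_diagonal_matrix_is_perfect(self):
        cm = TypeConfusion.from_rows((10, 0, 0), (0, 5, 0))
        m = class_metrics(cm)
        assert m["weighted"]["f1"] == 1.0 and m["accuracy"] == 1.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            class_metrics(TypeConfusion.from_rows((0, 0, 0), (0, 0, 0)))

    def test_na_counts_as_false_negative(self):
        cm = TypeConfusion.from_rows((5, 0, 5), (0, 10, 0))
        m = class_metrics(cm)
        assert m["per_class"]["DATE"]["recall"] == 0.5
        assert m["per_class"]["DATE"]["precision"] == 1.0

    def test_oracle_equivalence_on_random_matrices(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            date_row = tuple(int(x) for x in rng.integers(0, 12, size=3))
            dur_row = tuple(int(x) for x in rng.integers(0, 12, size=3))
            if sum(date_row) + sum(dur_row) == 0:
                continue
            m = class_metrics(TypeConfusion.from_rows(date_row, dur_row))
            oracle, weighted, acc = oracle_class_metrics(date_row, dur_row)
            for c in ("DATE", "DURATION"):
                assert m["per_class"][c]["precision"] == pytest.approx(oracle[c][0])
                assert m["per_class"][c]["recall"] == pytest.approx(oracle[c][1])
                assert m["per_class"][c]["f1"] == pytest.approx(oracle[c][2])
            assert m["weighted"]["f1"] == pytest.approx(weighted[2])
            assert m["accuracy"] == pytest.approx(acc)

    def test_weighted_lies_between_class_scores(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            cm = TypeConfusion.from_rows(
                tuple(int(x) for x in rng.integers(1, 20, size=3)),
                tuple(int(x) for x in rng.integers(1, 20, size=3)))
            m = class_metrics(cm)
            for metric in ("precision", "recall", "f1"):
                lo = min(m["per_class"][c][metric] for c in ("DATE", "DURATION"))
                hi = max(m["per_class"][c][metric] for c in ("DATE", "DURATION"))
                assert lo - 1e-12 <= m["weighted"][metric] <= hi + 1e-12

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            TypeConfusion.from_rows((-1, 0, 0), (0, 0, 0))


class TestErrorBreakdown:
    def test_value_error_when_label_correct(self):
        gold = [ann(0, 6, TimexType.DURATION, value="P2D")]
        system = [ann(0, 6, TimexType.DURATION, value="P3D")]
        report = error_breakdown([gold], [system])
        assert report.value_errors == 1 and report.label_errors == 0

    def test_label_error_suppresses_value_check(self):
        gold = [ann(0, 6, TimexType.DATE, value="2013-02-04")]
        system = [ann(0, 6, TimexType.DURATION, value="")]
        report = error_breakdown([gold], [system])
        assert report.label_errors == 1 and report.value_errors == 0

    def test_injected_errors_match_bookkeeping(self):
        docs, _ = generate_corpus(GeneratorConfig(n_documents=30, seed=21))
        rates = {"drop": 0.15, "flip": 0.1, "value": 0.2, "add": 0.1}
        system, log = generate_system_run(docs, rates, seed=5)
        report = error_breakdown(
            [d.annotations for d in docs],
            [system[d.doc_id] for d in docs])
        assert report.missed == sum(len(e["dropped"]) for e in log.values())
        assert report.label_errors == sum(len(e["flipped"]) for e in log.values())
        assert report.value_errors == sum(len(e["value"]) for e in log.values())
        assert report.added == sum(len(e["added"]) for e in log.values())

    def test_rel_share_uses_reliv_membership(self):
        gold = [ann(0, 6, TimexType.DURATION, value="P2D"),
                ann(10, 20, TimexType.DURATION, value="P3W")]
        system = [ann(0, 6, TimexType.DURATION, value="P4D"),
                  ann(10, 20, TimexType.DURATION, value="P5W")]
        report = error_breakdown([gold], [system], reliv_sets=[[gold[0]]])
        assert report.value_errors == 2
        assert report.value_rel_share == pytest.approx(0.5)

    def test_percentages_sum_to_100(self):
        report = ErrorReport(total_errors=10, value_errors=4, label_errors=3,
                             missed=2, added=1, value_rel_share=0.0,
                             label_rel_share=0.0)
        assert sum(report.percentages().values()) == pytest.approx(100.0)


class TestDifficultFiles:
    def test_selection_rule(self):
        metrics = {
            "f1": {"precision": 0.9, "recall": 0.9, "value_accuracy": 0.70},
            "f2": {"precision": 0.76, "recall": 0.8, "value_accuracy": 0.9},
            "f3": {"precision": 0.75, "recall": 0.9, "value_accuracy": 0.9},
        }
        assert select_difficult_files(metrics) == ["f1", "f3"]

    def test_threshold_one_selects_all(self):
        metrics = {"f1": {"precision": 1.0, "recall": 1.0, "value_accuracy": 1.0}}
        assert select_difficult_files(metrics, threshold=1.0) == ["f1"]


class TestBootstrap:
    def test_degenerate_zero_width(self):
        docs = [1.0] * 10
        point, lo, hi = bootstrap_ci(docs, lambda xs: sum(xs) / len(xs),
                                     B=200, seed=0)
        assert point == lo == hi == 1.0

    def test_seed_reproducibility(self):
        docs = list(np.random.default_rng(3).normal(size=20))
        metric = lambda xs: float(np.mean(xs))
        assert (bootstrap_ci(docs, metric, B=300, seed=9)
                == bootstrap_ci(docs, metric, B=300, seed=9))

    def test_interval_covers_point_estimate(self):
        docs, _ = generate_corpus(GeneratorConfig(n_documents=25, seed=3))
        system, _ = generate_system_run(docs, {"flip": 0.15}, seed=2)
        pairs = [(d.annotations, system[d.doc_id]) for d in docs]
        metric = lambda ps: class_metrics(confusion_from_pairs(ps))["weighted"]["f1"]
        point, lo, hi = bootstrap_ci(pairs, metric, B=1000, seed=0)
        assert lo <= point <= hi

    def test_too_few_documents(self):
        with pytest.raises(ValueError):
            bootstrap_ci([1.0], lambda xs: 1.0, B=200, seed=0)


class TestCanonicalValue:
    def test_duration_case_insensitive(self):
        assert canonical_value("p2d") == canonical_value("P2D")

    def test_datetime_seconds_trimmed(self):
        assert canonical_value("2014-01-08T09:00:00") == "2014-01-08T09:00"
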