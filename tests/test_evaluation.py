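"""Metric suite, copy-number discretization, resolution changes."""

import logging

import numpy as np
import pytest

from exocnv.calling import SegmentCall, merge_segments, CallRecord
from exocnv.depth_io import DEL, DUP, NOCALL, ExonTarget, TruthCall
from exocnv.evaluation import (
    MetricsReport,
    compute_metrics,
    consensus_truth_for_segment,
    discretize_copy_number,
    discretize_truth,
    f1_score,
    intersect_segments_to_exons,
    metrics_by_exon_length,
    segment_level_metrics,
)
from exocnv.training import assign_exon_labels


class TestDiscretizeCopyNumber:
    @pytest.mark.parametrize("cn,expected", [(0, DEL), (1, DEL), (2, NOCALL), (3, DUP), (4, DUP)])
    def test_rule(self, cn, expected):
        assert discretize_copy_number(cn) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            discretize_copy_number(-1)

    def test_truth_records_discretized_and_neutral_dropped(self):
        truth = [
            TruthCall(1, 0, 10, copy_number=4),
            TruthCall(1, 20, 30, copy_number=2),
            TruthCall(1, 40, 50, copy_number=0),
            TruthCall(2, 0, 10, call=DEL),
        ]
        out = discretize_truth(truth)
        assert [(c.chrom_index, c.call) for c in out] == [(1, DUP), (1, DEL), (2, DEL)]


class TestComputeMetrics:
    def test_perfect_prediction_scores_one_everywhere(self):
        calls = {"a": DEL, "b": DUP, "c": NOCALL, "d": DEL}
        _, rep = compute_metrics(calls, dict(calls))
        for name in ("precision", "recall", "f1", "npa", "npv"):
            for cls in ("del", "dup", "overall"):
                assert getattr(rep, f"{name}_{cls}") == 1.0

    def test_universe_mismatch_names_missing_exons(self):
        with pytest.raises(ValueError, match="exon7"):
            compute_metrics({"exon7": DEL}, {"exon9": DEL})

    def test_zero_denominators_report_zero_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING):
            _, rep = compute_metrics({"a": NOCALL}, {"a": NOCALL})
        assert rep.precision_del == 0.0 and rep.recall_dup == 0.0
        assert "empty denominator" in caplog.text

    def test_matches_bruteforce_recount_on_random_instances(self):
        rng = np.random.default_rng(7)
        classes = (DEL, DUP, NOCALL)
        for _ in range(25):
            n = int(rng.integers(1, 200))
            ids = [f"e{i}" for i in range(n)]
            pred = {i: classes[int(rng.integers(0, 3))] for i in ids}
            truth = {i: classes[int(rng.integers(0, 3))] for i in ids}
            ct, rep = compute_metrics(pred, truth)
            for cls, pre_attr, rec_attr in ((DUP, "precision_dup", "recall_dup"),
                                            (DEL, "precision_del", "recall_del")):
                tp = sum(1 for i in ids if pred[i] == cls and truth[i] == cls)
                fp = sum(1 for i in ids if pred[i] == cls and truth[i] != cls)
                t_total = sum(1 for i in ids if truth[i] == cls)
                assert getattr(rep, pre_attr) == (tp / (tp + fp) if tp + fp else 0.0)
                assert getattr(rep, rec_attr) == (tp / t_total if t_total else 0.0)
            assert rep.precision_overall == (rep.precision_dup + rep.precision_del) / 2
            assert rep.recall_overall == (rep.recall_dup + rep.recall_del) / 2
            assert rep.f1_overall == f1_score(rep.precision_overall, rep.recall_overall)
            assert ct.T_dup == sum(1 for i in ids if truth[i] == DUP)

    def test_matches_sklearn_confusion_matrix(self):
        """Independent cross-check of the per-class counts."""
        from sklearn.metrics import confusion_matrix

        rng = np.random.default_rng(8)
        classes = (DEL, DUP, NOCALL)
        n = 300
        pred = [classes[int(rng.integers(0, 3))] for _ in range(n)]
        truth = [classes[int(rng.integers(0, 3))] for _ in range(n)]
        ids = [f"e{i}" for i in range(n)]
        ct, _ = compute_metrics(dict(zip(ids, pred)), dict(zip(ids, truth)))
        cm = confusion_matrix(truth, pred, labels=list(classes))
        assert ct.TP_del == cm[0, 0]
        assert ct.TP_dup == cm[1, 1]
        assert ct.FP_del == cm[1, 0] + cm[2, 0]
        assert ct.FN_dup == cm[1, 0] + cm[1, 2]

    def test_f1_is_zero_when_either_component_is_zero(self):
        assert f1_score(0.0, 0.9) == 0.0
        assert f1_score(0.9, 0.0) == 0.0
        assert f1_score(0.5, 0.5) == 0.5


class TestResolutionChanges:
    def test_exon_inside_segment_takes_its_call(self):
        segs = [SegmentCall(1, 0, 1000, DUP, 3)]
        out = intersect_segments_to_exons(segs, [ExonTarget(1, 100, 200, "e")])
        assert out == {"e": DUP}

    def test_majority_base_rule_with_tie_to_nocall(self):
        segs = [SegmentCall(1, 0, 180, DEL, 1), SegmentCall(1, 180, 300, DUP, 1)]
        targets = [
            ExonTarget(1, 100, 200, "mostly_del"),   # 80 bp DEL / 20 bp DUP
            ExonTarget(1, 160, 200, "tied"),         # 20 / 20
            ExonTarget(1, 400, 500, "gap"),
        ]
        out = intersect_segments_to_exons(segs, targets)
        assert out == {"mostly_del": DEL, "tied": NOCALL, "gap": NOCALL}

    def test_overlapping_same_call_segments_merge_silently(self):
        segs = [SegmentCall(1, 0, 150, DEL, 1), SegmentCall(1, 100, 300, DEL, 2)]
        out = intersect_segments_to_exons(segs, [ExonTarget(1, 120, 140, "e")])
        assert out == {"e": DEL}

    def test_consensus_label_by_covered_bases(self):
        seg = SegmentCall(1, 0, 1000, DEL, 4)
        truth = [TruthCall(1, 0, 700, call=DEL), TruthCall(1, 700, 750, call=DUP)]
        assert consensus_truth_for_segment(seg, truth) == DEL

    def test_consensus_without_overlap_or_with_tie_is_nocall(self):
        seg = SegmentCall(1, 0, 100, DEL, 1)
        assert consensus_truth_for_segment(seg, []) == NOCALL
        tie = [TruthCall(1, 0, 50, call=DEL), TruthCall(1, 50, 100, call=DUP)]
        assert consensus_truth_for_segment(seg, tie) == NOCALL

    def test_consensus_and_intersection_match_per_base_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            targets, pos = [], 0
            for i in range(10):
                pos += int(rng.integers(5, 50))
                end = pos + int(rng.integers(5, 60))
                targets.append(ExonTarget(1, pos, end, f"t{i}"))
                pos = end
            segs, truth, cursor = [], [], 0
            for _ in range(int(rng.integers(0, 6))):
                cursor += int(rng.integers(0, 80))
                end = cursor + int(rng.integers(5, 90))
                segs.append(SegmentCall(1, cursor, end, DEL if rng.random() < 0.5 else DUP, 1))
                cursor = end + 1
            cursor = 0
            for _ in range(int(rng.integers(0, 6))):
                cursor += int(rng.integers(0, 80))
                end = cursor + int(rng.integers(5, 90))
                truth.append(TruthCall(1, cursor, end, call=DEL if rng.random() < 0.5 else DUP))
                cursor = end + 1

            def base_cover(lo, hi, items, cls):
                return sum(
                    1
                    for b in range(lo, hi)
                    if any(x.start <= b < x.end and _cls(x) == cls for x in items)
                )

            def _cls(x):
                return x.call

            out = intersect_segments_to_exons(segs, targets)
            for t in targets:
                d = base_cover(t.start, t.end, segs, DEL)
                u = base_cover(t.start, t.end, segs, DUP)
                expected = NOCALL if d == u else (DEL if d > u else DUP)
                assert out[t.id] == expected, (t, d, u)
            for s in segs:
                d = base_cover(s.start, s.end, truth, DEL)
                u = base_cover(s.start, s.end, truth, DUP)
                expected = NOCALL if d == u else (DEL if d > u else DUP)
                assert consensus_truth_for_segment(s, truth) == expected

    def test_exon_resolution_truth_survives_segment_round_trip(self):
        """merge -> consensus -> intersect leaves an exon-resolution call set
        unchanged."""
        rng = np.random.default_rng(10)
        targets, records, pos = [], [], 0
        for i in range(30):
            pos += int(rng.integers(10, 60))
            end = pos + int(rng.integers(10, 50))
            t = ExonTarget(1 + i % 2, pos, end, f"t{i}")
            targets.append(t)
            records.append(CallRecord(t, (DEL, DUP, NOCALL)[int(rng.integers(0, 3))]))
            pos = end
        records.sort(key=lambda r: (r.target.chrom_index, r.target.start))
        targets.sort(key=lambda t: (t.chrom_index, t.start))
        segs = merge_segments(records)
        back = intersect_segments_to_exons(segs, targets)
        for r in records:
            if r.call != NOCALL:
                assert back[r.target.id] == r.call
            else:
                assert back[r.target.id] == NOCALL
        truth_calls = [TruthCall(s.chrom_index, s.start, s.end, call=s.call) for s in segs]
        for s in segs:
            assert consensus_truth_for_segment(s, truth_calls) == s.call


def test_segment_level_metrics_perfect_and_disjoint():
    segs = [SegmentCall(1, 0, 100, DEL, 2), SegmentCall(1, 200, 300, DUP, 1)]
    truth = [TruthCall(1, 0, 100, call=DEL), TruthCall(1, 200, 300, call=DUP)]
    rep = segment_level_metrics(segs, truth)
    assert rep.precision_overall == 1.0 and rep.recall_overall == 1.0
    rep2 = segment_level_metrics(segs, [TruthCall(2, 0, 100, call=DEL)])
    assert rep2.precision_overall == 0.0


def test_metrics_by_exon_length_partitions_exons():
    targets = [
        ExonTarget(1, 0, 100, "s1"), ExonTarget(1, 120, 190, "s2"),
        ExonTarget(1, 200, 1000, "l1"), ExonTarget(1, 1200, 2000, "l2"),
    ]
    pred = {"s1": DEL, "s2": DUP, "l1": DUP, "l2": DEL}
    rows = metrics_by_exon_length(pred, pred, targets, edges=(0, 150, 10_000))
    assert [r["n_exons"] for r in rows] == [2, 2]
    assert all(r["f1"] == 1.0 for r in rows)


def test_aggregation_from_per_class_values_uses_macro_means():
    rep = MetricsReport.from_per_class(
        precision_del=0.8, precision_dup=0.6, recall_del=0.5, recall_dup=0.3
    )
    assert rep.precision_overall == pytest.approx(0.7)
    assert rep.recall_overall == pytest.approx(0.4)
    assert rep.f1_del == pytest.approx(2 * 0.8 * 0.5 / 1.3)
    assert rep.f1_overall == pytest.approx(2 * 0.7 * 0.4 / 1.1)
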