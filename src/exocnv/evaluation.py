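"""Exon- and segment-resolution scoring of CNV call sets.

The unit of evaluation is the exon target.  Per-class precision is
TP/(TP+FP); per-class recall divides by the number of truth calls of that
class; "overall" values are unweighted (macro) means of the DEL and DUP
values, and overall F1 is the harmonic mean of overall precision and overall
recall.  NPA (specificity) and NPV use the one-vs-rest negatives of each
class, macro-averaged; the no-call exons of the sample's target list are the
negative universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .calling import SegmentCall
from .depth_io import DEL, DUP, NOCALL, ExonTarget, TruthCall

logger = logging.getLogger(__name__)


def discretize_copy_number(cn: int) -> str:
    """Integer copy number to class: >2 DUP, <2 DEL, ==2 NOCALL."""
    if cn < 0:
        raise ValueError("copy number must be >= 0")
    if cn > 2:
        return DUP
    if cn < 2:
        return DEL
    return NOCALL


def discretize_truth(truth_calls: Sequence[TruthCall]) -> list[TruthCall]:
    """Replace integer-copy-number truth records with DEL/DUP/NOCALL classes.

    Copy-number-2 records discretize to NOCALL and are dropped (no event).
    """
    out = []
    for c in truth_calls:
        if c.call is not None:
            out.append(c)
        else:
            label = discretize_copy_number(c.copy_number)
            if label != NOCALL:
                out.append(TruthCall(c.chrom_index, c.start, c.end, call=label))
    return out


@dataclass
class ConfusionTable:
    """Per-class exon counts; T_dup/T_del are truth totals."""

    TP_dup: int = 0
    FP_dup: int = 0
    FN_dup: int = 0
    TN_dup: int = 0
    TP_del: int = 0
    FP_del: int = 0
    FN_del: int = 0
    TN_del: int = 0

    @property
    def T_dup(self) -> int:
        return self.TP_dup + self.FN_dup

    @property
    def T_del(self) -> int:
        return self.TP_del + self.FN_del


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.warning("empty denominator for %s; reporting 0", what)
        return 0.0
    return num / den


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean, 0 whenever either input is 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def macro_mean(dup_value: float, del_value: float) -> float:
    return 0.5 * (dup_value + del_value)


@dataclass
class MetricsReport:
    """The full metric suite; see module docstring for definitions."""

    precision_del: float
    precision_dup: float
    precision_overall: float
    recall_del: float
    recall_dup: float
    recall_overall: float
    f1_del: float
    f1_dup: float
    f1_overall: float
    npa_del: float
    npa_dup: float
    npa_overall: float
    npv_del: float
    npv_dup: float
    npv_overall: float

    @classmethod
    def from_per_class(
        cls,
        precision_del: float,
        precision_dup: float,
        recall_del: float,
        recall_dup: float,
        npa_del: float = 0.0,
        npa_dup: float = 0.0,
        npv_del: float = 0.0,
        npv_dup: float = 0.0,
    ) -> "MetricsReport":
        """Aggregate a report from per-class precision/recall values.

        This is the single aggregation path: overall precision/recall are
        macro means, per-class F1 is the harmonic mean of that class's
        precision and recall, and overall F1 is the harmonic mean of the
        overall precision and overall recall.
        """
        p_over = macro_mean(precision_dup, precision_del)
        r_over = macro_mean(recall_dup, recall_del)
        return cls(
            precision_del=precision_del,
            precision_dup=precision_dup,
            precision_overall=p_over,
            recall_del=recall_del,
            recall_dup=recall_dup,
            recall_overall=r_over,
            f1_del=f1_score(precision_del, recall_del),
            f1_dup=f1_score(precision_dup, recall_dup),
            f1_overall=f1_score(p_over, r_over),
            npa_del=npa_del,
            npa_dup=npa_dup,
            npa_overall=macro_mean(npa_dup, npa_del),
            npv_del=npv_del,
            npv_dup=npv_dup,
            npv_overall=macro_mean(npv_dup, npv_del),
        )

    @property
    def macro_f1_events(self) -> float:
        """Unweighted mean of the DEL and DUP F1 scores."""
        return macro_mean(self.f1_dup, self.f1_del)

    def to_dict(self) -> dict[str, float]:
        return dict(self.__dict__)

    def summary(self) -> str:
        rows = [
            ("precision", self.precision_del, self.precision_dup, self.precision_overall),
            ("recall", self.recall_del, self.recall_dup, self.recall_overall),
            ("F1", self.f1_del, self.f1_dup, self.f1_overall),
            ("NPA", self.npa_del, self.npa_dup, self.npa_overall),
            ("NPV", self.npv_del, self.npv_dup, self.npv_overall),
        ]
        lines = [f"{'metric':<12}{'DEL':>8}{'DUP':>8}{'overall':>9}"]
        for name, d, u, o in rows:
            lines.append(f"{name:<12}{d:>8.3f}{u:>8.3f}{o:>9.3f}")
        return "\n".join(lines)


def compute_metrics(
    predicted_exon_calls: Mapping[str, str],
    truth_exon_calls: Mapping[str, str],
) -> tuple[ConfusionTable, MetricsReport]:
    """Score per-exon predictions against per-exon truth labels.

    Both mappings are exon id -> {DEL, DUP, NOCALL} over the same exon
    universe; a mismatch raises and names the missing exons.
    """
    missing = set(predicted_exon_calls) ^ set(truth_exon_calls)
    if missing:
        some = ", ".join(sorted(missing)[:5])
        raise ValueError(f"exon universe mismatch; first differing ids: {some}")
    ct = ConfusionTable()
    for exon_id, pred in predicted_exon_calls.items():
        truth = truth_exon_calls[exon_id]
        for cls_name, tp, fp, fn, tn in (
            (DUP, "TP_dup", "FP_dup", "FN_dup", "TN_dup"),
            (DEL, "TP_del", "FP_del", "FN_del", "TN_del"),
        ):
            if pred == cls_name and truth == cls_name:
                setattr(ct, tp, getattr(ct, tp) + 1)
            elif pred == cls_name:
                setattr(ct, fp, getattr(ct, fp) + 1)
            elif truth == cls_name:
                setattr(ct, fn, getattr(ct, fn) + 1)
            else:
                setattr(ct, tn, getattr(ct, tn) + 1)
    report = MetricsReport.from_per_class(
        precision_del=_safe_div(ct.TP_del, ct.TP_del + ct.FP_del, "DEL precision"),
        precision_dup=_safe_div(ct.TP_dup, ct.TP_dup + ct.FP_dup, "DUP precision"),
        recall_del=_safe_div(ct.TP_del, ct.T_del, "DEL recall"),
        recall_dup=_safe_div(ct.TP_dup, ct.T_dup, "DUP recall"),
        npa_del=_safe_div(ct.TN_del, ct.TN_del + ct.FP_del, "DEL NPA"),
        npa_dup=_safe_div(ct.TN_dup, ct.TN_dup + ct.FP_dup, "DUP NPA"),
        npv_del=_safe_div(ct.TN_del, ct.TN_del + ct.FN_del, "DEL NPV"),
        npv_dup=_safe_div(ct.TN_dup, ct.TN_dup + ct.FN_dup, "DUP NPV"),
    )
    return ct, report


# ---------------------------------------------------------------------------
# segment <-> exon resolution changes


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def _merge_same_call(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of intervals (merges overlapping same-call segments silently)."""
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(x) for x in merged]


def intersect_segments_to_exons(
    segments: Sequence[SegmentCall],
    targets: Sequence[ExonTarget],
) -> dict[str, str]:
    """Project segment calls onto exon targets (majority overlapped bases).

    An exon overlapping segments of both classes takes the class covering
    more of its bases; an exact tie, or no overlap, gives NOCALL.
    """
    per_class: dict[int, dict[str, list[tuple[int, int]]]] = {}
    for seg in segments:
        per_class.setdefault(seg.chrom_index, {DEL: [], DUP: []})[seg.call].append(
            (seg.start, seg.end)
        )
    conflicts = 0
    out: dict[str, str] = {}
    for t in targets:
        chrom = per_class.get(t.chrom_index, {DEL: [], DUP: []})
        cov = {}
        for cls_name in (DEL, DUP):
            cov[cls_name] = sum(
                _overlap(t.start, t.end, s, e) for s, e in _merge_same_call(chrom[cls_name])
            )
        if cov[DEL] > 0 and cov[DUP] > 0:
            conflicts += 1
        if cov[DEL] == cov[DUP]:
            out[t.id] = NOCALL
        else:
            out[t.id] = DEL if cov[DEL] > cov[DUP] else DUP
    if conflicts:
        logger.info("%d exon(s) overlapped segments of both classes", conflicts)
    return out


def consensus_truth_for_segment(
    segment: SegmentCall,
    truth_calls: Sequence[TruthCall],
) -> str:
    """Consensus truth label for a merged segment: most covered bases wins.

    Coverage per class is the union of that class's truth intervals clipped
    to the segment; no overlap or an exact tie gives NOCALL.
    """
    cov = {}
    for cls_name in (DEL, DUP):
        ivs = [
            (max(segment.start, c.start), min(segment.end, c.end))
            for c in truth_calls
            if c.call == cls_name
            and c.chrom_index == segment.chrom_index
            and _overlap(segment.start, segment.end, c.start, c.end) > 0
        ]
        cov[cls_name] = sum(e - s for s, e in _merge_same_call(ivs))
    if cov[DEL] == cov[DUP]:
        return NOCALL
    return DEL if cov[DEL] > cov[DUP] else DUP


def segment_level_metrics(
    segments: Sequence[SegmentCall],
    truth_calls: Sequence[TruthCall],
) -> MetricsReport:
    """Score merged call segments against truth intervals.

    Precision per class: predicted segments of that class whose consensus
    truth label (most covered bases) matches.  Recall per class: truth
    intervals of that class whose consensus predicted-segment label matches.
    NPA/NPV have no segment-level negative universe and are reported as 0.
    """
    pred_ok = {DEL: 0, DUP: 0}
    pred_n = {DEL: 0, DUP: 0}
    for seg in segments:
        pred_n[seg.call] += 1
        if consensus_truth_for_segment(seg, truth_calls) == seg.call:
            pred_ok[seg.call] += 1
    truth_ok = {DEL: 0, DUP: 0}
    truth_n = {DEL: 0, DUP: 0}
    pred_as_truth = [
        TruthCall(s.chrom_index, s.start, s.end, call=s.call) for s in segments
    ]
    for c in truth_calls:
        if c.call is None:
            continue
        truth_n[c.call] += 1
        pseudo = SegmentCall(c.chrom_index, c.start, c.end, c.call, 1)
        if consensus_truth_for_segment(pseudo, pred_as_truth) == c.call:
            truth_ok[c.call] += 1
    return MetricsReport.from_per_class(
        precision_del=_safe_div(pred_ok[DEL], pred_n[DEL], "segment DEL precision"),
        precision_dup=_safe_div(pred_ok[DUP], pred_n[DUP], "segment DUP precision"),
        recall_del=_safe_div(truth_ok[DEL], truth_n[DEL], "segment DEL recall"),
        recall_dup=_safe_div(truth_ok[DUP], truth_n[DUP], "segment DUP recall"),
    )


def metrics_by_exon_length(
    predicted_exon_calls: Mapping[str, str],
    truth_exon_calls: Mapping[str, str],
    targets: Sequence[ExonTarget],
    edges: Sequence[int] = (0, 200, 500, 1000, 4000, 10**9),
) -> list[dict]:
    """Macro precision/recall/F1 stratified by exon length (table rows)."""
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        ids = [t.id for t in targets if lo <= t.length < hi]
        if not ids:
            continue
        _, rep = compute_metrics(
            {i: predicted_exon_calls[i] for i in ids},
            {i: truth_exon_calls[i] for i in ids},
        )
        rows.append(
            dict(
                length_min=lo,
                length_max=hi,
                n_exons=len(ids),
                precision=rep.precision_overall,
                recall=rep.recall_overall,
                f1=rep.f1_overall,
            )
        )
    return rows
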