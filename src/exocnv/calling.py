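"""Per-sample CNV calling: model calls, nearest-neighbour imputation, merging.

Roughly a fifth of capture targets carry no read depth in a typical exome;
those exons receive the majority vote of the three genomically nearest exons
(interval midpoints, same chromosome) that have model calls.  Consecutive
same-call exons are then merged into CNV segments for segment-level
reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .depth_io import DEL, DUP, NOCALL, INT_TO_LABEL, EncodedExon, ExonTarget
from .encoder_model import ClassProbabilities, ModelState, predict_proba


@dataclass
class CallRecord:
    """One exon's call; imputed records carry no probabilities."""

    target: ExonTarget
    call: str
    probs: ClassProbabilities | None = None
    imputed: bool = False

    def __post_init__(self) -> None:
        if self.call not in (DEL, DUP, NOCALL):
            raise ValueError(f"invalid call token {self.call!r}")
        if self.imputed and self.probs is not None:
            raise ValueError("imputed records carry no probabilities")


@dataclass(frozen=True)
class SegmentCall:
    """A merged run of consecutive same-call exons."""

    chrom_index: int
    start: int
    end: int
    call: str
    n_exons: int

    def __post_init__(self) -> None:
        if self.call not in (DEL, DUP):
            raise ValueError("segments carry DEL or DUP only")
        if not (self.start < self.end and self.n_exons >= 1):
            raise ValueError("invalid segment")


def _sort_key(t: ExonTarget):
    return (t.chrom_index, t.start, t.end)


def call_sample(
    model_state: ModelState,
    encoded_exons: list[EncodedExon],
    min_call_prob: float | None = None,
    batch_size: int = 256,
) -> list[CallRecord]:
    """Model calls for every encodable exon, sorted by genomic position.

    Encodings must carry the model's own standardization statistics
    (checked via the stats hash embedded at encode time).
    """
    if not encoded_exons:
        return []
    if model_state.stats is not None:
        want = model_state.stats.key
        for e in encoded_exons:
            if e.stats_key and e.stats_key != want:
                raise ValueError(
                    f"standardization stats mismatch for exon {e.target.id}: "
                    "re-encode with the model's stats"
                )
    probs = predict_proba(model_state, encoded_exons, batch_size=batch_size)
    records = []
    for e, pr in zip(encoded_exons, probs):
        cp = ClassProbabilities(float(pr[0]), float(pr[1]), float(pr[2]))
        label = INT_TO_LABEL[int(np.argmax(pr))]
        if min_call_prob is not None and label in (DEL, DUP) and pr.max() < min_call_prob:
            label = NOCALL
        records.append(CallRecord(target=e.target, call=label, probs=cp))
    records.sort(key=lambda r: _sort_key(r.target))
    return records


def majority_vote(calls: Sequence[str]) -> str:
    """Majority call among neighbour predictions; any tie resolves to NOCALL."""
    if not calls:
        return NOCALL
    counts = {c: 0 for c in (DEL, DUP, NOCALL)}
    for c in calls:
        counts[c] += 1
    best = max(counts.values())
    winners = [c for c, n in counts.items() if n == best]
    return winners[0] if len(winners) == 1 else NOCALL


def impute_no_depth_exons(
    call_records: list[CallRecord],
    no_depth_targets: Sequence[ExonTarget],
) -> list[CallRecord]:
    """Augment model calls with 3-nearest-neighbour votes for depth-less exons.

    Neighbours are the (up to) 3 model-called exons on the same chromosome
    nearest by interval-midpoint distance, distance ties broken toward the
    lower start coordinate.  Existing records are never modified; the result
    is the sorted union.
    """
    called = list(call_records)
    by_chrom: dict[int, list[CallRecord]] = {}
    for r in called:
        by_chrom.setdefault(r.target.chrom_index, []).append(r)
    for ch in by_chrom:
        by_chrom[ch].sort(key=lambda r: _sort_key(r.target))

    imputed: list[CallRecord] = []
    for t in no_depth_targets:
        cands = by_chrom.get(t.chrom_index, [])
        if not cands:
            imputed.append(CallRecord(target=t, call=NOCALL, imputed=True))
            continue
        mids = np.array([c.target.midpoint for c in cands])
        starts = np.array([c.target.start for c in cands])
        dist = np.abs(mids - t.midpoint)
        order = np.lexsort((starts, dist))[:3]
        vote = majority_vote([cands[i].call for i in order])
        imputed.append(CallRecord(target=t, call=vote, imputed=True))
    out = called + imputed
    out.sort(key=lambda r: _sort_key(r.target))
    return out


def merge_segments(
    call_records: Sequence[CallRecord],
    gap_cap: int | None = None,
) -> list[SegmentCall]:
    """Merge maximal runs of consecutive same-call exons into segments.

    Adjacency means consecutive position in the sorted exon list on one
    chromosome; NOCALL exons break runs and emit nothing.  ``gap_cap``
    optionally also breaks a run when the genomic gap between consecutive
    exons exceeds the cap.
    """
    keys = [_sort_key(r.target) for r in call_records]
    if keys != sorted(keys):
        raise ValueError("call records must be sorted by (chromosome, start)")
    segments: list[SegmentCall] = []
    run: list[CallRecord] = []

    def _flush():
        if run:
            segments.append(
                SegmentCall(
                    chrom_index=run[0].target.chrom_index,
                    start=run[0].target.start,
                    end=run[-1].target.end,
                    call=run[0].call,
                    n_exons=len(run),
                )
            )
            run.clear()

    for r in call_records:
        if r.call == NOCALL:
            _flush()
            continue
        if run and (
            r.target.chrom_index != run[0].target.chrom_index
            or r.call != run[0].call
            or (gap_cap is not None and r.target.start - run[-1].target.end > gap_cap)
        ):
            _flush()
        run.append(r)
    _flush()
    return segments
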