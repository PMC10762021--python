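"""Synthetic whole-exome read-depth generator with implanted CNVs.

Emits the three files the pipeline consumes — exon targets (BED), a per-base
depth table (TSV) and a truth call set (BED) — so that training, calling and
evaluation are exercised end to end without external sequencing data.

Depth is modelled per base as an overdispersed count: a gamma-distributed
latent rate (negative-binomial marginal, dispersion ``r``; Poisson in the
``r -> inf`` limit) around a per-exon mean of ``base_coverage`` times the
copy-state multiplier, with optional short-range smoothing of the latent
rate so that event boundaries show as sharp steps rather than white noise.
Deletions and duplications initiate per exon with configured probabilities
and span a geometric number of consecutive exons; heterozygous events scale
depth by 0.5 / 1.5 and a configurable fraction are homozygous (0.0 / 2.0).
A fraction of exons (default 0.2, a typical exome share) is emitted with no
depth rows at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .depth_io import (
    DEL,
    DUP,
    NOCALL,
    ExonTarget,
    TruthCall,
    chrom_index_to_name,
)


@dataclass(frozen=True)
class SimulationParams:
    """Generator settings; defaults emulate a ~50x germline exome."""

    n_chromosomes: int = 2
    exons_per_chromosome: int = 1000
    exon_len_log_mean: float = 5.0  # log-normal, median ~150 bp
    exon_len_log_sd: float = 0.35
    exon_len_min: int = 50
    exon_len_max: int = 4000
    gap_log_mean: float = 7.6  # intergap median ~2 kb
    gap_log_sd: float = 0.8
    gap_min: int = 200
    chrom_offset: int = 20_000  # first target start; keeps coordinates >= 14.6 kb
    base_coverage: float = 50.0
    dispersion: float = 10.0  # NB size parameter; larger = closer to Poisson
    smoothing_window: int = 5  # latent-rate moving average; 1 disables
    del_rate: float = 0.05
    dup_rate: float = 0.05
    event_span_p: float = 0.5  # geometric success prob; mean span = 1/p exons
    partial_boundary_fraction: float = 0.5  # chance a breakpoint falls inside its boundary exon
    del_multiplier: float = 0.5
    dup_multiplier: float = 1.5
    hom_fraction: float = 0.1  # fraction of events that are homozygous
    hom_del_multiplier: float = 0.0
    hom_dup_multiplier: float = 2.0
    no_depth_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("del_rate", "dup_rate", "hom_fraction", "no_depth_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("del_multiplier", "dup_multiplier", "hom_del_multiplier", "hom_dup_multiplier"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (self.base_coverage > 0 and self.dispersion > 0):
            raise ValueError("base_coverage and dispersion must be > 0")
        if not 0 < self.event_span_p <= 1:
            raise ValueError("event_span_p must be in (0, 1]")
        if not 1 <= self.n_chromosomes <= 24:
            raise ValueError("n_chromosomes must be in 1..24")


@dataclass
class SimulatedSample:
    """Targets, per-base depth table, truth intervals and per-exon labels."""

    targets: list[ExonTarget]
    depth_table: pd.DataFrame
    truth_calls: list[TruthCall]
    labels: dict[str, str]
    multipliers: dict[str, float] = field(default_factory=dict)


def _simulate_targets(params: SimulationParams, rng: np.random.Generator) -> list[ExonTarget]:
    targets = []
    for ci in range(1, params.n_chromosomes + 1):
        pos = params.chrom_offset
        for k in range(params.exons_per_chromosome):
            length = int(
                np.clip(
                    np.round(rng.lognormal(params.exon_len_log_mean, params.exon_len_log_sd)),
                    params.exon_len_min,
                    params.exon_len_max,
                )
            )
            t = ExonTarget(ci, pos, pos + length, f"{chrom_index_to_name(ci)}_e{k:05d}")
            targets.append(t)
            gap = int(max(params.gap_min, np.round(rng.lognormal(params.gap_log_mean, params.gap_log_sd))))
            pos += length + gap
    return targets


@dataclass(frozen=True)
class CNVEvent:
    """One implanted event: genomic interval, class, depth multiplier."""

    chrom_index: int
    start: int
    end: int
    call: str
    mult: float
    exon_ids: tuple[str, ...]


def _place_events(
    params: SimulationParams,
    targets: Sequence[ExonTarget],
    rng: np.random.Generator,
    del_rate: float | None = None,
    dup_rate: float | None = None,
    blocked: frozenset[str] = frozenset(),
) -> list[CNVEvent]:
    """Implant events scanning exons in order.

    An event spans a geometric number of consecutive exons; each of its two
    breakpoints falls strictly inside the boundary exon (uniform position)
    with probability ``partial_boundary_fraction``, else on the exon edge —
    real CNV breakpoints do not respect capture-probe boundaries, and the
    resulting intra-exon depth steps are what the classifier and the
    explainer must key on.  Events touching a ``blocked`` exon are dropped
    (used to keep cohort-shared and private events disjoint).
    """
    del_rate = params.del_rate if del_rate is None else del_rate
    dup_rate = params.dup_rate if dup_rate is None else dup_rate
    events: list[CNVEvent] = []
    by_chrom: dict[int, list[ExonTarget]] = {}
    for t in targets:
        by_chrom.setdefault(t.chrom_index, []).append(t)
    for ci, chrom_targets in by_chrom.items():
        i = 0
        n = len(chrom_targets)
        while i < n:
            u = rng.random()
            if u >= del_rate + dup_rate:
                i += 1
                continue
            label = DEL if u < del_rate else DUP
            span = int(rng.geometric(params.event_span_p))
            hom = rng.random() < params.hom_fraction
            if label == DEL:
                mult = params.hom_del_multiplier if hom else params.del_multiplier
            else:
                mult = params.hom_dup_multiplier if hom else params.dup_multiplier
            first = chrom_targets[i]
            last = chrom_targets[min(i + span - 1, n - 1)]
            gstart = first.start
            if rng.random() < params.partial_boundary_fraction:
                gstart = int(first.start + rng.integers(0, first.length - 1))
            gend = last.end
            if rng.random() < params.partial_boundary_fraction:
                gend = int(rng.integers(max(gstart + 1, last.start + 1), last.end + 1))
            ids = tuple(t.id for t in chrom_targets[i : min(i + span, n)])
            if not (blocked and any(x in blocked for x in ids)):
                events.append(CNVEvent(ci, gstart, gend, label, mult, ids))
            i += span
    return events


def _exon_mean(t: ExonTarget, events: dict[str, CNVEvent], base: float) -> np.ndarray:
    """Per-base expected depth for one exon under its (optional) event."""
    mean = np.full(t.length, base, dtype=np.float64)
    ev = events.get(t.id)
    if ev is not None:
        lo = max(t.start, ev.start) - t.start
        hi = min(t.end, ev.end) - t.start
        if hi > lo:
            mean[lo:hi] *= ev.mult
    return mean


def _exon_depth(
    mean: np.ndarray,
    params: SimulationParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Overdispersed per-base counts around ``mean`` with smoothed latent rate."""
    r = params.dispersion
    lam = np.where(mean > 0, rng.gamma(shape=r, scale=np.maximum(mean, 1e-12) / r), 0.0)
    w = params.smoothing_window
    if w > 1:
        kernel = np.ones(w) / w
        lam = np.convolve(np.pad(lam, (w // 2, w - 1 - w // 2), mode="edge"), kernel, mode="valid")
    return rng.poisson(lam).astype(np.int64)


def simulate_sample(
    params: SimulationParams,
    targets: Sequence[ExonTarget] | None = None,
    seed: int | None = None,
    shared_events: Sequence[CNVEvent] | None = None,
    del_rate: float | None = None,
    dup_rate: float | None = None,
) -> SimulatedSample:
    """Generate one sample; fully reproducible from the seed.

    RNG consumption order is fixed: target layout (when not supplied), event
    placement in sorted target order, no-depth selection, then per-base
    depth exon by exon in sorted order.  Per-exon truth labels are derived
    from the event intervals with the same majority-base rule used for real
    truth sets, so label/interval consistency holds by construction.
    """
    from .training import assign_exon_labels

    rng = np.random.default_rng(params.seed if seed is None else seed)
    if targets is None:
        targets = _simulate_targets(params, rng)
    blocked = frozenset()
    if shared_events:
        blocked = frozenset(x for ev in shared_events for x in ev.exon_ids)
    events = _place_events(
        params, targets, rng, del_rate=del_rate, dup_rate=dup_rate, blocked=blocked
    )
    if shared_events:
        events = sorted(
            list(events) + list(shared_events), key=lambda e: (e.chrom_index, e.start)
        )
    ev_by_exon = {x: ev for ev in events for x in ev.exon_ids}
    no_depth_ids = set()
    if params.no_depth_fraction > 0:
        drop = rng.random(len(targets)) < params.no_depth_fraction
        no_depth_ids = {t.id for t, d in zip(targets, drop) if d}

    chroms, positions, depths = [], [], []
    for t in targets:
        if t.id in no_depth_ids:
            continue
        vec = _exon_depth(_exon_mean(t, ev_by_exon, params.base_coverage), params, rng)
        chroms.append(np.full(t.length, t.chrom_index, dtype=np.int64))
        positions.append(np.arange(t.start + 1, t.end + 1, dtype=np.int64))  # 1-based
        depths.append(vec)
    if chroms:
        depth_table = pd.DataFrame(
            {
                "chrom": [chrom_index_to_name(int(c)) for c in np.concatenate(chroms)],
                "pos": np.concatenate(positions),
                "depth": np.concatenate(depths),
            }
        )
    else:
        depth_table = pd.DataFrame(columns=["chrom", "pos", "depth"])

    truth = [TruthCall(e.chrom_index, e.start, e.end, call=e.call) for e in events]
    truth.sort(key=lambda c: (c.chrom_index, c.start, c.end))
    labels = dict(zip([t.id for t in targets], assign_exon_labels(targets, truth)))
    mults = {
        t.id: (ev_by_exon[t.id].mult if t.id in ev_by_exon else 1.0) for t in targets
    }
    return SimulatedSample(
        targets=list(targets),
        depth_table=depth_table,
        truth_calls=truth,
        labels=labels,
        multipliers=mults,
    )


def simulate_cohort(
    params: SimulationParams,
    n_samples: int,
    shared_fraction: float = 0.0,
    del_rate: float | None = None,
    dup_rate: float | None = None,
) -> tuple[list[SimulatedSample], list[ExonTarget]]:
    """Samples sharing one capture design, independent events per sample.

    ``shared_fraction`` routes that fraction of the event rate into a common
    event layout present in every sample; the remainder is private.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if not 0.0 <= shared_fraction <= 1.0:
        raise ValueError("shared_fraction must be in [0, 1]")
    if n_samples == 1 and shared_fraction == 0.0:
        # a one-sample cohort is exactly one sample
        sample = simulate_sample(params, del_rate=del_rate, dup_rate=dup_rate)
        return [sample], sample.targets
    root = np.random.SeedSequence(params.seed)
    design_seed, shared_seed, *sample_seeds = [
        int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(n_samples + 2)
    ]
    rng = np.random.default_rng(design_seed)
    targets = _simulate_targets(params, rng)
    d_rate = params.del_rate if del_rate is None else del_rate
    u_rate = params.dup_rate if dup_rate is None else dup_rate
    shared_events: list[CNVEvent] | None = None
    if shared_fraction > 0:
        shared_events = _place_events(
            params,
            targets,
            np.random.default_rng(shared_seed),
            del_rate=d_rate * shared_fraction,
            dup_rate=u_rate * shared_fraction,
        )
    samples = [
        simulate_sample(
            params,
            targets=targets,
            seed=s,
            shared_events=shared_events,
            del_rate=d_rate * (1.0 - shared_fraction),
            dup_rate=u_rate * (1.0 - shared_fraction),
        )
        for s in sample_seeds
    ]
    return samples, targets
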