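"""Training and fine-tuning of the per-exon classifier.

Training minimises three-class cross-entropy with Adam, a cosine-annealed
learning rate starting at 5e-5, and Xavier-initialised weights.  The quoted
convergence epoch counts of the original regimes are treated as fixed epoch
budgets so that runs are reproducible.  Fine-tuning is ordinary continued
training from a trained state on a small labeled set (expert-curated,
independent call set, or somatic regimes), with provenance of the base state
recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _nn
from .depth_io import (
    DEL,
    DUP,
    NOCALL,
    LABEL_TO_INT,
    EncodedExon,
    ExonTarget,
    TruthCall,
)
from .encoder_model import ModelState, backward_batch, forward_batch, stack_encoded


@dataclass
class TrainConfig:
    """Optimisation settings; defaults follow the published training regime."""

    lr_initial: float = 5e-5
    epochs: int = 4
    batch_size: int = 256
    seed: int = 0
    class_weights: Sequence[float] | None = None
    nocall_subsample: float | None = None  # keep-fraction of NOCALL exons, off by default

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not self.lr_initial > 0 and self.lr_initial != 0.0:
            raise ValueError("lr_initial must be >= 0")
        if self.class_weights is not None and not all(w > 0 for w in self.class_weights):
            raise ValueError("class_weights must be positive")


@dataclass
class LabeledExonSet:
    """Encoded exons with one truth label each (DEL/DUP/NOCALL)."""

    encoded: list[EncodedExon]
    labels: np.ndarray  # int codes, DEL=0 DUP=1 NOCALL=2

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.encoded) != self.labels.shape[0]:
            raise ValueError("one label per exon required")
        if self.labels.size and not np.all((self.labels >= 0) & (self.labels <= 2)):
            raise ValueError("invalid label codes")

    def __len__(self) -> int:
        return len(self.encoded)

    @classmethod
    def from_label_strings(cls, encoded: list[EncodedExon], labels: Sequence[str]) -> "LabeledExonSet":
        return cls(encoded, np.array([LABEL_TO_INT[l] for l in labels], dtype=np.int64))


def assign_exon_labels(
    targets: Sequence[ExonTarget],
    truth_calls: Sequence[TruthCall],
) -> list[str]:
    """Per-exon truth label by majority overlapped bases.

    An exon overlapping one or more truth intervals takes the class covering
    the most of its bases; no overlap or an exact base tie gives NOCALL.
    Integer-copy-number truth records must be discretized first
    (``evaluation.discretize_copy_number``).
    """
    by_chrom: dict[int, list[TruthCall]] = {}
    for c in truth_calls:
        if c.call is None:
            raise ValueError("integer copy-number truth must be discretized before labeling")
        by_chrom.setdefault(c.chrom_index, []).append(c)
    labels = []
    for t in targets:
        cov = {DEL: 0, DUP: 0}
        for c in by_chrom.get(t.chrom_index, ()):
            ov = min(t.end, c.end) - max(t.start, c.start)
            if ov > 0:
                cov[c.call] += ov
        if cov[DEL] == cov[DUP]:  # includes the no-overlap case (0 == 0)
            labels.append(NOCALL)
        elif cov[DEL] > cov[DUP]:
            labels.append(DEL)
        else:
            labels.append(DUP)
    return labels


def _epoch_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i : i + batch_size]


def train(
    model_state_init: ModelState,
    labeled_set: LabeledExonSet,
    train_config: TrainConfig,
) -> tuple[ModelState, list[float]]:
    """Train from ``model_state_init``; returns (trained state, per-epoch loss).

    Deterministic given the config seed and a fixed BLAS thread setup: data
    order, subsampling and every weight update flow from one Generator.
    """
    cfg = train_config
    state = model_state_init.copy()
    rng = np.random.default_rng(cfg.seed)
    enc, labels = labeled_set.encoded, labeled_set.labels
    if cfg.nocall_subsample is not None:
        keep = (labels != LABEL_TO_INT[NOCALL]) | (rng.random(labels.shape[0]) < cfg.nocall_subsample)
        enc = [e for e, k in zip(enc, keep) if k]
        labels = labels[keep]
    if len(enc) == 0:
        raise ValueError("empty training set")
    stacked = stack_encoded(enc)
    opt = _nn.Adam(lr=cfg.lr_initial)
    trace: list[float] = []
    for epoch in range(cfg.epochs):
        lr = _nn.cosine_lr(cfg.lr_initial, epoch, cfg.epochs)
        losses = []
        for idx in _epoch_batches(len(enc), cfg.batch_size, rng):
            batch = {k: v[idx] for k, v in stacked.items()}
            logits, cache = forward_batch(state, batch, need_cache=True)
            loss, dlogits = _nn.cross_entropy(logits, labels[idx], cfg.class_weights)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch starting at {idx[0]}"
                )
            grads, _ = backward_batch(state, cache, dlogits)
            opt.step(state.params, grads, lr=lr)
            losses.append(loss)
        trace.append(float(np.mean(losses)))
    state.provenance = dict(
        state.provenance,
        trained=dict(
            epochs=cfg.epochs,
            lr_initial=cfg.lr_initial,
            batch_size=cfg.batch_size,
            seed=cfg.seed,
            n_exons=len(enc),
            final_loss=trace[-1],
        ),
    )
    return state, trace


def finetune(
    base_state: ModelState,
    small_labeled_set: LabeledExonSet,
    train_config: TrainConfig,
) -> tuple[ModelState, list[float]]:
    """Continue training a trained state on a small labeled set.

    The returned state records the base parameters' hash and the fine-tune
    config in its provenance.
    """
    if len(small_labeled_set) == 0:
        raise ValueError("fine-tuning set is empty")
    if small_labeled_set.encoded[0].depth.shape[0] != base_state.config.max_len:
        raise ValueError("architecture mismatch: encoded length != model max_len")
    base_hash = base_state.params_hash()
    tuned, trace = train(base_state, small_labeled_set, train_config)
    tuned.provenance["finetuned_from"] = base_hash
    return tuned, trace
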