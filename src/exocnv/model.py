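"""High-level modelling API: a model object fitted to labeled exon data.

``ExonCNVModel`` bundles the encoded training data with the architecture
and optimisation settings; ``fit()`` returns an ``ExonCNVResults`` object
that carries the trained parameter state, the loss trace and diagnostics,
and exposes prediction, calling, fine-tuning, explanation and persistence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .calling import CallRecord, SegmentCall, call_sample, impute_no_depth_exons, merge_segments
from .depth_io import (
    EncodedExon,
    ExonTarget,
    INT_TO_LABEL,
    StandardizationStats,
)
from .encoder_model import (
    ModelConfig,
    ModelState,
    init_state,
    load_model,
    predict_proba,
    save_model,
)
from .evaluation import MetricsReport, compute_metrics
from .explain import RelevanceMap, relevance_map
from .training import LabeledExonSet, TrainConfig, finetune, train


class ExonCNVModel:
    """Three-class per-exon CNV classifier specification bound to data.

    Parameters
    ----------
    labeled_set
        Encoded exons with DEL/DUP/NOCALL labels (the training data).
    config
        Architecture hyperparameters; defaults are the full-scale model
        (H=192, L=3, 8 heads, max_len=1000).
    stats
        Standardization statistics of the training corpus; persisted with
        the fitted state and enforced at call time.
    """

    def __init__(
        self,
        labeled_set: LabeledExonSet,
        config: ModelConfig | None = None,
        stats: StandardizationStats | None = None,
    ) -> None:
        self.labeled_set = labeled_set
        self.config = config or ModelConfig()
        self.stats = stats

    @classmethod
    def from_simulation(cls, sample, stats, config=None, max_len=None):
        """Build a model from a :class:`~exocnv.simulation.SimulatedSample`."""
        from .depth_io import encode_sample

        config = config or ModelConfig()
        encoded, _ = encode_sample(
            sample.depth_table, sample.targets, stats, max_len=config.max_len
        )
        labels = [sample.labels[e.target.id] for e in encoded]
        return cls(LabeledExonSet.from_label_strings(encoded, labels), config, stats)

    def fit(
        self,
        train_config: TrainConfig | None = None,
        start_state: ModelState | None = None,
    ) -> "ExonCNVResults":
        """Train (or continue training) and return a results object."""
        cfg = train_config or TrainConfig()
        if start_state is None:
            state = init_state(self.config, seed=cfg.seed, stats=self.stats)
            trained, trace = train(state, self.labeled_set, cfg)
        else:
            trained, trace = finetune(start_state, self.labeled_set, cfg)
        return ExonCNVResults(model=self, state=trained, loss_trace=trace, train_config=cfg)


@dataclass
class ExonCNVResults:
    """A fitted per-exon CNV classifier with its training diagnostics."""

    model: ExonCNVModel
    state: ModelState
    loss_trace: list[float]
    train_config: TrainConfig

    # -- prediction ---------------------------------------------------------
    def predict_proba(self, encoded: list[EncodedExon]) -> np.ndarray:
        """(N, 3) probabilities over [DEL, DUP, NOCALL]."""
        return predict_proba(self.state, encoded)

    def predict(self, encoded: list[EncodedExon]) -> list[str]:
        p = self.predict_proba(encoded)
        return [INT_TO_LABEL[i] for i in np.argmax(p, axis=1)]

    def call(
        self,
        encoded: list[EncodedExon],
        no_depth_targets: Sequence[ExonTarget] = (),
        min_call_prob: float | None = None,
        impute: bool = True,
    ) -> list[CallRecord]:
        """Full calling pipeline: model calls + 3-NN imputation."""
        records = call_sample(self.state, encoded, min_call_prob=min_call_prob)
        if impute and len(no_depth_targets):
            records = impute_no_depth_exons(records, no_depth_targets)
        return records

    def segments(self, call_records: Sequence[CallRecord], gap_cap=None) -> list[SegmentCall]:
        return merge_segments(call_records, gap_cap=gap_cap)

    def explain(self, encoded_exon: EncodedExon, target_class: str | None = None) -> RelevanceMap:
        return relevance_map(self.state, encoded_exon, target_class)

    # -- evaluation ---------------------------------------------------------
    def score(
        self,
        encoded: list[EncodedExon],
        truth_labels: Sequence[str],
    ) -> MetricsReport:
        """Metric suite of direct model calls against per-exon truth labels."""
        pred = self.predict(encoded)
        ids = [e.target.id for e in encoded]
        _, report = compute_metrics(dict(zip(ids, pred)), dict(zip(ids, truth_labels)))
        return report

    def finetune(
        self,
        labeled_set: LabeledExonSet,
        train_config: TrainConfig | None = None,
    ) -> "ExonCNVResults":
        """Continue training on a small labeled set (returns new results)."""
        cfg = train_config or TrainConfig(epochs=11)
        tuned, trace = finetune(self.state, labeled_set, cfg)
        sub = ExonCNVModel(labeled_set, self.model.config, self.model.stats)
        return ExonCNVResults(model=sub, state=tuned, loss_trace=trace, train_config=cfg)

    # -- reporting / persistence -------------------------------------------
    def summary(self) -> str:
        cfg = self.state.config
        lines = [
            "Per-exon CNV transformer classifier",
            "=" * 43,
            f"{'embedding width H':<28}{cfg.H}",
            f"{'encoder blocks L':<28}{cfg.L}",
            f"{'attention heads':<28}{cfg.heads}",
            f"{'max exon length':<28}{cfg.max_len}",
            f"{'parameters':<28}{self.state.n_parameters()}",
            f"{'training exons':<28}{len(self.model.labeled_set)}",
            f"{'epochs':<28}{self.train_config.epochs}",
            f"{'initial learning rate':<28}{self.train_config.lr_initial:g}",
            f"{'final epoch loss':<28}{self.loss_trace[-1]:.4f}",
            f"{'parameter hash':<28}{self.state.params_hash()}",
        ]
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        save_model(self.state, path)

    @staticmethod
    def load_state(path: str | Path) -> ModelState:
        return load_model(path)
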