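"""Shared fixtures.

BLAS thread pools are pinned to one thread before numpy loads so that
floating-point reduction order — and therefore every trained parameter and
metric — is identical on any host.
"""

import os

for _var in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS",
             "NUMEXPR_NUM_THREADS", "VECLIB_MAXIMUM_THREADS"):
    os.environ.setdefault(_var, "1")

import numpy as np
import pytest

from exocnv.depth_io import (
    EncodedExon,
    ExonTarget,
    StandardizationStats,
    compute_standardization_stats,
    encode_sample,
    extract_depth_vectors,
)
from exocnv.encoder_model import ModelConfig, init_state
from exocnv.simulation import SimulationParams, simulate_cohort
from exocnv.training import LabeledExonSet, TrainConfig, train

# ---------------------------------------------------------------------------
# tiny architecture for fast unit tests


@pytest.fixture
def tiny_config():
    return ModelConfig(H=8, L=2, heads=2, max_len=16, mlp_hidden=12)


@pytest.fixture
def tiny_state(tiny_config):
    return init_state(tiny_config, seed=3, stats=StandardizationStats(mean=50.0, sd=25.0))


@pytest.fixture
def stats50():
    return StandardizationStats(mean=50.0, sd=25.0)


def make_encoded(rng, max_len, n_real=None, chrom=1, start=100_000, id_="e0", stats=None):
    """Random standardized EncodedExon for model-level tests."""
    if n_real is None:
        n_real = int(rng.integers(2, max_len + 1))
    depth = np.full(max_len, -1.0, dtype=np.float32)
    depth[max_len - n_real :] = rng.normal(size=n_real).astype(np.float32)
    mask = np.zeros(max_len, dtype=bool)
    mask[max_len - n_real :] = True
    target = ExonTarget(chrom, start, start + n_real, id_)
    return EncodedExon(
        depth=depth, mask=mask, target=target, n_real=n_real,
        stats_key="" if stats is None else stats.key,
    )


@pytest.fixture
def encoded_factory():
    return make_encoded


# ---------------------------------------------------------------------------
# the desk-scale study conditions: cohort, standardization, trained base model.
# Session-scoped because training takes minutes and several test modules
# (acceptance, fine-tuning) share it.

DESK_SIM = dict(
    n_chromosomes=2,
    exons_per_chromosome=1000,
    base_coverage=50.0,
    del_multiplier=0.5,
    dup_multiplier=1.5,
    dispersion=10.0,
    del_rate=0.05,
    dup_rate=0.05,
    exon_len_log_mean=4.8,
    exon_len_log_sd=0.3,
    exon_len_min=60,
    exon_len_max=200,
)
DESK_MODEL = dict(H=32, L=2, heads=4, max_len=200)
DESK_TRAIN = dict(lr_initial=1e-3, epochs=15, batch_size=32, seed=7)
DESK_FINETUNE = dict(lr_initial=5e-4, epochs=5, batch_size=16, seed=7)


class DeskBundle:
    """Everything the desk-scale experiments share."""

    def __init__(self):
        params = SimulationParams(seed=7, **DESK_SIM)
        (self.train_sample, self.test_sample), self.targets = simulate_cohort(params, 2)
        vectors, _ = extract_depth_vectors(self.train_sample.depth_table, self.targets)
        self.stats = compute_standardization_stats(vectors)
        self.config = ModelConfig(**DESK_MODEL)
        self.enc_train, self.left_train = encode_sample(
            self.train_sample.depth_table, self.targets, self.stats, max_len=self.config.max_len
        )
        self.enc_test, self.left_test = encode_sample(
            self.test_sample.depth_table, self.targets, self.stats, max_len=self.config.max_len
        )
        labeled = LabeledExonSet.from_label_strings(
            self.enc_train, [self.train_sample.labels[e.target.id] for e in self.enc_train]
        )
        self.base_state, self.loss_trace = train(
            init_state(self.config, seed=7, stats=self.stats),
            labeled,
            TrainConfig(**DESK_TRAIN),
        )


@pytest.fixture(scope="session")
def desk_bundle():
    return DeskBundle()
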