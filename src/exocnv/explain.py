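"""Per-base relevance maps for individual calls.

Implements gradient-weighted attention relevance propagation for the exact
softmax attention backend: for each encoder block, the attention map is
weighted elementwise by its gradient with respect to the target-class
score, negative contributions are clipped, heads are averaged after
weighting (a plain head average is known to produce noisy maps), and the
per-block maps are accumulated through a running relevance matrix
``R <- R + A_bar @ R`` initialised to the identity.  The classification
token's row of ``R`` over the depth columns is the per-base relevance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .depth_io import LABEL_TO_INT, INT_TO_LABEL, EncodedExon
from .encoder_model import ModelState, backward_batch, forward_batch, stack_encoded


@dataclass
class RelevanceMap:
    """Nonnegative, max-normalised per-position scores for one exon."""

    scores: np.ndarray  # length max_len, aligned to the encoded depth vector
    predicted_call: str
    target_call: str
    degenerate: bool = False  # all-zero map (constant-output model)

    def __post_init__(self) -> None:
        if np.any(self.scores < 0):
            raise ValueError("relevance scores must be nonnegative")


def relevance_map(
    model_state: ModelState,
    encoded_exon: EncodedExon,
    target_class: str | None = None,
) -> RelevanceMap:
    """Relevance of each depth position for the (target) class score.

    ``target_class`` defaults to the model's own prediction.  Padded
    positions always score exactly 0; when any signal is present the map is
    normalised so its maximum is 1.
    """
    batch = stack_encoded([encoded_exon])
    logits, cache = forward_batch(model_state, batch, need_cache=True)
    pred_idx = int(np.argmax(logits[0]))
    predicted = INT_TO_LABEL[pred_idx]
    target = predicted if target_class is None else target_class
    tgt_idx = LABEL_TO_INT[target]

    # gradient of the target-class logit
    dlogits = np.zeros_like(logits)
    dlogits[0, tgt_idx] = 1.0
    _, attn = backward_batch(model_state, cache, dlogits, capture_attention=True)

    T = model_state.config.max_len + 1
    R = np.eye(T, dtype=np.float64)
    for P, dP in attn:  # blocks in forward order
        weighted = np.maximum(P[0].astype(np.float64) * dP[0].astype(np.float64), 0.0)
        A_bar = weighted.mean(axis=0)  # head-average after gradient weighting
        R = R + A_bar @ R

    scores = np.maximum(R[0, 1:].copy(), 0.0)  # token row over depth columns
    scores[~encoded_exon.mask] = 0.0
    peak = scores.max()
    degenerate = not peak > 0
    if not degenerate:
        scores = scores / peak
    return RelevanceMap(
        scores=scores, predicted_call=predicted, target_call=target, degenerate=degenerate
    )


def write_relevance_tsv(rmap: RelevanceMap, encoded_exon: EncodedExon, sink) -> None:
    """Per-position TSV: offset in the exon, standardized depth, relevance."""
    import pandas as pd

    m = encoded_exon.mask
    pd.DataFrame(
        {
            "offset": np.arange(int(m.sum())),
            "depth_std": encoded_exon.depth[m],
            "relevance": rmap.scores[m],
        }
    ).to_csv(sink, sep="\t", index=False)


def plot_relevance(rmap: RelevanceMap, encoded_exon: EncodedExon, path) -> None:
    """Read-depth trace with a relevance heat track underneath (PNG/SVG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    m = encoded_exon.mask
    depth = encoded_exon.depth[m]
    rel = rmap.scores[m]
    fig, ax = plt.subplots(figsize=(8, 3))
    x = np.arange(depth.size)
    ax.imshow(
        rel[None, :],
        aspect="auto",
        cmap="inferno",
        alpha=0.8,
        extent=(0, depth.size, float(depth.min()), float(depth.max())),
    )
    ax.plot(x, depth, color="w", lw=1.2)
    ax.set_xlabel("base offset in exon")
    ax.set_ylabel("standardized depth")
    ax.set_title(f"call {rmap.predicted_call} (relevance for {rmap.target_call})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
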