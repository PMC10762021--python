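"""Per-exon three-class copy-number classifier.

The model embeds each standardized read-depth value into H dimensions with a
shared affine map, prepends one of 24 learned chromosome-specific
classification tokens, adds an absolute-coordinate sinusoidal positional
encoding (base constant 1e9, large enough to uniquely encode genomic
coordinates up to ~290 Mb), runs L pre-norm transformer encoder blocks with
padding-masked exact softmax attention, and classifies the transformed token
state into {DEL, DUP, NOCALL} with a two-layer head.

The network is implemented directly in numpy with hand-derived backward
passes (see ``_nn``); :func:`backward_batch` returns parameter gradients and
can capture per-block attention maps and their gradients for the
relevance-propagation explainer.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import _nn
from .depth_io import (
    DEL,
    DUP,
    NOCALL,
    INT_TO_LABEL,
    N_CHROMOSOMES,
    EncodedExon,
    ExonTarget,
    StandardizationStats,
)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``H`` is the embedding width, ``L`` the number of encoder blocks,
    ``mlp_hidden`` the hidden width of both the encoder MLP and the
    classification head (defaults to ``H``), and ``pe_constant`` the
    positional-encoding base, sized for absolute genomic coordinates.
    """

    H: int = 192
    L: int = 3
    heads: int = 8
    max_len: int = 1000
    n_chrom_tokens: int = N_CHROMOSOMES
    pe_constant: float = 1e9
    mlp_hidden: int | None = None
    n_classes: int = 3

    def __post_init__(self) -> None:
        if self.H % 2 != 0:
            raise ValueError("H must be even (sin/cos row pairing)")
        if self.H % self.heads != 0:
            raise ValueError("heads must divide H")
        if self.max_len < 1:
            raise ValueError("max_len must be >= 1")

    @property
    def hidden(self) -> int:
        return self.H if self.mlp_hidden is None else self.mlp_hidden


@dataclass
class ClassProbabilities:
    p_del: float
    p_dup: float
    p_nocall: float

    def __post_init__(self) -> None:
        s = self.p_del + self.p_dup + self.p_nocall
        if not math.isclose(s, 1.0, abs_tol=1e-5):
            raise ValueError(f"class probabilities sum to {s}, not 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_del, self.p_dup, self.p_nocall])


@dataclass
class ModelState:
    """All learnable parameters plus config, standardization stats, provenance."""

    config: ModelConfig
    params: dict[str, np.ndarray]
    stats: StandardizationStats | None = None
    provenance: dict = field(default_factory=dict)

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def copy(self) -> "ModelState":
        return ModelState(
            config=self.config,
            params={k: v.copy() for k, v in self.params.items()},
            stats=self.stats,
            provenance=dict(self.provenance),
        )

    def params_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for k in sorted(self.params):
            h.update(k.encode())
            h.update(self.params[k].tobytes())
        return h.hexdigest()[:16]


def init_state(
    config: ModelConfig,
    seed: int = 0,
    stats: StandardizationStats | None = None,
) -> ModelState:
    """Xavier-uniform initialization of every weight matrix; zero biases."""
    rng = np.random.default_rng(seed)
    H, M, C = config.H, config.hidden, config.n_classes
    p: dict[str, np.ndarray] = {}
    p["embed_W"] = _nn.xavier_uniform(rng, 1, H, (H,))
    p["embed_b"] = np.zeros(H, dtype=np.float32)
    p["token_C"] = _nn.xavier_uniform(rng, config.n_chrom_tokens, H, (H, config.n_chrom_tokens))
    for l in range(config.L):
        pre = f"blk{l}."
        p[pre + "ln1_g"] = np.ones(H, dtype=np.float32)
        p[pre + "ln1_b"] = np.zeros(H, dtype=np.float32)
        for name in ("Wq", "Wk", "Wv", "Wo"):
            p[pre + name] = _nn.xavier_uniform(rng, H, H, (H, H))
        for name in ("bq", "bk", "bv", "bo"):
            p[pre + name] = np.zeros(H, dtype=np.float32)
        p[pre + "ln2_g"] = np.ones(H, dtype=np.float32)
        p[pre + "ln2_b"] = np.zeros(H, dtype=np.float32)
        p[pre + "mlp_W1"] = _nn.xavier_uniform(rng, H, M, (H, M))
        p[pre + "mlp_b1"] = np.zeros(M, dtype=np.float32)
        p[pre + "mlp_W2"] = _nn.xavier_uniform(rng, M, H, (M, H))
        p[pre + "mlp_b2"] = np.zeros(H, dtype=np.float32)
    p["head_W1"] = _nn.xavier_uniform(rng, H, M, (H, M))
    p["head_b1"] = np.zeros(M, dtype=np.float32)
    p["head_W2"] = _nn.xavier_uniform(rng, M, C, (M, C))
    p["head_b2"] = np.zeros(C, dtype=np.float32)
    return ModelState(config=config, params=p, stats=stats, provenance={"init_seed": seed})


# ---------------------------------------------------------------------------
# batching helpers


def stack_encoded(encoded: list[EncodedExon]) -> dict[str, np.ndarray]:
    """Stack encoded exons into the batched arrays the model consumes."""
    return {
        "depth": np.stack([e.depth for e in encoded]).astype(np.float32),
        "mask": np.stack([e.mask for e in encoded]),
        "chrom": np.array([e.target.chrom_index for e in encoded], dtype=np.int64),
        "start": np.array([e.target.start for e in encoded], dtype=np.float64),
        "end": np.array([e.target.end for e in encoded], dtype=np.float64),
        "n_real": np.array([e.n_real for e in encoded], dtype=np.int64),
    }


def _locations(start, end, n_real, max_len: int) -> np.ndarray:
    """Per-column absolute genomic location, (B, max_len+1), float64.

    Column 0 (token slot) gets 0.  The trailing ``n_real`` depth columns map
    linearly from ``start`` toward ``end`` (step 1 when the exon fits
    unabridged); left-padding columns continue the same line below ``start``
    and are attention-masked anyway.
    """
    start = np.atleast_1d(np.asarray(start, dtype=np.float64))
    end = np.atleast_1d(np.asarray(end, dtype=np.float64))
    n_real = np.atleast_1d(np.asarray(n_real, dtype=np.float64))
    B = start.shape[0]
    cols = np.arange(max_len, dtype=np.float64)[None, :]  # depth columns 0..S-1
    step = (end - start) / n_real
    loc = start[:, None] + (cols - (max_len - n_real)[:, None]) * step[:, None]
    return np.concatenate([np.zeros((B, 1)), loc], axis=1)


def positional_encoding_batch(start, end, n_real, config: ModelConfig) -> np.ndarray:
    """(B, max_len+1, H) sinusoidal encoding of absolute coordinates."""
    loc = _locations(start, end, n_real, config.max_len)  # (B, T)
    H = config.H
    j = np.arange(H // 2, dtype=np.float64)
    div = config.pe_constant ** (2.0 * j / H)  # (H/2,)
    ang = loc[:, :, None] / div[None, None, :]  # (B, T, H/2)
    out = np.empty((loc.shape[0], loc.shape[1], H), dtype=np.float64)
    out[:, :, 0::2] = np.sin(ang)
    out[:, :, 1::2] = np.cos(ang)
    return out.astype(np.float32)


def positional_encoding(target: ExonTarget, config: ModelConfig, n_real: int | None = None) -> np.ndarray:
    """(H, max_len+1) encoding for one exon; column 0 is the token slot."""
    if target.start >= target.end:  # unreachable for a valid ExonTarget
        raise ValueError("start must be < end")
    if n_real is None:
        n_real = min(target.length, config.max_len)
    e = positional_encoding_batch(
        np.array([target.start]), np.array([target.end]), np.array([n_real]), config
    )
    return e[0].T


def embed_depth(encoded_exon: EncodedExon, state: ModelState) -> np.ndarray:
    """(H, max_len) position-wise affine embedding of the depth vector."""
    p = state.params
    if encoded_exon.depth.shape[0] != state.config.max_len:
        raise ValueError("encoded exon length does not match model max_len")
    return (encoded_exon.depth[:, None] * p["embed_W"] + p["embed_b"]).T


# ---------------------------------------------------------------------------
# forward / backward


def forward_batch(state: ModelState, batch: dict, need_cache: bool = False):
    """Run the encoder on a stacked batch; returns (logits, cache).

    ``cache`` is None unless ``need_cache``; with it, :func:`backward_batch`
    computes parameter gradients (and attention-map gradients on request).
    """
    cfg = state.config
    p = state.params
    D = batch["depth"]
    mask = batch["mask"]
    chrom = batch["chrom"]
    if D.shape[1] != cfg.max_len:
        raise ValueError("batch depth length does not match model max_len")
    if np.any((chrom < 1) | (chrom > cfg.n_chrom_tokens)):
        raise ValueError("chrom_index outside 1..%d" % cfg.n_chrom_tokens)
    B, S = D.shape
    nh, dh = cfg.heads, cfg.H // cfg.heads
    scale = 1.0 / math.sqrt(dh)

    X = D[:, :, None] * p["embed_W"][None, None, :] + p["embed_b"]
    tok = p["token_C"][:, chrom - 1].T  # (B, H)
    X1 = np.concatenate([tok[:, None, :], X], axis=1)  # (B, T, H)
    E = positional_encoding_batch(batch["start"], batch["end"], batch["n_real"], cfg)
    O = X1 + E
    key_mask = np.concatenate([np.ones((B, 1), dtype=bool), mask], axis=1)

    blocks = []
    for l in range(cfg.L):
        pre = f"blk{l}."
        ln1, ln1_c = _nn.layernorm_forward(O, p[pre + "ln1_g"], p[pre + "ln1_b"])
        Q = (ln1 @ p[pre + "Wq"] + p[pre + "bq"]).reshape(B, S + 1, nh, dh).transpose(0, 2, 1, 3)
        K = (ln1 @ p[pre + "Wk"] + p[pre + "bk"]).reshape(B, S + 1, nh, dh).transpose(0, 2, 1, 3)
        V = (ln1 @ p[pre + "Wv"] + p[pre + "bv"]).reshape(B, S + 1, nh, dh).transpose(0, 2, 1, 3)
        scores = (Q @ K.swapaxes(-1, -2)) * scale
        P = _nn.masked_softmax(scores, key_mask)
        ctx = (P @ V).transpose(0, 2, 1, 3).reshape(B, S + 1, cfg.H)
        attn_out = ctx @ p[pre + "Wo"] + p[pre + "bo"]
        O1 = attn_out + O
        ln2, ln2_c = _nn.layernorm_forward(O1, p[pre + "ln2_g"], p[pre + "ln2_b"])
        h_pre = ln2 @ p[pre + "mlp_W1"] + p[pre + "mlp_b1"]
        h_act = _nn.gelu(h_pre)
        O_next = h_act @ p[pre + "mlp_W2"] + p[pre + "mlp_b2"] + O1
        if not np.all(np.isfinite(O_next[:, 0, :])):
            raise FloatingPointError(f"non-finite activations in encoder block {l}")
        if need_cache:
            blocks.append(
                dict(ln1=ln1, ln1_c=ln1_c, Q=Q, K=K, V=V, P=P, ctx=ctx, O_in=O,
                     O1=O1, ln2=ln2, ln2_c=ln2_c, h_pre=h_pre, h_act=h_act)
            )
        O = O_next

    t0 = O[:, 0, :]
    h1_pre = t0 @ p["head_W1"] + p["head_b1"]
    h1 = _nn.gelu(h1_pre)
    logits = h1 @ p["head_W2"] + p["head_b2"]
    if not np.all(np.isfinite(logits)):
        raise FloatingPointError("non-finite activations in classification head")
    cache = None
    if need_cache:
        cache = dict(batch=batch, blocks=blocks, t0=t0, h1_pre=h1_pre, h1=h1, key_mask=key_mask)
    return logits, cache


def backward_batch(
    state: ModelState,
    cache: dict,
    dlogits: np.ndarray,
    capture_attention: bool = False,
):
    """Gradients of a scalar loss w.r.t. all parameters.

    Returns ``(grads, attn)`` where ``attn`` is a per-block list of
    ``(P, dP)`` attention maps and their gradients when requested (used by
    the explainer), else None.
    """
    cfg = state.config
    p = state.params
    batch = cache["batch"]
    D = batch["depth"]
    chrom = batch["chrom"]
    B, S = D.shape
    nh, dh = cfg.heads, cfg.H // cfg.heads
    scale = 1.0 / math.sqrt(dh)
    g: dict[str, np.ndarray] = {}
    attn: list[tuple[np.ndarray, np.ndarray]] | None = [] if capture_attention else None

    dh1 = dlogits @ p["head_W2"].T
    g["head_W2"] = cache["h1"].T @ dlogits
    g["head_b2"] = dlogits.sum(axis=0)
    dh1_pre = dh1 * _nn.gelu_grad(cache["h1_pre"])
    g["head_W1"] = cache["t0"].T @ dh1_pre
    g["head_b1"] = dh1_pre.sum(axis=0)
    dt0 = dh1_pre @ p["head_W1"].T

    dO = np.zeros((B, S + 1, cfg.H), dtype=np.float32)
    dO[:, 0, :] = dt0

    for l in range(cfg.L - 1, -1, -1):
        pre = f"blk{l}."
        c = cache["blocks"][l]
        # O_next = h_act @ W2 + b2 + O1
        dO1 = dO.copy()
        dh_act = dO @ p[pre + "mlp_W2"].T
        _, g[pre + "mlp_W2"], g[pre + "mlp_b2"] = _nn.linear_backward(dO, c["h_act"], p[pre + "mlp_W2"])
        dh_pre = dh_act * _nn.gelu_grad(c["h_pre"])
        dln2, g[pre + "mlp_W1"], g[pre + "mlp_b1"] = _nn.linear_backward(dh_pre, c["ln2"], p[pre + "mlp_W1"])
        dO1_ln, g[pre + "ln2_g"], g[pre + "ln2_b"] = _nn.layernorm_backward(dln2, c["ln2_c"])
        dO1 += dO1_ln
        # O1 = ctx @ Wo + bo + O_in
        dO_in = dO1.copy()
        dctx_flat, g[pre + "Wo"], g[pre + "bo"] = _nn.linear_backward(dO1, c["ctx"], p[pre + "Wo"])
        dctx = dctx_flat.reshape(B, S + 1, nh, dh).transpose(0, 2, 1, 3)
        P, V = c["P"], c["V"]
        dP = dctx @ V.swapaxes(-1, -2)
        dV = P.swapaxes(-1, -2) @ dctx
        if capture_attention:
            attn.append((P, dP))
        dS = P * (dP - (dP * P).sum(axis=-1, keepdims=True))
        dQ = (dS @ c["K"]) * scale
        dK = (dS.swapaxes(-1, -2) @ c["Q"]) * scale

        def _unhead(x):
            return x.transpose(0, 2, 1, 3).reshape(B, S + 1, cfg.H)

        dQf, dKf, dVf = _unhead(dQ), _unhead(dK), _unhead(dV)
        ln1 = c["ln1"]
        dln1 = dQf @ p[pre + "Wq"].T + dKf @ p[pre + "Wk"].T + dVf @ p[pre + "Wv"].T
        for name, dx in (("Wq", dQf), ("Wk", dKf), ("Wv", dVf)):
            _, g[pre + name], g[pre + "b" + name[1]] = _nn.linear_backward(dx, ln1, p[pre + name])
        dO_in_ln, g[pre + "ln1_g"], g[pre + "ln1_b"] = _nn.layernorm_backward(dln1, c["ln1_c"])
        dO = dO_in + dO_in_ln

    # O0 = [token | depth-embedding] + E_pos
    dtok = dO[:, 0, :]
    dC = np.zeros_like(p["token_C"])
    np.add.at(dC.T, chrom - 1, dtok)
    g["token_C"] = dC
    dX = dO[:, 1:, :]
    g["embed_W"] = np.einsum("bs,bsh->h", D, dX)
    g["embed_b"] = dX.sum(axis=(0, 1))
    if capture_attention:
        attn.reverse()  # restore block order 0..L-1
    return g, attn


# ---------------------------------------------------------------------------
# single-exon convenience API


def forward(encoded_exon: EncodedExon, state: ModelState) -> ClassProbabilities:
    """Class pseudo-probabilities for one encoded exon (evaluation mode)."""
    logits, _ = forward_batch(state, stack_encoded([encoded_exon]))
    probs = _nn.softmax(logits.astype(np.float64))[0]
    return ClassProbabilities(float(probs[0]), float(probs[1]), float(probs[2]))


def predict_proba(state: ModelState, encoded: list[EncodedExon], batch_size: int = 256) -> np.ndarray:
    """(N, 3) probabilities over [DEL, DUP, NOCALL] for a list of exons."""
    out = np.empty((len(encoded), 3), dtype=np.float64)
    for i in range(0, len(encoded), batch_size):
        chunk = encoded[i : i + batch_size]
        logits, _ = forward_batch(state, stack_encoded(chunk))
        out[i : i + len(chunk)] = _nn.softmax(logits.astype(np.float64))
    return out


def predict_label(probabilities: ClassProbabilities, min_call_prob: float | None = None) -> str:
    """Argmax class; optionally demote low-confidence DEL/DUP to NOCALL."""
    arr = probabilities.as_array()
    label = INT_TO_LABEL[int(np.argmax(arr))]
    if min_call_prob is not None and label in (DEL, DUP) and arr.max() < min_call_prob:
        return NOCALL
    return label


# ---------------------------------------------------------------------------
# model bundle persistence


def save_model(state: ModelState, path: str | Path) -> None:
    """Write a model bundle: ``weights.npz`` + ``model.json`` sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savez(path / "weights.npz", **state.params)
    sidecar = {
        "config": asdict(state.config),
        "stats": None if state.stats is None else {"mean": state.stats.mean, "sd": state.stats.sd},
        "provenance": state.provenance,
        "params_hash": state.params_hash(),
    }
    (path / "model.json").write_text(json.dumps(sidecar, indent=2))


def load_model(path: str | Path) -> ModelState:
    path = Path(path)
    sidecar = json.loads((path / "model.json").read_text())
    config = ModelConfig(**sidecar["config"])
    with np.load(path / "weights.npz") as npz:
        params = {k: npz[k].copy() for k in npz.files}
    stats = None
    if sidecar["stats"] is not None:
        stats = StandardizationStats(**sidecar["stats"])
    state = ModelState(config=config, params=params, stats=stats, provenance=sidecar["provenance"])
    if state.params_hash() != sidecar["params_hash"]:
        raise ValueError("model bundle corrupt: parameter hash mismatch")
    return state
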