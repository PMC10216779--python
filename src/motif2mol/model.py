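"""Encoder-decoder transformer translating binding-site motifs to SMILES.

Architecture: token embeddings scaled by sqrt(d_model) plus sinusoidal
positional encodings on both sides; encoder modules of multi-head
self-attention + feed-forward sub-layers; decoder modules of masked
(causal) self-attention, cross-attention over the encoder states, and
feed-forward sub-layers; residual connections with post-layer
normalization; a final linear projection to target-vocabulary logits.
Defaults follow the machine-translation recipe this family of models is
built on: d_model 512, 8 heads, 3+3 modules, feed-forward width 512,
Adam(lr 1e-4, betas (0.9, 0.98), eps 1e-9), cross-entropy ignoring PAD.

The network and its training loop are written on numpy with
reverse-mode automatic differentiation (HIPS autograd), which keeps the
whole model a plain dict of float arrays: initialization, training and
sampling are exactly reproducible from a seed on a given platform.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import autograd.numpy as anp
import numpy as np
from autograd import value_and_grad

from .curation import MotifCompoundPair
from .tokenization import (
    EOS_IDX,
    PAD_IDX,
    Vocab,
    build_vocab,
    tokenize_motif,
    tokenize_smiles,
)

logger = logging.getLogger(__name__)

_NEG_INF = -1e9


@dataclass(frozen=True)
class ModelConfig:
    """Transformer hyperparameters."""

    d_model: int = 512
    n_heads: int = 8
    n_encoder_modules: int = 3
    n_decoder_modules: int = 3
    d_feedforward: int = 512
    dropout: float = 0.1
    max_src_len: int = 200
    max_tgt_len: int = 150

    def __post_init__(self):
        counts = (
            self.d_model,
            self.n_heads,
            self.n_encoder_modules,
            self.n_decoder_modules,
            self.d_feedforward,
            self.max_src_len,
            self.max_tgt_len,
        )
        if any(c <= 0 for c in counts):
            raise ValueError("all size parameters must be positive")
        if self.d_model % self.n_heads != 0:
            raise ValueError(
                f"d_model ({self.d_model}) must be divisible by n_heads ({self.n_heads})"
            )
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


#: Full-scale preset (d_model 512, 8 heads, 3+3 modules).
PAPER_PRESET = ModelConfig()

#: Reduced preset for desk-scale experiments and tests.
TINY_PRESET = ModelConfig(
    d_model=64,
    n_heads=4,
    n_encoder_modules=2,
    n_decoder_modules=2,
    d_feedforward=128,
)

PRESETS = {"paper": PAPER_PRESET, "tiny": TINY_PRESET}


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if self.epochs <= 0 or self.batch_size <= 0 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size and learning_rate must be positive")


@dataclass
class TrainedModel:
    """Model state: config, vocabularies, parameter dict, loss history."""

    config: ModelConfig
    source_vocab: Vocab
    target_vocab: Vocab
    params: Dict[str, np.ndarray]
    loss_history: List[Tuple[float, float]] = field(default_factory=list)


# --- parameter initialization ------------------------------------------------


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=(fan_in, fan_out)).astype(np.float32)


def _init_attn(params, rng, prefix, d):
    for name in ("q", "k", "v", "o"):
        params[f"{prefix}_W{name}"] = _xavier(rng, d, d)
        params[f"{prefix}_b{name}"] = np.zeros(d, dtype=np.float32)


def _init_ln(params, prefix, d):
    params[f"{prefix}_g"] = np.ones(d, dtype=np.float32)
    params[f"{prefix}_b"] = np.zeros(d, dtype=np.float32)


def _init_ff(params, rng, prefix, d, dff):
    params[f"{prefix}_W1"] = _xavier(rng, d, dff)
    params[f"{prefix}_b1"] = np.zeros(dff, dtype=np.float32)
    params[f"{prefix}_W2"] = _xavier(rng, dff, d)
    params[f"{prefix}_b2"] = np.zeros(d, dtype=np.float32)


def init_model(
    cfg: ModelConfig, src_vocab: Vocab, tgt_vocab: Vocab, seed: int = 0
) -> TrainedModel:
    """Construct an untrained model with seeded Xavier-uniform parameters.

    The same seed yields bitwise-identical initial parameters on the same
    platform.
    """
    if len(src_vocab) < 5 or len(tgt_vocab) < 5:
        raise ValueError("vocabularies must contain the specials plus content tokens")
    rng = np.random.default_rng(seed)
    d, dff = cfg.d_model, cfg.d_feedforward
    params: Dict[str, np.ndarray] = {
        "src_emb": _xavier(rng, len(src_vocab), d),
        "tgt_emb": _xavier(rng, len(tgt_vocab), d),
    }
    for i in range(cfg.n_encoder_modules):
        _init_attn(params, rng, f"enc{i}_sa", d)
        _init_ln(params, f"enc{i}_ln1", d)
        _init_ff(params, rng, f"enc{i}_ff", d, dff)
        _init_ln(params, f"enc{i}_ln2", d)
    _init_ln(params, "enc_lnf", d)
    for i in range(cfg.n_decoder_modules):
        _init_attn(params, rng, f"dec{i}_sa", d)
        _init_ln(params, f"dec{i}_ln1", d)
        _init_attn(params, rng, f"dec{i}_ca", d)
        _init_ln(params, f"dec{i}_ln2", d)
        _init_ff(params, rng, f"dec{i}_ff", d, dff)
        _init_ln(params, f"dec{i}_ln3", d)
    _init_ln(params, "dec_lnf", d)
    params["out_W"] = _xavier(rng, d, len(tgt_vocab))
    params["out_b"] = np.zeros(len(tgt_vocab), dtype=np.float32)
    return TrainedModel(
        config=cfg, source_vocab=src_vocab, target_vocab=tgt_vocab, params=params
    )


# --- forward pass ------------------------------------------------------------


def sinusoidal_positions(max_len: int, d_model: int) -> np.ndarray:
    """Standard sinusoidal positional-encoding table, shape (max_len, d_model)."""
    pos = np.arange(max_len)[:, None]
    i = np.arange(0, d_model, 2)[None, :]
    angle = pos / np.power(10000.0, i / d_model)
    pe = np.zeros((max_len, d_model), dtype=np.float32)
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle[:, : d_model - d_model // 2])
    return pe


def _dropout(x, rate: float, rng: Optional[np.random.Generator]):
    if rng is None or rate <= 0.0:
        return x
    mask = (rng.random(np.shape(x)) >= rate).astype(np.float32) / np.float32(1.0 - rate)
    return x * mask


def _layer_norm(x, g, b, eps: float = 1e-5):
    mu = anp.mean(x, axis=-1, keepdims=True)
    var = anp.mean((x - mu) ** 2, axis=-1, keepdims=True)
    return (x - mu) / anp.sqrt(var + eps) * g + b


def _split_heads(x, n_heads: int):
    b, l, d = x.shape
    return anp.transpose(anp.reshape(x, (b, l, n_heads, d // n_heads)), (0, 2, 1, 3))


def _multi_head_attention(params, prefix, query, memory, mask_add, n_heads):
    """Scaled dot-product attention; ``mask_add`` is an additive mask (0 at
    kept positions, a large negative value at masked ones), broadcastable to
    (batch, heads, len_q, len_k)."""
    q = _split_heads(anp.matmul(query, params[f"{prefix}_Wq"]) + params[f"{prefix}_bq"], n_heads)
    k = _split_heads(anp.matmul(memory, params[f"{prefix}_Wk"]) + params[f"{prefix}_bk"], n_heads)
    v = _split_heads(anp.matmul(memory, params[f"{prefix}_Wv"]) + params[f"{prefix}_bv"], n_heads)
    scale = np.float32(1.0 / np.sqrt(q.shape[-1]))
    scores = anp.matmul(q, anp.swapaxes(k, -1, -2)) * scale + mask_add
    # dropout is applied to sub-layer outputs, not to the attention weights:
    # regularizing the (B, H, Lq, Lk) weight tensor costs more than the rest
    # of the pass combined and adds little at these model sizes
    weights = _softmax(scores)
    ctx = anp.matmul(weights, v)
    b, h, l, dh = ctx.shape
    ctx = anp.reshape(anp.transpose(ctx, (0, 2, 1, 3)), (b, l, h * dh))
    return anp.matmul(ctx, params[f"{prefix}_Wo"]) + params[f"{prefix}_bo"]


def _additive(keep: np.ndarray) -> np.ndarray:
    """Boolean keep-mask -> additive float mask (0 kept, -1e9 masked)."""
    return np.where(keep, np.float32(0.0), np.float32(_NEG_INF))


def _softmax(x):
    x = x - anp.max(x, axis=-1, keepdims=True)
    e = anp.exp(x)
    return e / anp.sum(e, axis=-1, keepdims=True)


def _feed_forward(params, prefix, x, rate, rng):
    h = anp.maximum(0.0, anp.matmul(x, params[f"{prefix}_W1"]) + params[f"{prefix}_b1"])
    h = _dropout(h, rate, rng)
    return anp.matmul(h, params[f"{prefix}_W2"]) + params[f"{prefix}_b2"]


def _embed(params, table_key, ids, d_model, rate, rng):
    x = params[table_key][ids] * np.float32(np.sqrt(d_model))
    x = x + sinusoidal_positions(ids.shape[1], d_model)
    return _dropout(x, rate, rng)


def encode(params, cfg: ModelConfig, src_ids: np.ndarray, src_keep: np.ndarray,
           rng: Optional[np.random.Generator] = None):
    """Run the encoder stack.  ``src_keep`` is True at real (non-PAD) tokens."""
    rate = cfg.dropout if rng is not None else 0.0
    x = _embed(params, "src_emb", src_ids, cfg.d_model, rate, rng)
    attn_mask = _additive(src_keep[:, None, None, :])  # keys only
    # pre-norm residual blocks: normalize the sub-layer input, leave the
    # residual stream unnormalized (stable at large step sizes, which the
    # short desk-scale training schedules rely on)
    for i in range(cfg.n_encoder_modules):
        h = _layer_norm(x, params[f"enc{i}_ln1_g"], params[f"enc{i}_ln1_b"])
        x = x + _dropout(
            _multi_head_attention(params, f"enc{i}_sa", h, h, attn_mask, cfg.n_heads),
            rate, rng,
        )
        h = _layer_norm(x, params[f"enc{i}_ln2_g"], params[f"enc{i}_ln2_b"])
        x = x + _dropout(_feed_forward(params, f"enc{i}_ff", h, rate, rng), rate, rng)
    return _layer_norm(x, params["enc_lnf_g"], params["enc_lnf_b"])


def decode(params, cfg: ModelConfig, memory, src_keep: np.ndarray,
           tgt_ids: np.ndarray, rng: Optional[np.random.Generator] = None):
    """Run the decoder stack on right-shifted target ids; returns logits.

    Causal masking guarantees position t attends only to positions <= t.
    """
    rate = cfg.dropout if rng is not None else 0.0
    lt = tgt_ids.shape[1]
    x = _embed(params, "tgt_emb", tgt_ids, cfg.d_model, rate, rng)
    causal = np.tril(np.ones((lt, lt), dtype=bool))
    tgt_keep = tgt_ids != PAD_IDX
    self_mask = _additive(causal[None, None, :, :] & tgt_keep[:, None, None, :])
    cross_mask = _additive(src_keep[:, None, None, :])
    for i in range(cfg.n_decoder_modules):
        h = _layer_norm(x, params[f"dec{i}_ln1_g"], params[f"dec{i}_ln1_b"])
        x = x + _dropout(
            _multi_head_attention(params, f"dec{i}_sa", h, h, self_mask, cfg.n_heads),
            rate, rng,
        )
        h = _layer_norm(x, params[f"dec{i}_ln2_g"], params[f"dec{i}_ln2_b"])
        x = x + _dropout(
            _multi_head_attention(params, f"dec{i}_ca", h, memory, cross_mask, cfg.n_heads),
            rate, rng,
        )
        h = _layer_norm(x, params[f"dec{i}_ln3_g"], params[f"dec{i}_ln3_b"])
        x = x + _dropout(_feed_forward(params, f"dec{i}_ff", h, rate, rng), rate, rng)
    x = _layer_norm(x, params["dec_lnf_g"], params["dec_lnf_b"])
    return anp.matmul(x, params["out_W"]) + params["out_b"]


def forward_logits(params, cfg, src_ids, tgt_in_ids, rng=None):
    src_keep = src_ids != PAD_IDX
    memory = encode(params, cfg, src_ids, src_keep, rng)
    return decode(params, cfg, memory, src_keep, tgt_in_ids, rng)


# --- batching ----------------------------------------------------------------


def _encode_sequences(seqs: Sequence[Sequence[int]], max_len: int, what: str) -> np.ndarray:
    """Pad a list of id sequences into a (n, L) array, truncating to max_len."""
    truncated = 0
    clipped = []
    for s in seqs:
        if len(s) > max_len:
            truncated += 1
            s = list(s[: max_len - 1]) + [EOS_IDX]
        clipped.append(s)
    if truncated:
        logger.warning("%d %s sequences truncated to %d tokens", truncated, what, max_len)
    width = max(len(s) for s in clipped)
    out = np.full((len(clipped), width), PAD_IDX, dtype=np.int64)
    for i, s in enumerate(clipped):
        out[i, : len(s)] = s
    return out


def encode_pairs(
    pairs: Sequence[MotifCompoundPair], src_vocab: Vocab, tgt_vocab: Vocab,
    cfg: ModelConfig,
) -> Tuple[np.ndarray, np.ndarray]:
    """Tokenize and index a pair list into padded (src, tgt) id arrays."""
    src = [src_vocab.encode(tokenize_motif(p.motif_text)) for p in pairs]
    tgt = [tgt_vocab.encode(tokenize_smiles(p.canonical_smiles)) for p in pairs]
    return (
        _encode_sequences(src, cfg.max_src_len, "source"),
        _encode_sequences(tgt, cfg.max_tgt_len, "target"),
    )


def build_vocabs(pairs: Sequence[MotifCompoundPair]) -> Tuple[Vocab, Vocab]:
    """Source and target vocabularies from a training pair list."""
    src = build_vocab(tokenize_motif(p.motif_text) for p in pairs)
    tgt = build_vocab(tokenize_smiles(p.canonical_smiles) for p in pairs)
    return src, tgt


# --- loss & training ---------------------------------------------------------


def _loss_from_ids(params, cfg, src_ids, tgt_ids, rng=None):
    """Mean token-level cross-entropy over non-PAD target positions.

    The decoder input is the gold target right-shifted (BOS prefix retained,
    final token dropped); the labels are the gold target left-shifted.
    """
    tgt_in = tgt_ids[:, :-1]
    labels = tgt_ids[:, 1:]
    logits = forward_logits(params, cfg, src_ids, tgt_in, rng)
    logz = anp.log(anp.sum(anp.exp(logits - anp.max(logits, axis=-1, keepdims=True)),
                           axis=-1)) + anp.max(logits, axis=-1)
    onehot = np.eye(logits.shape[-1], dtype=np.float32)[labels]
    gold = anp.sum(logits * onehot, axis=-1)
    keep = (labels != PAD_IDX).astype(np.float32)
    return anp.sum((logz - gold) * keep) / anp.sum(keep)


def teacher_forced_loss(model: TrainedModel, batch: Sequence[MotifCompoundPair]) -> float:
    """Teacher-forced cross-entropy of a batch of motif/SMILES pairs."""
    if not batch:
        raise ValueError("empty batch")
    src, tgt = encode_pairs(batch, model.source_vocab, model.target_vocab, model.config)
    return float(_loss_from_ids(model.params, model.config, src, tgt))


def _lr_schedule(step: int, total_steps: int, peak_lr: float) -> float:
    """Linear warmup over the first 5% of steps, then cosine decay to 10%
    of the peak learning rate."""
    warmup = max(1, int(0.05 * total_steps))
    if step < warmup:
        return peak_lr * (step + 1) / warmup
    frac = (step - warmup) / max(1, total_steps - warmup)
    return peak_lr * (0.1 + 0.9 * 0.5 * (1.0 + np.cos(np.pi * frac)))


class _Adam:
    """Adam over a dict of arrays (betas 0.9/0.98, eps 1e-9)."""

    def __init__(self, params, lr, betas=(0.9, 0.98), eps=1e-9):
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] = params[k] - self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps
            )


def dataset_loss(model: TrainedModel, src: np.ndarray, tgt: np.ndarray,
                 batch_size: int = 64) -> float:
    """Token-weighted mean cross-entropy over a whole encoded dataset."""
    total, tokens = 0.0, 0
    for lo in range(0, src.shape[0], batch_size):
        sb, tb = src[lo : lo + batch_size], tgt[lo : lo + batch_size]
        n_tok = int(np.sum(tb[:, 1:] != PAD_IDX))
        total += float(_loss_from_ids(model.params, model.config, sb, tb)) * n_tok
        tokens += n_tok
    return total / tokens


def train(
    model: TrainedModel,
    train_pairs: Sequence[MotifCompoundPair],
    val_pairs: Sequence[MotifCompoundPair],
    tc: TrainConfig,
) -> TrainedModel:
    """Train in place with per-epoch shuffled minibatches; returns the model.

    Records (train loss, validation loss) after every epoch; the final-epoch
    model is the result (no early stopping or checkpoint selection).  Aborts
    with a diagnostic if the loss becomes non-finite.
    """
    if not train_pairs or not val_pairs:
        raise ValueError("both train and validation partitions must be non-empty")
    cfg = model.config
    src_tr, tgt_tr = encode_pairs(train_pairs, model.source_vocab, model.target_vocab, cfg)
    src_va, tgt_va = encode_pairs(val_pairs, model.source_vocab, model.target_vocab, cfg)
    rng = np.random.default_rng(tc.seed)
    opt = _Adam(model.params, tc.learning_rate)
    grad_fn = value_and_grad(
        lambda p, sb, tb, drop_rng: _loss_from_ids(p, cfg, sb, tb, drop_rng)
    )
    n = src_tr.shape[0]
    batches_per_epoch = (n + tc.batch_size - 1) // tc.batch_size
    total_steps = tc.epochs * batches_per_epoch
    global_step = 0
    for epoch in range(tc.epochs):
        order = rng.permutation(n)
        epoch_loss, epoch_tok = 0.0, 0
        for lo in range(0, n, tc.batch_size):
            idx = order[lo : lo + tc.batch_size]
            sb, tb = src_tr[idx], tgt_tr[idx]
            opt.lr = _lr_schedule(global_step, total_steps, tc.learning_rate)
            global_step += 1
            loss, grads = grad_fn(model.params, sb, tb, rng if cfg.dropout > 0 else None)
            loss = float(loss)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, batch offset {lo}"
                )
            opt.step(model.params, grads)
            n_tok = int(np.sum(tb[:, 1:] != PAD_IDX))
            epoch_loss += loss * n_tok
            epoch_tok += n_tok
        train_loss = epoch_loss / epoch_tok
        val_loss = dataset_loss(model, src_va, tgt_va)
        model.loss_history.append((train_loss, val_loss))
        logger.info(
            "epoch %d/%d: train %.4f, validation %.4f",
            epoch + 1, tc.epochs, train_loss, val_loss,
        )
    return model


# --- persistence -------------------------------------------------------------


def save_model(model: TrainedModel, path) -> None:
    """Write a checkpoint (.npz): parameters, config, vocabs, loss history."""
    meta = {
        "config": asdict(model.config),
        "src_vocab": [model.source_vocab.index_to_token[i] for i in range(len(model.source_vocab))],
        "tgt_vocab": [model.target_vocab.index_to_token[i] for i in range(len(model.target_vocab))],
        "loss_history": model.loss_history,
    }
    arrays = {f"param::{k}": v for k, v in model.params.items()}
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(str(path), **arrays)


def load_model(path) -> TrainedModel:
    with np.load(str(path)) as data:
        meta = json.loads(bytes(data["meta_json"]).decode())
        params = {
            k[len("param::") :]: data[k] for k in data.files if k.startswith("param::")
        }
    def _vocab(tokens):
        t2i = {t: i for i, t in enumerate(tokens)}
        return Vocab(token_to_index=t2i, index_to_token={i: t for t, i in t2i.items()})
    return TrainedModel(
        config=ModelConfig(**meta["config"]),
        source_vocab=_vocab(meta["src_vocab"]),
        target_vocab=_vocab(meta["tgt_vocab"]),
        params=params,
        loss_history=[tuple(x) for x in meta["loss_history"]],
    )
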