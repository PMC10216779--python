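"""Transformer construction, loss, masking and training contracts.

Most tests run a micro configuration (d_model 16, 1+1 modules) on short
hand-made pairs so the whole file stays fast; learning-quality checks on
the realistic tiny preset live with the end-to-end evaluation tests.
"""

import numpy as np
import pytest

from motif2mol.curation import MotifCompoundPair
from motif2mol.model import (
    ModelConfig,
    TrainConfig,
    build_vocabs,
    dataset_loss,
    encode_pairs,
    forward_logits,
    init_model,
    load_model,
    save_model,
    teacher_forced_loss,
    train,
)

MICRO = ModelConfig(
    d_model=16, n_heads=2, n_encoder_modules=1, n_decoder_modules=1,
    d_feedforward=32, dropout=0.0, max_src_len=40, max_tgt_len=30,
)

PAIRS = [
    MotifCompoundPair("T1", "MKVLAEHG", "CCO"),
    MotifCompoundPair("T2", "GHEALVKM", "c1ccccc1"),
    MotifCompoundPair("T3", "MKVAAEHG", "CCN"),
    MotifCompoundPair("T4", "AHEALVKM", "c1ccncc1"),
    MotifCompoundPair("T5", "MKVLAEAG", "CC(C)O"),
    MotifCompoundPair("T6", "GHEALVAM", "CC=O"),
]


@pytest.fixture(scope="module")
def micro_model():
    sv, tv = build_vocabs(PAIRS)
    return init_model(MICRO, sv, tv, seed=1)


# --- construction ------------------------------------------------------------


def test_paper_scale_config_constructs():
    cfg = ModelConfig()  # d_model 512, 8 heads, 3+3 modules, d_ff 512
    sv, tv = build_vocabs(PAIRS)
    model = init_model(cfg, sv, tv, seed=0)
    assert model.params["src_emb"].shape == (len(sv), 512)
    assert sum(1 for k in model.params if k.startswith("enc")) > 0


def test_head_divisibility_enforced():
    with pytest.raises(ValueError, match="divisible"):
        ModelConfig(d_model=10, n_heads=3)


def test_init_deterministic_per_seed():
    sv, tv = build_vocabs(PAIRS)
    a = init_model(MICRO, sv, tv, seed=7)
    b = init_model(MICRO, sv, tv, seed=7)
    c = init_model(MICRO, sv, tv, seed=8)
    for k in a.params:
        assert np.array_equal(a.params[k], b.params[k])
    assert any(not np.array_equal(a.params[k], c.params[k]) for k in a.params)


# --- loss --------------------------------------------------------------------


def test_uniform_model_loss_is_log_vocab(micro_model):
    """Zeroing the output projection makes the predictive distribution
    uniform, whose cross-entropy is exactly ln(vocab size)."""
    model = init_model(MICRO, micro_model.source_vocab, micro_model.target_vocab, seed=1)
    model.params["out_W"] = np.zeros_like(model.params["out_W"])
    model.params["out_b"] = np.zeros_like(model.params["out_b"])
    loss = teacher_forced_loss(model, PAIRS)
    assert loss == pytest.approx(np.log(len(model.target_vocab)), rel=1e-4)


def test_loss_batch_order_invariant(micro_model):
    loss_fwd = teacher_forced_loss(micro_model, PAIRS)
    loss_rev = teacher_forced_loss(micro_model, PAIRS[::-1])
    assert loss_rev == pytest.approx(loss_fwd, abs=1e-5)


def test_loss_minibatch_accumulation_matches_full(micro_model):
    src, tgt = encode_pairs(
        PAIRS, micro_model.source_vocab, micro_model.target_vocab, MICRO
    )
    full = dataset_loss(micro_model, src, tgt, batch_size=len(PAIRS))
    accum = dataset_loss(micro_model, src, tgt, batch_size=2)
    assert accum == pytest.approx(full, abs=1e-5)


def test_loss_empty_batch_rejected(micro_model):
    with pytest.raises(ValueError):
        teacher_forced_loss(micro_model, [])


def test_overlong_sequence_truncated_with_warning(micro_model, caplog):
    import logging

    long_pair = MotifCompoundPair("TX", "MKVLAEHG" * 10, "CCO")
    with caplog.at_level(logging.WARNING, logger="motif2mol.model"):
        loss = teacher_forced_loss(micro_model, [long_pair])
    assert np.isfinite(loss)
    assert any("truncated" in r.message for r in caplog.records)


# --- masking -----------------------------------------------------------------


def _ids(model, pairs):
    return encode_pairs(pairs, model.source_vocab, model.target_vocab, MICRO)


def test_causal_mask_blocks_future_tokens(micro_model):
    """Perturbing target token t+1 must never change logits at positions <= t."""
    src, tgt = _ids(micro_model, PAIRS[:1])
    tgt_in = tgt[:, :-1]
    base = forward_logits(micro_model.params, MICRO, src, tgt_in)
    for t in range(1, tgt_in.shape[1]):
        perturbed = tgt_in.copy()
        perturbed[0, t] = (perturbed[0, t] + 1) % len(micro_model.target_vocab)
        out = forward_logits(micro_model.params, MICRO, src, perturbed)
        assert np.allclose(out[0, :t], base[0, :t], atol=1e-5), f"leak at t={t}"


def test_cross_attention_conditions_on_source(micro_model):
    """Different motifs must produce different decoder logits."""
    src_a, tgt = _ids(micro_model, [PAIRS[0]])
    src_b, _ = _ids(micro_model, [MotifCompoundPair("T1", "GGGGGGGG", "CCO")])
    out_a = forward_logits(micro_model.params, MICRO, src_a, tgt[:, :-1])
    out_b = forward_logits(micro_model.params, MICRO, src_b, tgt[:, :-1])
    assert not np.allclose(out_a, out_b, atol=1e-4)


def test_pad_positions_do_not_affect_other_rows(micro_model):
    """A short sequence's loss is unchanged by the padding introduced when it
    shares a batch with a longer one."""
    solo = teacher_forced_loss(micro_model, [PAIRS[0]])
    src, tgt = _ids(micro_model, [PAIRS[0], PAIRS[1]])
    from motif2mol.model import _loss_from_ids

    both = float(_loss_from_ids(micro_model.params, MICRO, src, tgt))
    other = teacher_forced_loss(micro_model, [PAIRS[1]])
    n1 = int(np.sum(tgt[0, 1:] != 0))
    n2 = int(np.sum(tgt[1, 1:] != 0))
    assert both == pytest.approx((solo * n1 + other * n2) / (n1 + n2), abs=1e-5)


# --- training ----------------------------------------------------------------


def test_training_reduces_loss_and_is_deterministic():
    tc = TrainConfig(epochs=40, batch_size=3, learning_rate=2e-3, seed=5)
    histories = []
    for _ in range(2):
        sv, tv = build_vocabs(PAIRS)
        model = init_model(MICRO, sv, tv, seed=5)
        train(model, PAIRS[:4], PAIRS[4:], tc)
        histories.append(model.loss_history)
    assert histories[0] == histories[1]  # bitwise-identical runs
    first_train = histories[0][0][0]
    last_train = histories[0][-1][0]
    assert last_train < first_train * 0.5
    assert len(histories[0]) == tc.epochs
    assert all(np.isfinite(v) and v >= 0 for pair in histories[0] for v in pair)


def test_train_rejects_empty_partition(micro_model):
    with pytest.raises(ValueError):
        train(micro_model, [], PAIRS, TrainConfig(epochs=1))


# --- persistence -------------------------------------------------------------


def test_checkpoint_roundtrip(tmp_path, micro_model):
    path = tmp_path / "model.npz"
    micro_model.loss_history = [(1.0, 1.1), (0.5, 0.6)]
    save_model(micro_model, path)
    back = load_model(path)
    assert back.config == micro_model.config
    assert back.loss_history == micro_model.loss_history
    assert back.source_vocab.token_to_index == micro_model.source_vocab.token_to_index
    for k in micro_model.params:
        assert np.array_equal(back.params[k], micro_model.params[k])
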