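"""Temperature sampling of candidate SMILES from a trained model.

One sampling run is one autoregressive decode yielding one string: tokens
are drawn with probability proportional to exp(logit / T), stopping at EOS
or the length cap.  Two run protocols are provided: sample until a fixed
number of unique valid structures is reached (training/validation-target
protocol) and a fixed number of runs (held-out-target protocol).
Uniqueness is judged on canonical SMILES, so two raw strings encoding one
structure count once; decodes that hit the length cap without emitting EOS
count as invalid.

For throughput the decodes are executed in parallel batches, but each run
owns an independent child RNG derived from (seed, run index), so the
string produced by run i depends only on the seed and i - results are
identical whatever the batch size, and a longer run sequence extends a
shorter one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Set

import numpy as np

from .curation import InvalidStructureError, canonicalize_smiles
from .model import TrainedModel, decode, encode
from .tokenization import BOS_IDX, EOS_IDX, PAD_IDX, detokenize, tokenize_motif


@dataclass
class RunRecord:
    """Accounting for a single sampling run."""

    run_index: int
    raw_smiles: str
    canonical_smiles: Optional[str]
    is_valid: bool
    is_new_unique: bool


@dataclass
class SamplingResult:
    """Outcome of a sampling campaign against one target motif."""

    target_id: str
    runs_performed: int
    raw_strings: List[str]
    unique_valid: Set[str]
    temperature: float
    completed: bool = True
    records: List[RunRecord] = field(default_factory=list)


def _encode_motif(model: TrainedModel, motif_text: str) -> np.ndarray:
    ids = model.source_vocab.encode(tokenize_motif(motif_text))
    if len(ids) > model.config.max_src_len:
        ids = ids[: model.config.max_src_len - 1] + [EOS_IDX]
    return np.asarray([ids], dtype=np.int64)


def _decode_batch(
    model: TrainedModel,
    memory_one: np.ndarray,
    src_keep_one: np.ndarray,
    temperature: float,
    max_len: int,
    rngs: Sequence[np.random.Generator],
) -> List[Optional[List[int]]]:
    """Autoregressively decode len(rngs) sequences in parallel.

    Returns one token-id list per row, or None for rows that hit the length
    cap without emitting EOS.
    """
    cfg = model.config
    b = len(rngs)
    memory = np.repeat(memory_one, b, axis=0)
    src_keep = np.repeat(src_keep_one, b, axis=0)
    tgt = np.full((b, 1), BOS_IDX, dtype=np.int64)
    finished = np.zeros(b, dtype=bool)
    for _ in range(max_len):
        logits = decode(model.params, cfg, memory, src_keep, tgt)[:, -1, :]
        z = logits / temperature
        z = z - np.max(z, axis=-1, keepdims=True)
        probs = np.exp(z)
        probs /= np.sum(probs, axis=-1, keepdims=True)
        nxt = np.full(b, PAD_IDX, dtype=np.int64)
        for row in range(b):
            if not finished[row]:
                nxt[row] = rngs[row].choice(probs.shape[-1], p=probs[row])
        finished |= nxt == EOS_IDX
        tgt = np.concatenate([tgt, nxt[:, None]], axis=1)
        if finished.all():
            break
    out: List[Optional[List[int]]] = []
    for row in range(b):
        ids = tgt[row].tolist()
        if EOS_IDX in ids:
            out.append(ids[: ids.index(EOS_IDX) + 1])
        else:
            out.append(None)  # length cap without termination
    return out


def _run_rng(seed: int, run_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(run_index,)))


def sample_one(
    model: TrainedModel,
    motif_text: str,
    temperature: float = 1.0,
    max_len: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> str:
    """One sampling run: a single decoded SMILES string (validity not
    guaranteed; a decode that hits the length cap returns its partial
    string)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    rng = rng if rng is not None else np.random.default_rng()
    max_len = max_len or model.config.max_tgt_len
    src_ids = _encode_motif(model, motif_text)
    src_keep = src_ids != PAD_IDX
    memory = encode(model.params, model.config, src_ids, src_keep)
    ids = _decode_batch(model, memory, src_keep, temperature, max_len, [rng])[0]
    if ids is None:
        return ""
    return detokenize(model.target_vocab.decode(ids))


def greedy_decode(model: TrainedModel, motif_text: str, max_len: Optional[int] = None) -> str:
    """Deterministic argmax decode (the T -> 0 limit of sampling)."""
    max_len = max_len or model.config.max_tgt_len
    cfg = model.config
    src_ids = _encode_motif(model, motif_text)
    src_keep = src_ids != PAD_IDX
    memory = encode(model.params, cfg, src_ids, src_keep)
    tgt = np.full((1, 1), BOS_IDX, dtype=np.int64)
    for _ in range(max_len):
        logits = decode(model.params, cfg, memory, src_keep, tgt)[0, -1, :]
        nxt = int(np.argmax(logits))
        tgt = np.concatenate([tgt, [[nxt]]], axis=1)
        if nxt == EOS_IDX:
            break
    ids = tgt[0].tolist()
    if EOS_IDX in ids:
        ids = ids[: ids.index(EOS_IDX) + 1]
    return detokenize(model.target_vocab.decode(ids))


def _campaign(
    model: TrainedModel,
    motif_text: str,
    temperature: float,
    seed: int,
    target_id: str,
    max_runs: int,
    n_unique: Optional[int],
    batch_size: int = 64,
) -> SamplingResult:
    """Shared engine: decode runs in order until the stop condition."""
    cfg = model.config
    src_ids = _encode_motif(model, motif_text)
    src_keep = src_ids != PAD_IDX
    memory = encode(model.params, cfg, src_ids, src_keep)
    unique: Set[str] = set()
    records: List[RunRecord] = []
    raw: List[str] = []
    runs_done = 0
    completed = False
    while runs_done < max_runs:
        b = min(batch_size, max_runs - runs_done)
        rngs = [_run_rng(seed, runs_done + j) for j in range(b)]
        token_lists = _decode_batch(
            model, memory, src_keep, temperature, cfg.max_tgt_len, rngs
        )
        for ids in token_lists:
            run_index = runs_done
            runs_done += 1
            if ids is None:
                smi, canonical, valid = "", None, False
            else:
                smi = detokenize(model.target_vocab.decode(ids))
                try:
                    canonical = canonicalize_smiles(smi)
                    valid = True
                except InvalidStructureError:
                    canonical, valid = None, False
            new_unique = valid and canonical not in unique
            if new_unique:
                unique.add(canonical)
            raw.append(smi)
            records.append(RunRecord(run_index, smi, canonical, valid, new_unique))
            if n_unique is not None and len(unique) >= n_unique:
                completed = True
                break
        if completed:
            break
    if n_unique is None:
        completed = True
    elif len(unique) < n_unique:
        completed = False
    return SamplingResult(
        target_id=target_id,
        runs_performed=runs_done,
        raw_strings=raw,
        unique_valid=unique,
        temperature=temperature,
        completed=completed,
        records=records,
    )


def sample_until_unique(
    model: TrainedModel,
    motif_text: str,
    n_unique: int = 100,
    temperature: float = 1.0,
    max_runs: Optional[int] = None,
    seed: int = 0,
    target_id: str = "",
) -> SamplingResult:
    """Sample until ``n_unique`` unique valid structures are collected.

    Invalid and duplicate strings consume runs without counting;
    ``runs_performed`` is the structure-generation-frequency statistic.  If
    the cap (default 100 x n_unique) is reached first, the partial result is
    returned with ``completed=False`` rather than raising.
    """
    if n_unique < 1:
        raise ValueError("n_unique must be >= 1")
    cap = max_runs if max_runs is not None else 100 * n_unique
    return _campaign(model, motif_text, temperature, seed, target_id, cap, n_unique)


def sample_fixed_runs(
    model: TrainedModel,
    motif_text: str,
    runs: int = 1000,
    temperature: float = 1.0,
    seed: int = 0,
    target_id: str = "",
) -> SamplingResult:
    """Perform exactly ``runs`` sampling runs, accumulating unique valid
    structures (the held-out-target protocol)."""
    if runs < 1:
        raise ValueError("runs must be >= 1")
    return _campaign(model, motif_text, temperature, seed, target_id, runs, None)


def write_samples(results: Sequence[SamplingResult], path) -> None:
    """TSV: target_id, run_index, raw_smiles, canonical_smiles, is_valid, is_new_unique."""
    import pandas as pd

    rows = [
        (
            res.target_id,
            rec.run_index,
            rec.raw_smiles,
            rec.canonical_smiles if rec.canonical_smiles is not None else "NA",
            rec.is_valid,
            rec.is_new_unique,
        )
        for res in results
        for rec in res.records
    ]
    pd.DataFrame(
        rows,
        columns=[
            "target_id", "run_index", "raw_smiles",
            "canonical_smiles", "is_valid", "is_new_unique",
        ],
    ).to_csv(path, sep="\t", index=False)
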