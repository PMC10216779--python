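"""Bioactivity curation: filtering, canonicalization, pair enumeration, splitting.

Mirrors the workflow used to assemble motif/inhibitor training data from a
ChEMBL-style export: keep records at the highest target confidence with
potency pIC50 >= 6 (IC50 <= 1 uM), canonicalize structures, enumerate one
training pair per unique (target, structure), pool everything and split
80/20 at the pair level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")  # RDKit parse chatter; failures surface as errors

ACTIVITY_COLUMNS = ["target_id", "compound_id", "smiles", "pic50", "confidence"]


class InvalidStructureError(ValueError):
    """A SMILES string that does not parse to a chemically sane molecule."""


@dataclass(frozen=True)
class ActivityRecord:
    """One bioactivity measurement row."""

    target_id: str
    compound_id: str
    smiles: str
    pic50: float
    confidence: int


@dataclass(frozen=True)
class MotifCompoundPair:
    """One (binding-site motif, active compound) training instance."""

    target_id: str
    motif_text: str
    canonical_smiles: str


@dataclass(frozen=True)
class SplitDataset:
    train: tuple
    validation: tuple
    seed: int
    fraction: float


def read_activity_table(path) -> List[ActivityRecord]:
    """Read a tab-delimited activity table.

    Required header columns: target_id, compound_id, smiles, pic50,
    confidence.  Rows with missing potency are dropped with a logged count.
    """
    df = pd.read_csv(path, sep="\t", dtype={"target_id": str, "compound_id": str})
    missing = [c for c in ACTIVITY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"activity table missing columns: {missing}")
    n_na = int(df["pic50"].isna().sum())
    if n_na:
        logger.info("dropping %d records with missing pIC50", n_na)
        df = df.dropna(subset=["pic50"])
    return [
        ActivityRecord(
            target_id=str(r.target_id),
            compound_id=str(r.compound_id),
            smiles=str(r.smiles),
            pic50=float(r.pic50),
            confidence=int(r.confidence),
        )
        for r in df.itertuples(index=False)
    ]


def filter_records(
    records: Sequence[ActivityRecord],
    min_pic50: float = 6.0,
    min_confidence: int = 9,
) -> List[ActivityRecord]:
    """Keep records with pic50 >= min_pic50 AND confidence >= min_confidence.

    Both thresholds are inclusive; input order is preserved.  An empty result
    is permitted (logged), not an error.
    """
    kept = [
        r
        for r in records
        if np.isfinite(r.pic50)
        and r.pic50 >= min_pic50
        and r.confidence >= min_confidence
    ]
    if not kept:
        logger.warning(
            "no records survive filtering (min_pic50=%s, min_confidence=%s)",
            min_pic50,
            min_confidence,
        )
    return kept


def canonicalize_smiles(smiles: str) -> str:
    """Return the RDKit-canonical SMILES; idempotent.

    Raises :class:`InvalidStructureError` for strings that do not parse or
    fail valence sanitization.
    """
    if not smiles or not smiles.strip():
        raise InvalidStructureError("empty SMILES")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        raise InvalidStructureError(f"unparseable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def deduplicate_pairs(
    records: Sequence[ActivityRecord],
    motifs: Dict[str, str],
) -> List[MotifCompoundPair]:
    """Enumerate one pair per unique (target_id, canonical structure).

    A compound active on k targets yields k pairs.  Records whose target has
    no motif, or whose SMILES is invalid, are dropped with logged counts.
    """
    seen = set()
    pairs: List[MotifCompoundPair] = []
    n_no_motif = n_invalid = 0
    for rec in records:
        motif = motifs.get(rec.target_id)
        if motif is None:
            n_no_motif += 1
            continue
        try:
            canonical = canonicalize_smiles(rec.smiles)
        except InvalidStructureError:
            n_invalid += 1
            continue
        key = (rec.target_id, canonical)
        if key in seen:
            continue
        seen.add(key)
        pairs.append(MotifCompoundPair(rec.target_id, motif, canonical))
    if n_no_motif:
        logger.warning("%d records dropped: target without motif", n_no_motif)
    if n_invalid:
        logger.warning("%d records dropped: invalid SMILES", n_invalid)
    return pairs


def split_pairs(
    pairs: Sequence[MotifCompoundPair],
    fraction: float = 0.8,
    seed: int = 0,
) -> SplitDataset:
    """Random pair-level split: first floor(fraction*n) of a seeded uniform
    permutation to train, remainder to validation."""
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0,1), got {fraction}")
    n = len(pairs)
    if n < 2:
        raise ValueError(f"need at least 2 pairs to split, got {n}")
    perm = np.random.default_rng(seed).permutation(n)
    n_train = int(np.floor(fraction * n))
    train = tuple(pairs[i] for i in perm[:n_train])
    validation = tuple(pairs[i] for i in perm[n_train:])
    return SplitDataset(train=train, validation=validation, seed=seed, fraction=fraction)


def split_sizes(n: int, fraction: float = 0.8) -> tuple:
    """(train, validation) sizes under the floor rule."""
    n_train = int(np.floor(fraction * n))
    return n_train, n - n_train


# --- I/O ---------------------------------------------------------------------


def write_pairs(split: SplitDataset, path) -> None:
    """TSV with columns target_id, motif_text, canonical_smiles, partition."""
    rows = [
        (p.target_id, p.motif_text, p.canonical_smiles, part)
        for part, pairs in (("train", split.train), ("validation", split.validation))
        for p in pairs
    ]
    pd.DataFrame(
        rows, columns=["target_id", "motif_text", "canonical_smiles", "partition"]
    ).to_csv(path, sep="\t", index=False)


def read_pairs(path) -> SplitDataset:
    """Read a pair table written by :func:`write_pairs`."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    by_part = {"train": [], "validation": []}
    for r in df.itertuples(index=False):
        by_part[r.partition].append(
            MotifCompoundPair(r.target_id, r.motif_text, r.canonical_smiles)
        )
    total = len(df)
    frac = len(by_part["train"]) / total if total else 0.0
    return SplitDataset(
        train=tuple(by_part["train"]),
        validation=tuple(by_part["validation"]),
        seed=-1,
        fraction=frac,
    )


def curate(
    records: Sequence[ActivityRecord],
    motifs: Dict[str, str],
    min_pic50: float = 6.0,
    min_confidence: int = 9,
    fraction: float = 0.8,
    seed: int = 0,
    exclude_targets: Optional[Iterable[str]] = None,
) -> SplitDataset:
    """Full curation path: exclusion, filtering, pair enumeration, split.

    ``exclude_targets`` removes held-out evaluation targets from the data
    entirely, before any other step.
    """
    excluded = set(exclude_targets or ())
    if excluded:
        records = [r for r in records if r.target_id not in excluded]
        motifs = {t: m for t, m in motifs.items() if t not in excluded}
    filtered = filter_records(records, min_pic50=min_pic50, min_confidence=min_confidence)
    pairs = deduplicate_pairs(filtered, motifs)
    return split_pairs(pairs, fraction=fraction, seed=seed)
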