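"""Synthetic kinome and bioactivity-table generator.

Emulates the statistical shape of a curated kinase/inhibitor extraction so
the whole pipeline - motif scanning, curation, training, sampling,
evaluation - runs end to end with no external database:

* every target sequence embeds exactly one ATP-binding signature match
  (a random instantiation of PS00107) preceded by a 20-60 residue prefix
  and followed by extension_length + 30 downstream residues;
* each target's chemistry is a scaffold plus a small pool of substituents,
  both chosen by a deterministic hash of the instantiated signature
  segment, so that motif -> chemistry is a learnable mapping;
* actives are assembled from SMILES templates (never by string mutation),
  hence valid by construction, with pIC50 ~ U[6.1, 9.0] at confidence 9;
* decoy records fail the potency or confidence filter and must vanish
  during curation;
* per-target active counts follow a deterministic linear ramp around the
  nominal count (~0.2x to ~1.8x), emulating the wide spread of available
  inhibitors per kinase seen in real extractions and giving the
  training-set-size gradient the similarity-trend analysis needs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .curation import ActivityRecord, canonicalize_smiles
from .prosite import (
    DEFAULT_EXTENSION,
    PS00107,
    STANDARD_AA,
    ProsPattern,
    parse_prosite,
)

#: Asymmetric two-slot scaffold templates ({a}/{b} are substituent sites).
#: Asymmetry matters: on a symmetric core the pairs (a,b) and (b,a) collapse
#: to one canonical structure and per-target compound counts would shrink.
SCAFFOLD_TEMPLATES: Tuple[str, ...] = (
    "c1nc({a})nc({b})c1",        # pyrimidine (2,4)
    "O=C({a})Nc1ccc({b})cc1",    # anilide
    "O=S(=O)({a})c1ccc({b})cc1", # aryl sulfone
    "c1oc({a})nc1{b}",           # oxazole
    "c1sc({a})nc1{b}",           # thiazole
    "c1cc({a})cnc1{b}",          # pyridine (3,6)
    "c1cc({a})ncc1{b}",          # pyridine (4,... )
    "c1cnc({a})c({b})c1",        # pyridine (2,3)
    "c1cc({a})c({b})nc1",        # pyridine, adjacent slots
    "c1nc({a})oc1{b}",           # oxazole, swapped slots
)

#: Chemically simple substituent fragments, all valid inside a branch.
SUBSTITUENTS: Tuple[str, ...] = (
    "C", "CC", "CCC", "C(C)C", "CCCC", "O", "OC", "OCC", "N", "NC",
    "N(C)C", "F", "Cl", "Br", "C#N", "C(=O)O", "C(=O)N", "C(=O)C",
    "C(F)(F)F", "CO", "CCO", "CN", "CCN", "S", "SC", "[N+](=O)[O-]",
    "C=C", "C#C", "CC=C", "OC(C)C",
)

#: Substituents each target prefers; 7 of 30, giving 49 ordered pairs per
#: scaffold, enough headroom above the largest ramped compound count.
POOL_SIZE = 7


@dataclass(frozen=True)
class SynthSpec:
    """Study conditions for a synthetic kinome."""

    n_targets: int = 20
    n_compounds_per_target: int = 25
    seed: int = 0
    extension_length: int = DEFAULT_EXTENSION
    scaffold_library_size: int = 8
    decoy_fraction: float = 0.2

    def __post_init__(self):
        if self.n_targets < 2:
            raise ValueError("need at least 2 targets")
        if not 0 <= self.decoy_fraction < 1:
            raise ValueError("decoy_fraction must be in [0, 1)")
        if not 1 <= self.scaffold_library_size <= len(SCAFFOLD_TEMPLATES):
            raise ValueError(
                f"scaffold_library_size must be in [1, {len(SCAFFOLD_TEMPLATES)}]"
            )
        if self.n_compounds_per_target < 2:
            raise ValueError("need at least 2 compounds per target")


@dataclass(frozen=True)
class SynthTarget:
    """Ground truth for one synthetic kinase."""

    target_id: str
    sequence: str
    segment_parts: Tuple[str, ...]  # per-element pieces of the signature match
    scaffold_index: int
    substituent_pool: Tuple[str, ...]
    actives: Tuple[str, ...]  # canonical SMILES

    @property
    def signature_segment(self) -> str:
        return "".join(self.segment_parts)


@dataclass
class SynthKinome:
    spec: SynthSpec
    targets: List[SynthTarget]
    records: List[ActivityRecord]


def _random_residues(rng: np.random.Generator, n: int) -> str:
    return "".join(STANDARD_AA[i] for i in rng.integers(0, len(STANDARD_AA), n))


def _instantiate_parts(pattern: ProsPattern, rng: np.random.Generator) -> Tuple[str, ...]:
    parts = []
    for el in pattern.elements:
        n = int(rng.integers(el.min_repeat, el.max_repeat + 1))
        choices = sorted(el.accepted)
        parts.append("".join(choices[int(i)] for i in rng.integers(0, len(choices), n)))
    return tuple(parts)


def _segment_hash(segment: str) -> int:
    return zlib.crc32(segment.encode("ascii"))


def _chemistry_for_segment(segment: str, n_scaffolds: int) -> Tuple[int, Tuple[str, ...]]:
    """Deterministic motif->chemistry assignment via a hash of the signature
    segment: a scaffold index and a preferred substituent pool."""
    h = _segment_hash(segment)
    scaffold_index = h % n_scaffolds
    pool_rng = np.random.default_rng(h)
    pool = tuple(
        SUBSTITUENTS[int(i)]
        for i in pool_rng.choice(len(SUBSTITUENTS), size=POOL_SIZE, replace=False)
    )
    return scaffold_index, pool


def _assemble(template: str, a: str, b: str) -> str:
    return canonicalize_smiles(template.format(a=a, b=b))


def _draw_actives(
    scaffold_index: int,
    pool: Sequence[str],
    count: int,
    rng: np.random.Generator,
) -> Tuple[str, ...]:
    """Draw ``count`` distinct structures: scaffold + ordered substituent pair."""
    template = SCAFFOLD_TEMPLATES[scaffold_index]
    combos = [(a, b) for a in pool for b in pool]
    order = rng.permutation(len(combos))
    out: List[str] = []
    seen = set()
    for idx in order:
        a, b = combos[int(idx)]
        smi = _assemble(template, a, b)
        if smi in seen:
            continue
        seen.add(smi)
        out.append(smi)
        if len(out) == count:
            break
    return tuple(out)


def _ramped_counts(spec: SynthSpec) -> np.ndarray:
    """Per-target active counts: linear ramp ~0.2x-1.8x the nominal count,
    largest first, mean ~= n_compounds_per_target."""
    ramp = np.linspace(1.8, 0.2, spec.n_targets)
    counts = np.maximum(2, np.rint(ramp * spec.n_compounds_per_target).astype(int))
    cap = POOL_SIZE * POOL_SIZE
    return np.minimum(counts, cap)


def generate_kinome(spec: SynthSpec) -> SynthKinome:
    """Generate the toy kinome: sequences, activity records, ground truth.

    Deterministic in ``spec.seed``: two runs produce identical output.
    """
    rng = np.random.default_rng(spec.seed)
    pattern = parse_prosite(PS00107, accession_label="PS00107")
    width = max(2, len(str(spec.n_targets - 1)))
    counts = _ramped_counts(spec)
    targets: List[SynthTarget] = []
    records: List[ActivityRecord] = []
    for t in range(spec.n_targets):
        target_id = f"SYNK{t:0{width}d}"
        prefix = _random_residues(rng, int(rng.integers(20, 61)))
        parts = _instantiate_parts(pattern, rng)
        downstream = _random_residues(rng, spec.extension_length + 30)
        sequence = prefix + "".join(parts) + downstream
        scaffold_index, pool = _chemistry_for_segment(
            "".join(parts), spec.scaffold_library_size
        )
        actives = _draw_actives(scaffold_index, pool, int(counts[t]), rng)
        targets.append(
            SynthTarget(target_id, sequence, parts, scaffold_index, pool, actives)
        )
        for c, smi in enumerate(actives):
            records.append(
                ActivityRecord(
                    target_id=target_id,
                    compound_id=f"{target_id}_CPD{c:03d}",
                    smiles=smi,
                    pic50=float(np.round(rng.uniform(6.1, 9.0), 2)),
                    confidence=9,
                )
            )
    # decoys: records that must fail the potency or confidence filter
    n_actives = len(records)
    n_decoys = int(np.floor(spec.decoy_fraction / (1 - spec.decoy_fraction) * n_actives))
    for d in range(n_decoys):
        tgt = targets[int(rng.integers(0, len(targets)))]
        a = SUBSTITUENTS[int(rng.integers(0, len(SUBSTITUENTS)))]
        b = SUBSTITUENTS[int(rng.integers(0, len(SUBSTITUENTS)))]
        smi = _assemble(SCAFFOLD_TEMPLATES[tgt.scaffold_index], a, b)
        if rng.random() < 0.5:
            pic50, confidence = float(np.round(rng.uniform(3.0, 5.9), 2)), 9
        else:
            pic50, confidence = float(np.round(rng.uniform(6.1, 9.0), 2)), int(rng.integers(0, 9))
        records.append(
            ActivityRecord(
                target_id=tgt.target_id,
                compound_id=f"DECOY{d:04d}",
                smiles=smi,
                pic50=pic50,
                confidence=confidence,
            )
        )
    return SynthKinome(spec=spec, targets=targets, records=records)


def generate_heldout_target(
    kinome: SynthKinome,
    similarity_tier: str,
    seed: int = 0,
    max_retries: int = 50,
) -> SynthTarget:
    """A held-out evaluation target outside the training kinome.

    ``high`` tier: the signature segment (and the rest of the sequence) is
    copied from a training target with at most 3 residue edits inside the
    segment, so global sequence identity to that target exceeds 50% and the
    held-out chemistry (scaffold and substituent pool of the base target)
    remains reachable from what the model saw.  ``low`` tier: a fresh random
    sequence whose identity to every training target is at most 50%, with
    its own hash-derived chemistry.  Tier constraints are verified with
    BLOSUM62 global alignment; unsatisfiable constraints raise after
    ``max_retries`` attempts.
    """
    from .evaluation import sequence_identity  # deferred: avoids import cycle

    spec = kinome.spec
    rng = np.random.default_rng(seed)
    pattern = parse_prosite(PS00107, accession_label="PS00107")
    if similarity_tier == "high":
        base = kinome.targets[int(rng.integers(0, len(kinome.targets)))]
        editable = [
            i
            for i, (el, part) in enumerate(zip(pattern.elements, base.segment_parts))
            if len(part) == 1 and len(el.accepted) > 1
        ]
        n_edits = min(3, len(editable))
        for _ in range(max_retries):
            parts = list(base.segment_parts)
            for i in rng.choice(editable, size=n_edits, replace=False):
                el = pattern.elements[int(i)]
                alternatives = sorted(el.accepted - {parts[int(i)]})
                parts[int(i)] = alternatives[int(rng.integers(0, len(alternatives)))]
            segment = "".join(parts)
            prefix_len = base.sequence.index(base.signature_segment)
            sequence = (
                base.sequence[:prefix_len]
                + segment
                + base.sequence[prefix_len + len(base.signature_segment):]
            )
            if sequence_identity(sequence, base.sequence) > 50.0:
                actives = _draw_actives(
                    base.scaffold_index,
                    base.substituent_pool,
                    spec.n_compounds_per_target,
                    rng,
                )
                return SynthTarget(
                    "HELDOUT_HIGH", sequence, tuple(parts),
                    base.scaffold_index, base.substituent_pool, actives,
                )
        raise RuntimeError("could not build a high-identity held-out target")
    if similarity_tier == "low":
        for _ in range(max_retries):
            prefix = _random_residues(rng, int(rng.integers(20, 61)))
            parts = _instantiate_parts(pattern, rng)
            downstream = _random_residues(rng, spec.extension_length + 30)
            sequence = prefix + "".join(parts) + downstream
            if all(
                sequence_identity(sequence, t.sequence) <= 50.0
                for t in kinome.targets
            ):
                scaffold_index, pool = _chemistry_for_segment(
                    "".join(parts), spec.scaffold_library_size
                )
                actives = _draw_actives(
                    scaffold_index, pool, spec.n_compounds_per_target, rng
                )
                return SynthTarget(
                    "HELDOUT_LOW", sequence, parts, scaffold_index, pool, actives
                )
        raise RuntimeError("could not build a low-identity held-out target")
    raise ValueError(f"similarity_tier must be 'high' or 'low', got {similarity_tier!r}")


# --- I/O ---------------------------------------------------------------------


def write_fasta(targets: Sequence[SynthTarget], path) -> None:
    with Path(path).open("w") as fh:
        for t in targets:
            fh.write(f">{t.target_id} synthetic kinase\n")
            seq = t.sequence
            for lo in range(0, len(seq), 60):
                fh.write(seq[lo : lo + 60] + "\n")


def write_activities(records: Sequence[ActivityRecord], path) -> None:
    pd.DataFrame(
        [(r.target_id, r.compound_id, r.smiles, r.pic50, r.confidence) for r in records],
        columns=["target_id", "compound_id", "smiles", "pic50", "confidence"],
    ).to_csv(path, sep="\t", index=False)


def write_truth(targets: Sequence[SynthTarget], path) -> None:
    """Ground-truth TSV: target, scaffold, substituent pool, active set."""
    pd.DataFrame(
        [
            (
                t.target_id,
                t.signature_segment,
                SCAFFOLD_TEMPLATES[t.scaffold_index],
                ",".join(t.substituent_pool),
                ",".join(t.actives),
            )
            for t in targets
        ],
        columns=["target_id", "signature_segment", "scaffold", "substituent_pool", "actives"],
    ).to_csv(path, sep="\t", index=False)


def known_actives(kinome: SynthKinome) -> Dict[str, Tuple[str, ...]]:
    """target_id -> canonical active SMILES, from the ground truth."""
    return {t.target_id: t.actives for t in kinome.targets}
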