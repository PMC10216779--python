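"""Evaluation of generated compound sets.

Metrics: SMILES validity (N_valid / N_all, valence-checked by RDKit);
1-nearest-neighbor Tanimoto similarity between the generated set A and the
known-actives set B on 2048-bit Morgan fingerprints of radius 3, summarized
as its maximum over A (1NN Sim_max) and mean over A (1NN Sim_ave); exact
reproduction counts by canonical-SMILES identity (stricter than Tc = 1.0,
which can also arise for nearly identical structures); and global pairwise
sequence identity under BLOSUM62 with affine gaps for relating targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .curation import InvalidStructureError, canonicalize_smiles
from .prosite import STANDARD_AA
from .sampling import SamplingResult

logger = logging.getLogger(__name__)

FP_BITS = 2048
FP_RADIUS = 3

_fp_generator = rdFingerprintGenerator.GetMorganGenerator(
    radius=FP_RADIUS, fpSize=FP_BITS
)


@dataclass(frozen=True)
class EvalReport:
    """Per-target evaluation row."""

    target_id: str
    n_all: int
    n_valid: int
    nn_max: float
    nn_ave: float
    reproduced_count: int
    n_candidates: int  # |A|
    n_known: int  # |B|
    runs_performed: int = 0

    @property
    def validity(self) -> float:
        return self.n_valid / self.n_all


def validity(strings: Sequence[str]) -> Tuple[int, int, float]:
    """(N_valid, N_all, ratio): fraction of strings parsing to sane molecules."""
    if not strings:
        raise ValueError("validity of an empty string list is undefined")
    n_valid = 0
    for s in strings:
        try:
            canonicalize_smiles(s)
            n_valid += 1
        except InvalidStructureError:
            pass
    return n_valid, len(strings), n_valid / len(strings)


def fingerprint(smiles: str) -> FrozenSet[int]:
    """On-bit indices of the 2048-bit Morgan fingerprint (radius 3)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidStructureError(f"cannot fingerprint invalid SMILES {smiles!r}")
    return frozenset(_fp_generator.GetFingerprint(mol).GetOnBits())


def tanimoto(fa: FrozenSet[int], fb: FrozenSet[int]) -> float:
    """|a n b| / |a u b|; 1.0 for two empty fingerprints (identical absence)."""
    union = len(fa | fb)
    if union == 0:
        logger.info("Tanimoto of two empty fingerprints; defined as 1.0")
        return 1.0
    return len(fa & fb) / union


def _fp_matrix(smiles_list: Sequence[str]) -> np.ndarray:
    mat = np.zeros((len(smiles_list), FP_BITS), dtype=np.float64)
    for i, s in enumerate(smiles_list):
        mat[i, sorted(fingerprint(s))] = 1.0
    return mat


def nn_similarity(A: Sequence[str], B: Sequence[str]) -> Tuple[float, float]:
    """(nn_max, nn_ave): for each a in A its highest Tanimoto to B, then the
    maximum resp. mean of those per-candidate bests.

    Vectorized over the bit matrices; both sets must be non-empty valid
    structures.
    """
    if not A or not B:
        raise ValueError("nn_similarity requires non-empty sets")
    fa, fb = _fp_matrix(list(A)), _fp_matrix(list(B))
    inter = fa @ fb.T
    counts_a = fa.sum(axis=1)[:, None]
    counts_b = fb.sum(axis=1)[None, :]
    union = counts_a + counts_b - inter
    with np.errstate(invalid="ignore"):
        tc = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 1.0)
    best = tc.max(axis=1)
    return float(best.max()), float(best.mean())


def nn_profile(A: Sequence[str], B: Sequence[str]) -> List[Tuple[str, str, float]]:
    """Per-candidate nearest neighbor: (candidate, closest known, Tc)."""
    if not A or not B:
        raise ValueError("nn_profile requires non-empty sets")
    fb = [fingerprint(b) for b in B]
    out = []
    for a in A:
        fa = fingerprint(a)
        sims = [tanimoto(fa, f) for f in fb]
        j = int(np.argmax(sims))
        out.append((a, B[j], sims[j]))
    return out


def count_reproduced(A: Iterable[str], B: Iterable[str]) -> int:
    """Number of known structures in B whose canonical SMILES occurs in A.

    Identity is canonical-string equality - deliberately stricter than
    Tc = 1.0, which also covers nearly identical compounds.
    """
    canon_a = {canonicalize_smiles(a) for a in A}
    return sum(1 for b in set(canonicalize_smiles(x) for x in B) if b in canon_a)


# --- sequence comparison -----------------------------------------------------

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_AA_SET = frozenset(STANDARD_AA)


def _make_aligner(open_gap: float = -10.0, extend_gap: float = -0.5) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    return aligner


def sequence_identity(
    s1: str,
    s2: str,
    open_gap: float = -10.0,
    extend_gap: float = -0.5,
) -> float:
    """Percent identity under optimal global BLOSUM62 alignment.

    Identity = identical aligned pairs / alignment length (gaps included)
    x 100.  Gap penalties (open -10, extend -0.5) are surfaced as arguments.
    """
    if not s1 or not s2:
        raise ValueError("sequences must be non-empty")
    for name, s in (("s1", s1), ("s2", s2)):
        bad = sorted({c for c in s if c not in _AA_SET})
        if bad:
            raise ValueError(f"{name} contains non-standard residues {bad}")
    alignment = _make_aligner(open_gap, extend_gap).align(s1, s2)[0]
    counts = alignment.counts()
    length = counts.gaps + counts.identities + counts.mismatches
    return 100.0 * counts.identities / length


def alignment_score(s1: str, s2: str, open_gap: float = -10.0, extend_gap: float = -0.5) -> float:
    """Optimal global alignment score (BLOSUM62, affine gaps)."""
    return float(_make_aligner(open_gap, extend_gap).score(s1, s2))


# --- per-target reporting ----------------------------------------------------


def per_target_report(
    samples: Sequence[SamplingResult],
    known_inhibitors: Dict[str, Sequence[str]],
) -> List[EvalReport]:
    """One EvalReport per sampled target, ordered by descending reference-set
    size (the decreasing-training-data ordering of the headline figures).

    Targets lacking a reference set are skipped with a warning.
    """
    rows: List[EvalReport] = []
    for res in samples:
        known = known_inhibitors.get(res.target_id)
        if not known:
            logger.warning("target %s has no reference set; skipped", res.target_id)
            continue
        known_canon = sorted({canonicalize_smiles(k) for k in known})
        n_valid, n_all, _ = validity(res.raw_strings) if res.raw_strings else (0, 1, 0.0)
        candidates = sorted(res.unique_valid)
        if candidates:
            nn_max, nn_ave = nn_similarity(candidates, known_canon)
            reproduced = count_reproduced(candidates, known_canon)
        else:
            nn_max = nn_ave = 0.0
            reproduced = 0
        rows.append(
            EvalReport(
                target_id=res.target_id,
                n_all=n_all,
                n_valid=n_valid,
                nn_max=nn_max,
                nn_ave=nn_ave,
                reproduced_count=reproduced,
                n_candidates=len(candidates),
                n_known=len(known_canon),
                runs_performed=res.runs_performed,
            )
        )
    rows.sort(key=lambda r: (-r.n_known, r.target_id))
    return rows


def write_report(rows: Sequence[EvalReport], path) -> None:
    """Per-target report TSV (runs, validity, nn_ave, nn_max, reproduction)."""
    pd.DataFrame(
        [
            {
                "target_id": r.target_id,
                "n_known": r.n_known,
                "runs_performed": r.runs_performed,
                "n_all": r.n_all,
                "n_valid": r.n_valid,
                "validity": r.validity,
                "n_candidates": r.n_candidates,
                "nn_ave": r.nn_ave,
                "nn_max": r.nn_max,
                "reproduced_count": r.reproduced_count,
            }
            for r in rows
        ]
    ).to_csv(path, sep="\t", index=False)
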