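"""Validity, fingerprint similarity, reproduction and sequence identity."""

import numpy as np
import pytest

from motif2mol.evaluation import (
    count_reproduced,
    fingerprint,
    nn_profile,
    nn_similarity,
    per_target_report,
    sequence_identity,
    alignment_score,
    tanimoto,
    validity,
)
from motif2mol.sampling import SamplingResult
from motif2mol.synthetic import SCAFFOLD_TEMPLATES, SUBSTITUENTS, _assemble

# --- validity ----------------------------------------------------------------


def test_validity_all_valid():
    assert validity(["CCO", "c1ccccc1"]) == (2, 2, 1.0)


def test_validity_counts_unparseable():
    n_valid, n_all, ratio = validity(["CCO", "C1CC"])  # unclosed ring
    assert (n_valid, n_all, ratio) == (1, 2, 0.5)


def test_validity_empty_list_rejected():
    with pytest.raises(ValueError):
        validity([])


def test_generator_compounds_are_valid_by_construction(kinome):
    smiles = [r.smiles for r in kinome.records]
    assert validity(smiles)[2] == 1.0


# --- tanimoto ----------------------------------------------------------------


def test_tanimoto_identities():
    fa = frozenset({1, 2, 3})
    assert tanimoto(fa, fa) == 1.0
    assert tanimoto(fa, frozenset({7, 8})) == 0.0
    assert tanimoto(fa, frozenset({2, 3, 4})) == 0.5
    assert tanimoto(frozenset(), frozenset()) == 1.0


def test_tanimoto_symmetric():
    rng = np.random.default_rng(0)
    for _ in range(20):
        fa = frozenset(rng.integers(0, 2048, 30).tolist())
        fb = frozenset(rng.integers(0, 2048, 30).tolist())
        assert tanimoto(fa, fb) == tanimoto(fb, fa)


def test_fingerprint_bits_in_range_and_deterministic():
    fp = fingerprint("CC(=O)Oc1ccccc1C(=O)O")
    assert fp == fingerprint("CC(=O)Oc1ccccc1C(=O)O")
    assert all(0 <= b < 2048 for b in fp)


# --- 1-NN similarity ---------------------------------------------------------


def _random_sets(rng, n_a, n_b):
    def draw(n):
        out = set()
        while len(out) < n:
            t = SCAFFOLD_TEMPLATES[int(rng.integers(0, len(SCAFFOLD_TEMPLATES)))]
            a = SUBSTITUENTS[int(rng.integers(0, len(SUBSTITUENTS)))]
            b = SUBSTITUENTS[int(rng.integers(0, len(SUBSTITUENTS)))]
            out.add(_assemble(t, a, b))
        return sorted(out)

    return draw(n_a), draw(n_b)


def _brute_force_nn(A, B):
    """Independent double-loop implementation of the two summaries."""
    bests = []
    for a in A:
        fa = fingerprint(a)
        bests.append(max(tanimoto(fa, fingerprint(b)) for b in B))
    return max(bests), sum(bests) / len(bests)


def test_nn_similarity_matches_brute_force():
    rng = np.random.default_rng(17)
    for _ in range(25):
        A, B = _random_sets(rng, int(rng.integers(1, 8)), int(rng.integers(1, 12)))
        got = nn_similarity(A, B)
        want = _brute_force_nn(A, B)
        assert got[0] == pytest.approx(want[0], abs=1e-12)
        assert got[1] == pytest.approx(want[1], abs=1e-12)
        assert got[1] <= got[0] + 1e-12
        assert 0.0 <= got[1] <= got[0] <= 1.0


def test_nn_single_candidate_max_equals_ave():
    A, B = ["CCO"], ["CCN", "CCCO"]
    nn_max, nn_ave = nn_similarity(A, B)
    assert nn_max == nn_ave


def test_nn_subset_is_perfect():
    B = ["CCO", "c1ccccc1", "CC(C)N"]
    assert nn_similarity(B[:2], B) == (1.0, 1.0)


def test_nn_adding_known_member_forces_max_one():
    A, B = ["CCCCCCCC"], ["c1ccccc1O", "CCO"]
    assert nn_similarity(A + [B[0]], B)[0] == 1.0


def test_nn_empty_sets_rejected():
    with pytest.raises(ValueError):
        nn_similarity([], ["CCO"])
    with pytest.raises(ValueError):
        nn_similarity(["CCO"], [])


def test_nn_profile_reports_nearest_reference():
    prof = nn_profile(["CCO"], ["CCO", "c1ccccc1"])
    assert prof[0][1] == "CCO"
    assert prof[0][2] == 1.0


# --- reproduction ------------------------------------------------------------


def test_reproduction_counts():
    B = ["CCO", "c1ccccc1", "CCN"]
    assert count_reproduced(["CCCC"], B) == 0
    assert count_reproduced(B, B) == 3
    assert count_reproduced(["OCC"], B) == 1  # canonical-form identity


def test_reproduction_stricter_than_full_fingerprint_similarity():
    """A pair with identical fingerprints but different canonical structures
    (here: homologs long enough to fold onto the same circular substructure
    bits) counts for Tc = 1.0 but not for reproduction."""
    a, b = "C" * 24, "C" * 25  # tetracosane vs pentacosane
    assert tanimoto(fingerprint(a), fingerprint(b)) == 1.0
    from motif2mol.curation import canonicalize_smiles

    assert canonicalize_smiles(a) != canonicalize_smiles(b)
    assert count_reproduced([a], [b]) == 0


# --- sequence identity -------------------------------------------------------


def test_identity_of_identical_sequences():
    assert sequence_identity("MKVLAEHGW", "MKVLAEHGW") == 100.0


def test_identity_single_substitution():
    assert sequence_identity("ACDE", "ACDF") == 75.0


def test_identity_rejects_bad_input():
    with pytest.raises(ValueError):
        sequence_identity("ACDX1", "ACDE")
    with pytest.raises(ValueError):
        sequence_identity("", "ACDE")


def _gotoh_score(s1, s2, matrix, gap_open=-10.0, gap_extend=-0.5):
    """Independent affine-gap global alignment DP (Gotoh recursion)."""
    n, m = len(s1), len(s2)
    neg = -1e9
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)  # gap in s2
    Y = np.full((n + 1, m + 1), neg)  # gap in s1
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = matrix[s1[i - 1], s2[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + sub
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend)
    return max(M[n, m], X[n, m], Y[n, m])


def test_alignment_score_matches_dp_oracle():
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    rng = np.random.default_rng(23)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    for _ in range(15):
        s1 = "".join(rng.choice(list(aas), size=int(rng.integers(5, 30))))
        s2 = "".join(rng.choice(list(aas), size=int(rng.integers(5, 30))))
        assert alignment_score(s1, s2) == pytest.approx(
            _gotoh_score(s1, s2, blosum), abs=1e-9
        )


# --- per-target report -------------------------------------------------------


def _result(target, raw, unique):
    return SamplingResult(
        target_id=target,
        runs_performed=len(raw),
        raw_strings=raw,
        unique_valid=set(unique),
        temperature=1.0,
    )


def test_report_ordered_by_reference_size_and_bounds():
    samples = [
        _result("small", ["CCO", "badsmiles("], ["CCO"]),
        _result("big", ["CCN", "CCO", "c1ccccc1"], ["CCN", "CCO", "c1ccccc1"]),
    ]
    known = {
        "small": ["CCO", "CCN", "CCC"],
        "big": ["CCO", "CCN", "CCC", "CCCC", "c1ccccc1", "CC(C)O", "CCCCC",
                 "CCOC", "CCSC", "NCCN"],
    }
    rows = per_target_report(samples, known)
    assert [r.target_id for r in rows] == ["big", "small"]
    for r in rows:
        assert 0.0 <= r.validity <= 1.0
        assert 0.0 <= r.nn_ave <= r.nn_max <= 1.0
        assert r.reproduced_count <= min(r.n_candidates, r.n_known)


def test_report_skips_targets_without_reference(caplog):
    import logging

    with caplog.at_level(logging.WARNING, logger="motif2mol.evaluation"):
        rows = per_target_report([_result("orphan", ["CCO"], ["CCO"])], {})
    assert rows == []
    assert any("no reference set" in r.message for r in caplog.records)
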