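"""Score a generated compound set against known actives.

Shows the evaluation metrics on hand-made sets: validity of raw SMILES
strings, maximum and average 1-nearest-neighbor Tanimoto similarity
(2048-bit Morgan fingerprints, radius 3), exact reproduction counts, and
BLOSUM62 global sequence identity between two targets.
"""

import motif2mol as m2m

known = ["CCOc1ccccc1C(N)=O", "CCN(CC)c1ccccc1C(N)=O", "Cc1ccc(O)cc1"]
generated = ["CCOc1ccccc1C(N)=O",   # exact reproduction of a known active
             "CCOc1ccccc1C(=O)NC",  # close analog
             "C1CC1CCCCCCCC",       # unrelated structure
             "c1ccc(cc1"]           # malformed string

n_valid, n_all, ratio = m2m.validity(generated)
print(f"validity: {n_valid}/{n_all} = {ratio:.2f}")

valid = [s for s in generated if s != "c1ccc(cc1"]
nn_max, nn_ave = m2m.nn_similarity(valid, known)
print(f"1-NN similarity: max {nn_max:.3f}, average {nn_ave:.3f}")

reproduced = m2m.count_reproduced(valid, known)
print(f"known actives exactly reproduced: {reproduced}")

ident = m2m.sequence_identity("MKVLAEHGWKQRT", "MKVLQEHGWKDRT")
print(f"sequence identity of two related motifs: {ident:.1f}%")
# nn_max = 1.0 flags that at least one generated structure is (nearly)
# identical to a known active; reproduction additionally requires exact
# canonical-SMILES equality, the stricter criterion.
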