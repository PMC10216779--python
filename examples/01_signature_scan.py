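"""Locate a kinase ATP-binding site motif with the PROSITE signature.

Parses the packaged protein kinase ATP-binding region signature (PROSITE
PS00107), reports the range of match lengths it allows, scans a protein
sequence for it, and extracts the extended motif (match + 150 downstream
residues) that serves as the model input.
"""

import numpy as np

import motif2mol as m2m
from motif2mol.prosite import instantiate_pattern

pattern = m2m.parse_prosite(m2m.PS00107, accession_label="PS00107")
lo, hi = m2m.length_bounds(pattern)
print(f"signature: {m2m.PS00107}")
print(f"match length bounds: {lo}-{hi} residues")

# Build a demonstration sequence: 40 residues of padding, one signature
# instance, then enough downstream sequence for the 150-residue extension.
rng = np.random.default_rng(0)
segment = instantiate_pattern(pattern, rng)
sequence = "A" * 40 + segment + "G" * 160

motif = m2m.scan_and_extend(sequence, pattern, extension_length=150)
print(f"match at [{motif.match_start}, {motif.match_end}) "
      f"({len(motif.matched_segment)} residues)")
print(f"matched segment: {motif.matched_segment}")
print(f"extended motif length: {len(motif.motif_text)} residues")
# The extended motif (match + fixed 150-residue extension) is what the
# translation model conditions on; targets with fewer than 150 residues
# after the match are rejected rather than padded.
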