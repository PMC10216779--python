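"""Curate a bioactivity table into motif/compound training pairs.

Generates a small synthetic kinome (targets + activity records including
decoys), extracts each target's binding-site motif, filters to potent
high-confidence records (pIC50 >= 6, confidence 9), enumerates one pair
per unique (target, structure), and splits 80/20 at the pair level.
"""

import motif2mol as m2m

kinome = m2m.generate_kinome(m2m.SynthSpec(n_targets=6, n_compounds_per_target=10, seed=3))
print(f"kinome: {len(kinome.targets)} targets, {len(kinome.records)} activity records")

pattern = m2m.parse_prosite(m2m.PS00107)
motifs = {
    t.target_id: m2m.scan_and_extend(t.sequence, pattern, target_id=t.target_id).motif_text
    for t in kinome.targets
}

kept = m2m.filter_records(kinome.records, min_pic50=6.0, min_confidence=9)
print(f"records surviving the potency/confidence filter: {len(kept)} "
      f"({len(kinome.records) - len(kept)} decoys removed)")

split = m2m.curate(kinome.records, motifs, seed=3)
print(f"pairs: {len(split.train)} train / {len(split.validation)} validation "
      f"(fraction {split.fraction})")
example = split.train[0]
print(f"example pair: {example.target_id} motif[{len(example.motif_text)} aa] "
      f"-> {example.canonical_smiles}")
# Each pair couples one kinase's extended motif with the canonical SMILES of
# one of its inhibitors; a compound active on k targets contributes k pairs.
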