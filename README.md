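# motif2mol

Target-conditioned molecule generation from protein binding-site sequence
motifs, via a biochemical language model.

## The problem

Most generative models for drug design condition on known ligands or on a
3D structure of the target.  motif2mol instead treats compound design as
**machine translation from protein sequence to chemical structure**: the
source sentence is a short amino-acid motif describing a target's
ligand-binding region, the target sentence is the SMILES string of an
active compound.  Trained on (motif, inhibitor) pairs across a protein
family, the model generates candidate actives for any family member —
including targets it never saw — from sequence alone.

The proof-of-concept domain is protein kinases.  The PROSITE protein
kinase ATP-binding region signature (PS00107) locates the ATP-binding
region in a kinase sequence (a 21–34 residue match); the match extended
by the following 150 residues forms the model input, carrying
kinase-specific binding-site information without the essentially
invariant remainder of the catalytic domain.

## The model

An encoder–decoder transformer.  For a motif *m* = (a₁ … a_k) and SMILES
token sequence *s* = (s₁ … s_L), the model factorizes

    P(s | m) = ∏ₜ P(sₜ | s₁ … sₜ₋₁, m)

with the encoder embedding the motif (512-dim tokens + sinusoidal
positional encodings; 3 modules of 8-head self-attention + feed-forward)
and the decoder attending causally to its own prefix and by
cross-attention to the encoder states.  Training minimizes token-level
cross-entropy with teacher forcing on an 80/20 pair-level split.
Generation draws tokens with probability ∝ exp(logit/T) (temperature
sampling, T = 1.0) until EOS.

Candidate sets A are scored against known actives B by:

* **validity** — N_valid/N_all under RDKit parsing;
* **1NN Sim_max(A,B)** = max_{a∈A} max_{b∈B} Tc(a,b) and
  **1NN Sim_ave(A,B)** = (1/|A|) Σ_{a∈A} max_{b∈B} Tc(a,b), with Tc the
  Tanimoto coefficient on 2048-bit Morgan fingerprints of radius 3;
* **reproduction** — the number of known actives whose canonical SMILES
  appears verbatim among the candidates (stricter than Tc = 1.0).

The network and training loop are written on numpy with reverse-mode
automatic differentiation (HIPS autograd), so the whole model is a dict
of float arrays and every run is exactly reproducible from its seeds.

## Worked example

Locating a binding-site motif (`examples/01_signature_scan.py`):

```text
signature: [LIV]-G-{P}-G-{P}-[FYWMGSTNH]-[SGA]-{PW}-[LIVCAT]-{PD}-x-[GSTACLIVMFY]-x(5,18)-[LIVMFYWCSTAR]-[AIVP]-[LIVMFAGCKR]-K
match length bounds: 21-34 residues
match at [40, 70) (30 residues)
matched segment: VGQGLHAAAAETWMPYRPMNWGTQAIWPAK
extended motif length: 180 residues
```

The signature's parsed length bounds (21–34) are the sum of per-element
minimum and maximum repeats; the extracted motif is the leftmost,
shortest signature match plus exactly 150 downstream residues.

Scoring a generated set (`examples/04_evaluate.py`):

```text
validity: 3/4 = 0.75
1-NN similarity: max 1.000, average 0.541
known actives exactly reproduced: 1
sequence identity of two related motifs: 84.6%
```

One of four raw strings fails RDKit parsing (validity 0.75); among the
valid ones, the best candidate is identical to a known active
(1NN Sim_max = 1.0, one exact reproduction), while the average best
similarity over candidates is 0.541.

`examples/02_curation.py` walks through activity filtering and the
pair-level 80/20 split, and `examples/03_train_and_sample.py` trains a
miniature model on a synthetic kinome and samples candidates with both
run protocols (until-unique and fixed-runs).

The same pipeline is scriptable from the shell:

```bash
motif2mol synth  --targets 20 --compounds 25 --seed 1 --out data/
motif2mol curate --activities data/activities.tsv --fasta data/targets.fasta --seed 1 --out curated/
motif2mol train  --pairs curated/pairs.tsv --preset tiny --epochs 30 --seed 1 --out model.npz
motif2mol sample --model model.npz --fasta data/targets.fasta --mode until-unique --n 20 --seed 1 --out samples.tsv
motif2mol evaluate --samples samples.tsv --known curated/pairs.tsv --out report.tsv
```

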