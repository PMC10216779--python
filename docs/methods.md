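# Methods

## Problem and approach

Predicting new active compounds directly from protein sequence is framed
here as machine translation: the source "sentence" is a kinase's
ligand-binding-site sequence motif and the target "sentence" is the SMILES
string of an inhibitor.  The motif is not the whole protein sequence: the
PROSITE protein kinase ATP-binding region signature (accession PS00107)
locates the ATP-binding region (a 21–34 residue match), and the match plus
the following 150 residues forms the *extended sequence signature* used as
model input.  This keeps kinase-specific binding-site information while
excluding distant, essentially invariant parts of the catalytic domain.

The pipeline has five stages, each an importable module:

1. **prosite_motif** — parse the signature, scan sequences, extract motifs.
2. **curation** — filter a ChEMBL-style activity table, canonicalize
   structures, enumerate (motif, compound) pairs, split 80/20.
3. **tokenization / seq2seq_model** — token streams, vocabularies, and the
   encoder–decoder transformer with its training loop.
4. **sampling** — temperature sampling of candidate SMILES under two run
   protocols.
5. **evaluation** — validity, 1-NN fingerprint similarity, exact
   reproduction counts, and inter-target sequence identity.

A sixth module, **synthetic**, generates a toy kinome so that the whole
chain runs and is testable without any database access.

## Motif extraction

PROSITE patterns are parsed into an element list (fixed residue, allowed
set `[...]`, excluded set `{...}`, wildcard `x` with repeat ranges) and
compiled to a regular expression over the 20 standard residues.  Wildcard
repeats compile non-greedily, so scanning returns the *leftmost* match
and, at that position, the *shortest* expansion — a deterministic
convention for the rare sequences with multiple signature hits.  The
150-residue extension participates in the search as a lookahead: a match
without 150 downstream residues is passed over, and a target with no
qualifying match is excluded rather than padded.  Sequences containing
non-standard residue codes (B, Z, X, U) are rejected with a logged
warning, since the model vocabulary covers the 20 standard residues.
Coordinates are 0-based half-open internally.

## Curation rules

Records are kept when pIC50 ≥ 6 (IC50 ≤ 1 µM) *and* target confidence = 9,
both thresholds inclusive; a compound with several measurements is kept if
any one passes (values are never aggregated).  Structures are
RDKit-canonicalized; invalid SMILES are dropped and counted.  Pairs are
unique on (target, canonical structure), so a compound active on k targets
contributes k pairs.  All pairs are pooled and split at the *pair* level:
a seeded uniform permutation with the first floor(0.8·n) pairs as
training data.  The floor rule is the one consistent with a 62,462-pair
pool splitting into 49,969 + 12,493.  Held-out evaluation targets are
excluded from curation entirely, before filtering.

## Tokenization

Motifs use one token per residue.  SMILES use the de-facto standard regex
scheme: bracket atoms `[...]`, the two-letter halogens `Cl`/`Br`, and
`%nn` ring closures are atomic tokens; every other character stands alone.
Character-level splitting would break `Cl` into carbon + lowercase-L and
destroy chemical round-tripping.  Vocabularies hold PAD/BOS/EOS/UNK at
indices 0–3 followed by the observed tokens in sorted order, so identical
corpora always produce identical vocabularies and hence reproducible
checkpoints.

## Model

A standard encoder–decoder transformer: scaled token embeddings plus
sinusoidal positional encodings; encoder modules of multi-head
self-attention and a feed-forward sub-layer; decoder modules of causal
(masked) self-attention, cross-attention over encoder states, and a
feed-forward sub-layer; residual connections with layer normalization;
a linear projection to target-vocabulary logits.  Normalization is
*pre*-norm (each sub-layer reads a normalized copy of the residual
stream, with a final norm after each stack): pre-norm transformers train
stably at the large step sizes that short desk-scale schedules need,
where the classic post-norm arrangement requires long warmup.  The
full-scale preset is d_model 512, 8 heads, 3+3 modules, feed-forward 512.
Training minimizes token-level cross-entropy over non-PAD positions with
teacher forcing (decoder input right-shifted behind BOS), using
Adam(betas (0.9, 0.98), eps 1e-9) — the standard machine-translation
recipe settings, with default peak lr 1e-4 for the full preset — under a
schedule of linear warmup over the first 5% of steps followed by cosine
decay to 10% of the peak, with per-epoch shuffled minibatches of 32 and
no early stopping: the final-epoch model is the result.

The network is implemented on numpy with reverse-mode automatic
differentiation (HIPS autograd); the model is a flat dict of float32
arrays and every stage (init, shuffling, dropout, sampling) draws from
seeded generators, so runs are exactly reproducible on a platform.
Numerical choices: attention masking is additive (−10⁹ at masked
positions) ahead of a max-subtracted softmax; layer-norm epsilon 1e-5;
dropout (default 0.1) applied to embeddings, sub-layer outputs and the
feed-forward hidden layer but not to the attention-weight tensor, whose
regularization costs more than the rest of the pass combined and adds
little at these model sizes.  Over-long sequences are truncated to the
configured maxima (source 200, target 150 tokens) with a warning.

### Desk-scale preset

All desk-scale experiments use a reduced preset — d_model 64, 4 heads,
2+2 modules, feed-forward 128 — with learning rate 1e-3: a model this
small trained for a few hundred steps needs a larger step size than the
full-scale recipe's 1e-4, which is kept as the default for the full
preset.  The memorization check drives this preset to overfit a single
pair (400 epochs, lr 2e-3, batch 1, dropout off — dropout exists
precisely to impede memorization) until greedy decoding reproduces the
training SMILES exactly and T = 1 sampling returns it almost surely.

## Sampling

One sampling run is one autoregressive decode: tokens drawn with
probability ∝ exp(logit/T), stopping at EOS or the 150-token cap (a decode
hitting the cap counts as invalid).  T → 0 recovers greedy decoding.  Two
protocols mirror the two evaluation settings: sampling *until* a fixed
number of unique valid structures is reached (training/validation
targets; the number of runs needed is itself a statistic), and a fixed
number of runs (held-out targets).  Uniqueness is judged on canonical
SMILES; the cap for the until-unique protocol defaults to 100 × the
requested count so degenerate models terminate with a flagged partial
result.  Runs execute in parallel batches for throughput, but each run
owns a child RNG derived from (seed, run index), so results are
independent of batch size and a longer campaign is an exact extension of
a shorter one.

## Evaluation

* **Validity** — N_valid/N_all under RDKit parsing with valence checks.
* **1-NN similarity** — 2048-bit Morgan fingerprints of radius 3; for each
  generated structure a ∈ A the best Tanimoto coefficient over known
  actives b ∈ B; summarized as the maximum (1NN Sim_max) and the mean
  (1NN Sim_ave) over A.  Computed over the unique valid set.  The Tanimoto
  of two empty fingerprints is defined as 1.0 (identical absence) and
  logged when it occurs.
* **Reproduction** — a known active counts as reproduced only when its
  canonical SMILES appears verbatim among the candidates.  This is
  deliberately stricter than Tc = 1.0, which folded fingerprints also
  assign to nearly identical pairs (e.g. long-chain homologs).
* **Sequence identity** — optimal global alignment with BLOSUM62 and
  affine gaps (open −10, extend −0.5; only the matrix is fixed by the
  method, the gap penalties are surfaced as arguments); identity =
  identical aligned pairs / alignment length × 100.

## Synthetic kinome

The generator emulates the statistical shape the pipeline assumes, not
kinase biology.  Each target sequence is a 20–60 residue random prefix,
one random instantiation of the signature, and extension + 30 downstream
residues, so every target yields exactly one motif.  Chemistry is tied to
sequence deterministically: a CRC-32 hash of the instantiated signature
segment selects one of 8 asymmetric two-slot scaffold templates and a
7-member substituent pool (from a fixed list of 30 simple groups);
actives are scaffold + ordered substituent pairs, assembled by template
and therefore valid by construction, with pIC50 ~ U[6.1, 9.0] at
confidence 9.  Decoy records (20% of the table) fail the potency or
confidence filter and must vanish during curation.  Per-target active
counts follow a deterministic linear ramp from ~1.8× down to ~0.2× the
nominal count (default 25, so 45 down to 5 across 20 targets), emulating
the wide spread of available inhibitors per kinase in real extractions
and providing the training-set-size gradient that the
similarity-vs-data-volume trend analysis requires.

Held-out targets come in two tiers.  *High*: a training target's sequence
with ≤ 3 residue edits inside the signature segment (global identity
> 50%, verified by alignment), keeping the base target's chemistry —
the realistic premise that near-identical binding sites bind the same
compounds.  *Low*: a fresh random sequence verified to have ≤ 50%
identity to every training target, with its own hash-derived chemistry.

What passing on this generator shows: that the implementation learns a
motif→chemistry mapping when one exists, reproduces known actives of
seen and near-seen targets, and that every metric and filter behaves as
specified.  What it does not show: performance on real kinome data, where
motif–chemistry relations are vastly noisier, activity cliffs exist, and
chemical space is not a scaffold/substituent grid.

## Experiment sizes

The bundled experiments run on a single CPU: the reference kinome is 20
targets with a nominal 25 actives each (~500 actives plus decoys, ~400
training pairs), trained for 30 epochs on the reduced preset with batch
size 8 and peak lr 2e-3; candidate generation asks for 20 unique
structures per target; the held-out analysis performs 1000 runs under
each of 5 sampling seeds.  The batch size shrinks with the data: at 400
training pairs a batch of 32 would leave an epoch with 13 optimization
steps, so the desk-scale run uses batch 8 to keep a meaningful number of
updates (1500 total) while the full-scale preset retains the recipe's
batch 32.  The
full-scale preset (512-dim, 3+3 modules, 100 epochs) is exposed in the
API and CLI for users with the hardware and a real ChEMBL export.

## Known limitations

* The full-scale configuration is implemented but not exercised by the
  bundled experiments; no GPU path exists.
* No salt stripping or tautomer standardization beyond RDKit
  canonicalization; the activity-table contract assumes one parent
  structure per row.
* Profile-based (PSSM/HMM) motif detection is out of scope; only the
  single leftmost-shortest signature match is used.
* Sampling modifies the learned distribution by temperature only (no
  nucleus/top-k truncation, beam search, or property conditioning).
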