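"""Token streams and vocabularies for motifs (source) and SMILES (target).

Motifs tokenize one residue per token.  SMILES use the standard regex
scheme: bracket atoms ``[...]``, the two-letter halogens Cl/Br, and
``%nn`` ring closures stay atomic; everything else is one character.
Character-level splitting of e.g. Cl would make round-tripped strings
chemically different, so the regex scheme is required for validity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Sequence

from .prosite import STANDARD_AA

PAD, BOS, EOS, UNK = "<pad>", "<bos>", "<eos>", "<unk>"
SPECIALS = (PAD, BOS, EOS, UNK)
PAD_IDX, BOS_IDX, EOS_IDX, UNK_IDX = 0, 1, 2, 3

_AA_SET = frozenset(STANDARD_AA)

_SMILES_TOKEN_RE = re.compile(
    r"(\[[^\]]*\]|Br|Cl|%\d{2}|.)"
)


def tokenize_motif(motif_text: str) -> List[str]:
    """One token per residue, wrapped BOS ... EOS."""
    bad = sorted({c for c in motif_text if c not in _AA_SET})
    if bad:
        raise ValueError(f"unknown residue codes {bad} in motif")
    return [BOS, *motif_text, EOS]


def tokenize_smiles(smiles: str) -> List[str]:
    """Regex SMILES tokens wrapped BOS ... EOS.

    Raises ``ValueError`` on an unmatched '[' (an unterminated bracket atom).
    """
    if smiles.count("[") != smiles.count("]"):
        raise ValueError(f"unmatched bracket in SMILES: {smiles!r}")
    tokens = _SMILES_TOKEN_RE.findall(smiles)
    if "".join(tokens) != smiles:
        raise ValueError(f"SMILES tokenization failed for {smiles!r}")
    return [BOS, *tokens, EOS]


def detokenize(tokens: Sequence[str]) -> str:
    """Invert tokenization: strip specials, join the rest."""
    return "".join(t for t in tokens if t not in SPECIALS)


@dataclass(frozen=True)
class Vocab:
    """Bijective token<->index mapping with fixed special indices 0-3."""

    token_to_index: Dict[str, int]
    index_to_token: Dict[int, str]

    def __len__(self) -> int:
        return len(self.token_to_index)

    def encode(self, tokens: Sequence[str]) -> List[int]:
        t2i = self.token_to_index
        return [t2i.get(t, UNK_IDX) for t in tokens]

    def decode(self, indices: Sequence[int]) -> List[str]:
        return [self.index_to_token[int(i)] for i in indices]


def build_vocab(corpus: Iterable[Sequence[str]]) -> Vocab:
    """Vocabulary over a token-list corpus: specials 0-3, then sorted tokens.

    Deterministic given the token set, so two runs over identical data
    produce identical vocabularies (and hence reproducible checkpoints).
    """
    observed = set()
    n_lists = 0
    for tokens in corpus:
        n_lists += 1
        observed.update(tokens)
    if n_lists == 0:
        raise ValueError("empty corpus")
    ordered = list(SPECIALS) + sorted(observed - set(SPECIALS))
    t2i = {t: i for i, t in enumerate(ordered)}
    return Vocab(token_to_index=t2i, index_to_token={i: t for t, i in t2i.items()})


def save_vocab(vocab: Vocab, path) -> None:
    """Plain text, one token per line; index = line number."""
    lines = [vocab.index_to_token[i] for i in range(len(vocab))]
    Path(path).write_text("\n".join(lines) + "\n")


def load_vocab(path) -> Vocab:
    tokens = Path(path).read_text().splitlines()
    t2i = {t: i for i, t in enumerate(tokens)}
    if [t2i.get(s) for s in SPECIALS] != [PAD_IDX, BOS_IDX, EOS_IDX, UNK_IDX]:
        raise ValueError(f"vocab file {path} lacks the special tokens at indices 0-3")
    return Vocab(token_to_index=t2i, index_to_token={i: t for t, i in t2i.items()})
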