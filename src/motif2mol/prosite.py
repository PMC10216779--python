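"""PROSITE signature parsing, matching, and binding-site motif extraction.

PROSITE patterns describe conserved protein sequence motifs position by
position: ``[LIV]`` permits Leu/Ile/Val, ``{PW}`` forbids Pro and Trp,
``x`` matches any residue and ``x(5,18)`` a run of 5-18 arbitrary
residues.  A signature match in a kinase marks the ATP-binding region;
the match plus a fixed-length downstream segment (150 residues by
default) forms the extended binding-site motif used as the model input.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 standard one-letter amino-acid codes.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_AA)

#: PROSITE protein kinase ATP-binding region signature (accession PS00107).
#: Its match length ranges over 21-34 residues.
PS00107 = (
    "[LIV]-G-{P}-G-{P}-[FYWMGSTNH]-[SGA]-{PW}-[LIVCAT]-{PD}-x-"
    "[GSTACLIVMFY]-x(5,18)-[LIVMFYWCSTAR]-[AIVP]-[LIVMFAGCKR]-K"
)

#: Default downstream extension length appended to a signature match.
DEFAULT_EXTENSION = 150


class PrositeParseError(ValueError):
    """Raised for malformed PROSITE pattern text.

    Carries ``element_index``, the 0-based index of the offending
    '-'-separated element, or ``None`` for whole-pattern problems.
    """

    def __init__(self, message: str, element_index: Optional[int] = None):
        if element_index is not None:
            message = f"element {element_index}: {message}"
        super().__init__(message)
        self.element_index = element_index


@dataclass(frozen=True)
class PatternElement:
    """One position (or wildcard run) of a PROSITE pattern."""

    kind: str  # 'fixed' | 'allowed' | 'excluded' | 'wildcard'
    residues: frozenset = frozenset()
    min_repeat: int = 1
    max_repeat: int = 1

    def __post_init__(self):
        if self.kind not in ("fixed", "allowed", "excluded", "wildcard"):
            raise ValueError(f"unknown element kind {self.kind!r}")
        if not (1 <= self.min_repeat <= self.max_repeat):
            raise ValueError(
                f"invalid repeat range ({self.min_repeat},{self.max_repeat})"
            )
        if self.kind == "wildcard":
            if self.residues:
                raise ValueError("wildcard element carries no residue set")
        else:
            if not self.residues:
                raise ValueError(f"{self.kind} element needs residues")
            if self.kind == "fixed" and len(self.residues) != 1:
                raise ValueError("fixed element must hold exactly one residue")
            bad = set(self.residues) - _STANDARD_SET
            if bad:
                raise ValueError(f"non-standard residue codes {sorted(bad)}")

    @property
    def accepted(self) -> frozenset:
        """Set of residues this element accepts at each of its positions."""
        if self.kind == "excluded":
            return _STANDARD_SET - self.residues
        if self.kind == "wildcard":
            return _STANDARD_SET
        return frozenset(self.residues)


@dataclass(frozen=True)
class ProsPattern:
    """A parsed PROSITE signature: an ordered list of elements."""

    elements: tuple
    source_text: str = ""
    accession_label: Optional[str] = None

    def __post_init__(self):
        if not self.elements:
            raise ValueError("pattern must contain at least one element")


@dataclass(frozen=True)
class SequenceMotif:
    """A target's extracted binding-site motif.

    ``matched_segment`` is the signature match, ``extension`` the fixed-length
    downstream segment; ``motif_text`` is their concatenation.  Coordinates are
    0-based, half-open.
    """

    target_id: str
    match_start: int
    match_end: int
    matched_segment: str
    extension: str

    @property
    def motif_text(self) -> str:
        return self.matched_segment + self.extension


# --- parsing -----------------------------------------------------------------

_REPEAT_RE = re.compile(r"^(.*?)\((\d+)(?:,(\d+))?\)$")
_SET_RE = re.compile(r"^\[([A-Za-z]+)\]$")
_EXCL_RE = re.compile(r"^\{([A-Za-z]+)\}$")


def _parse_element(raw: str, index: int) -> PatternElement:
    m = _REPEAT_RE.match(raw)
    if m:
        core, lo, hi = m.group(1), int(m.group(2)), m.group(3)
        min_rep, max_rep = lo, (int(hi) if hi is not None else lo)
    else:
        core, min_rep, max_rep = raw, 1, 1
    if not core:
        raise PrositeParseError("empty element", index)
    if min_rep < 1 or min_rep > max_rep:
        raise PrositeParseError(
            f"invalid repeat range ({min_rep},{max_rep})", index
        )
    for opener, closer in ("[]", "{}"):
        if core.count(opener) != core.count(closer):
            raise PrositeParseError(f"unbalanced {opener!r}", index)
    try:
        if core in ("x", "X"):
            return PatternElement("wildcard", frozenset(), min_rep, max_rep)
        sm = _SET_RE.match(core)
        if sm:
            return PatternElement(
                "allowed", frozenset(sm.group(1).upper()), min_rep, max_rep
            )
        em = _EXCL_RE.match(core)
        if em:
            return PatternElement(
                "excluded", frozenset(em.group(1).upper()), min_rep, max_rep
            )
        if len(core) == 1 and core.upper() in _STANDARD_SET:
            return PatternElement("fixed", frozenset(core.upper()), min_rep, max_rep)
    except ValueError as exc:
        raise PrositeParseError(str(exc), index) from exc
    raise PrositeParseError(f"unrecognized element {raw!r}", index)


def parse_prosite(pattern_text: str, accession_label: Optional[str] = None) -> ProsPattern:
    """Parse PROSITE pattern syntax into a :class:`ProsPattern`.

    Elements are '-'-separated.  ``[XYZ]`` is an allowed set, ``{XYZ}`` an
    excluded set, ``x`` a wildcard, a bare letter a fixed residue; ``(n)`` or
    ``(n,m)`` suffixes attach repeat counts.  The PROSITE dialect extras -
    N-/C-terminal anchors ``<`` ``>`` and a trailing ``.`` - are accepted and
    ignored.

    Raises :class:`PrositeParseError` naming the offending element index on
    malformed input.
    """
    if pattern_text is None:
        raise PrositeParseError("pattern text is None")
    text = pattern_text.strip()
    if text.endswith("."):
        text = text[:-1]
    if text.startswith("<"):
        text = text[1:]
    if text.endswith(">"):
        text = text[:-1]
    if not text:
        raise PrositeParseError("empty pattern")
    elements = tuple(
        _parse_element(raw.strip(), i) for i, raw in enumerate(text.split("-"))
    )
    return ProsPattern(elements, source_text=pattern_text, accession_label=accession_label)


def length_bounds(pattern: ProsPattern) -> tuple:
    """(min, max) lengths, in residues, of strings the pattern can match."""
    return (
        sum(e.min_repeat for e in pattern.elements),
        sum(e.max_repeat for e in pattern.elements),
    )


# --- matching ----------------------------------------------------------------


def _element_regex(el: PatternElement) -> str:
    cls = "".join(sorted(el.accepted))
    body = cls if len(cls) == 1 else f"[{cls}]"
    if el.min_repeat == el.max_repeat:
        return body if el.min_repeat == 1 else f"{body}{{{el.min_repeat}}}"
    # non-greedy: leftmost-shortest match determinism
    return f"{body}{{{el.min_repeat},{el.max_repeat}}}?"


class Matcher:
    """Compiled PROSITE pattern matcher.

    Wildcard repeats are non-greedy, so scanning yields the leftmost match
    and, at that position, the shortest expansion.
    """

    def __init__(self, pattern: ProsPattern):
        self.pattern = pattern
        self._body = "".join(_element_regex(e) for e in pattern.elements)
        self._regex = re.compile(self._body)

    def fullmatch(self, s: str) -> bool:
        """True iff the whole string is an instance of the pattern."""
        return self._regex.fullmatch(s) is not None

    def search(self, seq: str, min_tail: int = 0):
        """Leftmost-shortest occurrence followed by >= ``min_tail`` residues.

        Returns ``(start, end)`` half-open coordinates, or ``None``.  The
        tail requirement participates in the search: a position whose only
        short expansion leaves too few downstream residues is still matched
        if a longer expansion (or a later position) satisfies it.
        """
        rx = self._regex
        if min_tail > 0:
            rx = re.compile(f"{self._body}(?=.{{{min_tail}}})", re.DOTALL)
        m = rx.search(seq)
        return (m.start(), m.end()) if m else None


def compile_matcher(pattern: ProsPattern) -> Matcher:
    """Compile a pattern into a :class:`Matcher`."""
    return Matcher(pattern)


def instantiate_pattern(pattern: ProsPattern, rng: np.random.Generator) -> str:
    """Draw one random string the pattern accepts (uniform per position)."""
    out = []
    for el in pattern.elements:
        n = int(rng.integers(el.min_repeat, el.max_repeat + 1))
        choices = sorted(el.accepted)
        out.extend(choices[int(i)] for i in rng.integers(0, len(choices), n))
    return "".join(out)


# --- scanning & extraction ---------------------------------------------------


def _check_residues(seq: str) -> None:
    bad = [i for i, c in enumerate(seq) if c not in _STANDARD_SET]
    if bad:
        shown = ", ".join(f"{i}:{seq[i]!r}" for i in bad[:10])
        more = "" if len(bad) <= 10 else f" (+{len(bad) - 10} more)"
        raise ValueError(f"non-standard residues at positions {shown}{more}")


def scan_and_extend(
    seq: str,
    pattern: ProsPattern,
    extension_length: int = DEFAULT_EXTENSION,
    target_id: str = "",
) -> Optional[SequenceMotif]:
    """Extract the extended binding-site motif from a protein sequence.

    Finds the leftmost, shortest signature match followed by at least
    ``extension_length`` residues and returns it together with exactly that
    many downstream residues.  Returns ``None`` when no qualifying match
    exists.  Sequences containing non-standard residue codes raise
    ``ValueError`` listing the offending positions.
    """
    seq = seq.upper()
    _check_residues(seq)
    hit = compile_matcher(pattern).search(seq, min_tail=extension_length)
    if hit is None:
        return None
    start, end = hit
    return SequenceMotif(
        target_id=target_id,
        match_start=start,
        match_end=end,
        matched_segment=seq[start:end],
        extension=seq[end : end + extension_length],
    )


# --- I/O ---------------------------------------------------------------------


def read_fasta(path) -> Iterator:
    """Yield ``(record_id, description, sequence)`` from a FASTA file."""
    for rec in SeqIO.parse(str(path), "fasta"):
        yield rec.id, rec.description, str(rec.seq)


def extract_motifs(
    fasta_path,
    pattern: ProsPattern,
    extension_length: int = DEFAULT_EXTENSION,
):
    """Scan every FASTA record; return ``(motifs, rejected)``.

    ``rejected`` maps target id -> reason.  Targets whose sequence contains
    non-standard residues, has no signature match, or lacks the downstream
    extension are rejected (with a logged warning), never padded.
    """
    motifs = []
    rejected = {}
    for target_id, _desc, seq in read_fasta(fasta_path):
        try:
            motif = scan_and_extend(seq, pattern, extension_length, target_id)
        except ValueError as exc:
            rejected[target_id] = str(exc)
            logger.warning("target %s rejected: %s", target_id, exc)
            continue
        if motif is None:
            rejected[target_id] = (
                f"no signature match with >= {extension_length} downstream residues"
            )
            logger.warning("target %s rejected: %s", target_id, rejected[target_id])
        else:
            motifs.append(motif)
    return motifs, rejected


def write_motif_table(motifs: Iterable, path) -> None:
    """Write motifs as TSV: target_id, match_start, match_end, matched_segment, motif_text."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("target_id\tmatch_start\tmatch_end\tmatched_segment\tmotif_text\n")
        for m in motifs:
            fh.write(
                f"{m.target_id}\t{m.match_start}\t{m.match_end}\t"
                f"{m.matched_segment}\t{m.motif_text}\n"
            )


def load_pattern(source: str) -> ProsPattern:
    """Resolve a pattern argument: 'PS00107', a pattern string, or a file path."""
    if source.strip().upper() == "PS00107":
        return parse_prosite(PS00107, accession_label="PS00107")
    p = Path(source)
    if p.exists() and p.is_file():
        return parse_prosite(p.read_text(), accession_label=p.stem)
    return parse_prosite(source)
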