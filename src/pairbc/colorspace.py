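"""SOLiD dibase ("color space") encoding and sequence distances.

SOLiD sequencers report reads as a known anchor base followed by a string of
color calls in {0,1,2,3}, where each color encodes a *pair* of adjacent bases.
The dibase scheme used here is the standard one: identical adjacent bases give
color 0, the transversion pairs A-C and G-T give 1, A-G and C-T give 2, and
A-T and C-G give 3.  With bases indexed A=0, C=1, G=2, T=3 this is exactly the
XOR of the two base indices, which makes encoding and decoding one-liners and
gives the scheme its defining properties: each row of the 4x4 matrix is a
bijection (so a color string plus its anchor decodes to a unique nucleotide
sequence), and a single base substitution flips the two adjacent colors (one
at the read's final position).

Distances between equal-length sequences are available in both spaces.  The
color-space distance is computed under a shared anchor base, modelling the
constant adaptor base that precedes a barcode on the read; the junction color
(anchor vs. first barcode base) is included.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, TextIO

__all__ = [
    "BASES",
    "ColorSeq",
    "encode_colors",
    "decode_colors",
    "hamming_nt",
    "hamming_color",
    "read_csfasta",
    "write_csfasta",
    "read_qual",
]

BASES = "ACGT"
_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COLORS = "0123"


class SequenceError(ValueError):
    """Invalid nucleotide or color symbol in an input sequence."""


@dataclass(frozen=True)
class ColorSeq:
    """A color-space sequence: digits in {0,1,2,3} plus the anchor base
    required to decode them back to nucleotides."""

    colors: str
    anchor: str

    def __post_init__(self) -> None:
        if self.anchor not in _IDX:
            raise SequenceError(f"anchor must be one of {BASES}, got {self.anchor!r}")
        for i, c in enumerate(self.colors):
            if c not in _COLORS:
                raise SequenceError(f"invalid color {c!r} at position {i}")

    def __len__(self) -> int:
        return len(self.colors)

    def decode(self) -> str:
        return decode_colors(self.colors, self.anchor)


def _check_nt(seq: str) -> None:
    for i, b in enumerate(seq):
        if b not in _IDX:
            raise SequenceError(f"invalid base {b!r} at position {i}")


def encode_colors(seq: str, anchor: str = "T") -> str:
    """Encode a nucleotide sequence as SOLiD colors given the preceding base.

    Parameters
    ----------
    seq : str
        Nucleotide sequence over ACGT (upper case).
    anchor : str
        The known base immediately 5' of ``seq`` (the primer/adaptor base on
        a SOLiD read).  The first color encodes the (anchor, seq[0]) pair.

    Returns
    -------
    str
        Color digits, one per base of ``seq``.
    """
    if anchor not in _IDX:
        raise SequenceError(f"anchor must be one of {BASES}, got {anchor!r}")
    _check_nt(seq)
    out = []
    prev = _IDX[anchor]
    for b in seq:
        cur = _IDX[b]
        out.append(_COLORS[prev ^ cur])
        prev = cur
    return "".join(out)


def decode_colors(colors: str, anchor: str = "T") -> str:
    """Invert :func:`encode_colors`: recover the nucleotide sequence from a
    color string and its anchor base."""
    if anchor not in _IDX:
        raise SequenceError(f"anchor must be one of {BASES}, got {anchor!r}")
    out = []
    prev = _IDX[anchor]
    for i, c in enumerate(colors):
        if c not in _COLORS:
            raise SequenceError(f"invalid color {c!r} at position {i}")
        prev ^= int(c)
        out.append(BASES[prev])
    return "".join(out)


def hamming(a: str, b: str) -> int:
    """Hamming distance between two equal-length symbol strings."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def hamming_nt(a: str, b: str) -> int:
    """Nucleotide-space Hamming distance (validates the alphabet)."""
    _check_nt(a)
    _check_nt(b)
    return hamming(a, b)


def hamming_color(a: str, b: str, anchor: str = "T") -> int:
    """Hamming distance between the color encodings of two nucleotide
    sequences under a shared anchor base.

    A substitution at an internal position flips two colors; at the terminal
    position it flips one, so this distance can be lower than twice the
    nucleotide distance when adjacent substitutions share a color.
    """
    return hamming(encode_colors(a, anchor), encode_colors(b, anchor))


# ---------------------------------------------------------------------------
# csfasta / QV I/O
#
# csfasta is FASTA-like: '>' header lines, then a sequence line consisting of
# the anchor base followed by color digits (e.g. "T01230...").  Quality values
# travel in a parallel .QV file with the same headers and space-separated
# integer scores, one per color call.
# ---------------------------------------------------------------------------


def read_csfasta(handle: TextIO | str) -> Iterator[tuple[str, ColorSeq]]:
    """Yield ``(read_id, ColorSeq)`` records from a csfasta file.

    Comment lines starting with '#' are skipped, as written by SOLiD primary
    analysis.
    """
    close = False
    if isinstance(handle, str):
        handle = open(handle)
        close = True
    try:
        rid = None
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                rid = line[1:].split()[0]
            else:
                if rid is None:
                    raise SequenceError("csfasta sequence line before any header")
                yield rid, ColorSeq(colors=line[1:], anchor=line[0])
                rid = None
    finally:
        if close:
            handle.close()


def write_csfasta(records: Iterable[tuple[str, ColorSeq]], handle: TextIO) -> int:
    """Write ``(read_id, ColorSeq)`` records in csfasta format; returns the
    number of records written."""
    n = 0
    for rid, cs in records:
        handle.write(f">{rid}\n{cs.anchor}{cs.colors}\n")
        n += 1
    return n


def read_qual(handle: TextIO | str) -> Iterator[tuple[str, list[int]]]:
    """Yield ``(read_id, scores)`` from a SOLiD .QV quality file."""
    close = False
    if isinstance(handle, str):
        handle = open(handle)
        close = True
    try:
        rid = None
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                rid = line[1:].split()[0]
            else:
                if rid is None:
                    raise SequenceError("QV scores line before any header")
                yield rid, [int(x) for x in line.split()]
                rid = None
    finally:
        if close:
            handle.close()
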