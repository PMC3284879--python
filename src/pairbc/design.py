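"""Barcode set design, validation and multiplex planning.

Pair-barcoding codes each sample by the combination of one forward (F) and
one reverse (R) 6-nt barcode, so N pooled samples need only about 2*sqrt(N)
distinct tagged oligos instead of N.  To keep decoding unambiguous under a
one-mismatch tolerance, every pair of barcodes in a set must differ at >= 3
nucleotide positions; because SOLiD maps reads in color space, sets are
additionally required to differ at >= 2 color positions under the shared
anchor base.  Both floors are enforced conjunctively by default and each can
be relaxed independently.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence, TextIO

import numpy as np

from .colorspace import BASES, encode_colors, hamming_nt

__all__ = [
    "Barcode",
    "BarcodeSet",
    "MultiplexPlan",
    "PairAssignment",
    "DesignError",
    "design_set",
    "validate_set",
    "plan_oligos",
    "plan_single",
    "assign_pairs",
    "read_barcode_tsv",
    "write_barcode_tsv",
    "read_barcode_fasta",
]


class DesignError(ValueError):
    """Raised when a barcode design request cannot be satisfied."""


@dataclass(frozen=True)
class Barcode:
    id: str
    seq: str
    role: str = "forward"  # "forward" | "reverse"


@dataclass
class BarcodeSet:
    """A set of equal-length barcodes with pairwise-distance guarantees.

    ``min_d_nt`` / ``min_d_color`` record the floors the set was designed or
    validated against; ``anchor`` is the fixed adaptor base 5' of the barcode
    under which color encodings are computed.
    """

    barcodes: list[Barcode]
    min_d_nt: int = 3
    min_d_color: int = 2
    anchor: str = "T"
    _color_cache: dict[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        lengths = {len(b.seq) for b in self.barcodes}
        if len(lengths) > 1:
            raise DesignError(f"mixed barcode lengths in set: {sorted(lengths)}")

    def __len__(self) -> int:
        return len(self.barcodes)

    def __iter__(self) -> Iterator[Barcode]:
        return iter(self.barcodes)

    @property
    def length(self) -> int:
        return len(self.barcodes[0].seq) if self.barcodes else 0

    @property
    def ids(self) -> list[str]:
        return [b.id for b in self.barcodes]

    @property
    def seqs(self) -> list[str]:
        return [b.seq for b in self.barcodes]

    def colors(self, seq: str) -> str:
        """Color encoding of a barcode sequence under the set's anchor
        (cached; decoding compares thousands of windows per barcode)."""
        cs = self._color_cache.get(seq)
        if cs is None:
            cs = encode_colors(seq, self.anchor)
            self._color_cache[seq] = cs
        return cs


@dataclass(frozen=True)
class MultiplexPlan:
    """Oligo budget for pooling ``n_samples`` with pair-barcoding."""

    n_samples: int
    n_forward: int
    n_reverse: int

    @property
    def total_oligos(self) -> int:
        return self.n_forward + self.n_reverse

    def __post_init__(self) -> None:
        if self.n_forward * self.n_reverse < self.n_samples:
            raise DesignError(
                f"{self.n_forward} F x {self.n_reverse} R barcodes address only "
                f"{self.n_forward * self.n_reverse} samples, need {self.n_samples}"
            )


@dataclass
class PairAssignment:
    """sample_id -> (forward barcode id, reverse barcode id), unique pairs."""

    entries: list[tuple[str, str, str]]

    def __post_init__(self) -> None:
        pairs = [(f, r) for _, f, r in self.entries]
        if len(set(pairs)) != len(pairs):
            raise DesignError("duplicate (F,R) pair in assignment")
        samples = [s for s, _, _ in self.entries]
        if len(set(samples)) != len(samples):
            raise DesignError("duplicate sample id in assignment")

    def __len__(self) -> int:
        return len(self.entries)

    def sample_of(self) -> dict[tuple[str, str], str]:
        return {(f, r): s for s, f, r in self.entries}

    @classmethod
    def from_csv(cls, handle: TextIO | str) -> "PairAssignment":
        """Read a sample sheet CSV with header sample_id,f_barcode,r_barcode."""
        close = isinstance(handle, str)
        fh = open(handle) if close else handle
        try:
            entries = []
            header = fh.readline().strip().split(",")
            if [h.strip().lower() for h in header[:3]] != ["sample_id", "f_barcode", "r_barcode"]:
                raise DesignError(
                    "sample sheet must start with header sample_id,f_barcode,r_barcode"
                )
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                parts = [p.strip() for p in line.split(",")]
                if len(parts) < 3:
                    raise DesignError(f"malformed sample sheet line: {line!r}")
                entries.append((parts[0], parts[1], parts[2]))
        finally:
            if close:
                fh.close()
        return cls(entries)

    def to_csv(self, handle: TextIO) -> None:
        handle.write("sample_id,f_barcode,r_barcode\n")
        for s, f, r in self.entries:
            handle.write(f"{s},{f},{r}\n")


def _has_long_homopolymer(seq: str, max_run: int = 3) -> bool:
    run, prev = 0, ""
    for b in seq:
        run = run + 1 if b == prev else 1
        prev = b
        if run > max_run:
            return True
    return False


def _compatible(cand: str, accepted: Sequence[str], min_d_nt: int,
                min_d_color: int, anchor: str) -> bool:
    for s in accepted:
        if min_d_nt and hamming_nt(cand, s) < min_d_nt:
            return False
        if min_d_color:
            # color distance under the shared anchor
            ca = encode_colors(cand, anchor)
            cb = encode_colors(s, anchor)
            if sum(x != y for x, y in zip(ca, cb)) < min_d_color:
                return False
    return True


def design_set(
    n: int,
    length: int = 6,
    min_d_nt: int = 3,
    min_d_color: int = 2,
    anchor: str = "T",
    seed: int = 0,
    forbid_homopolymer: bool = False,
    role: str = "forward",
    id_prefix: str | None = None,
) -> BarcodeSet:
    """Design ``n`` barcodes of ``length`` nt satisfying both distance floors.

    Candidates are scanned greedily in a seeded-random order; a candidate is
    accepted iff it keeps nucleotide distance >= ``min_d_nt`` and color
    distance >= ``min_d_color`` (under ``anchor``) to every accepted barcode.
    Deterministic for a fixed seed.  Setting either floor to 0 disables it.

    Raises
    ------
    DesignError
        If the candidate space is exhausted before ``n`` barcodes are found;
        the message names the achieved set size.
    """
    if n < 1:
        raise DesignError("need n >= 1 barcodes")
    rng = np.random.default_rng(seed)
    if 4 ** length <= 1 << 18:
        candidates = ["".join(p) for p in itertools.product(BASES, repeat=length)]
        rng.shuffle(candidates)
    else:
        # long barcodes: random sampling with a generous attempt cap
        cap = max(200_000, 200 * n)
        candidates = (
            "".join(BASES[i] for i in rng.integers(0, 4, size=length))
            for _ in range(cap)
        )

    accepted: list[str] = []
    seen: set[str] = set()
    for cand in candidates:
        if cand in seen:
            continue
        seen.add(cand)
        if forbid_homopolymer and _has_long_homopolymer(cand):
            continue
        if _compatible(cand, accepted, min_d_nt, min_d_color, anchor):
            accepted.append(cand)
            if len(accepted) == n:
                break
    if len(accepted) < n:
        raise DesignError(
            f"requested {n} barcodes but the search saturated at {len(accepted)} "
            f"(length={length}, min_d_nt={min_d_nt}, min_d_color={min_d_color})"
        )
    prefix = id_prefix or ("F" if role == "forward" else "R")
    barcodes = [Barcode(f"{prefix}{i + 1}", s, role) for i, s in enumerate(accepted)]
    return BarcodeSet(barcodes, min_d_nt=min_d_nt, min_d_color=min_d_color, anchor=anchor)


def validate_set(bset: BarcodeSet) -> list[tuple[str, str, int, int]]:
    """Check every barcode pair against the set's distance floors.

    Returns a list of violations ``(id_a, id_b, d_nt, d_color)``; empty iff
    the set's invariants hold.  Duplicate sequences always violate (d=0).
    """
    violations = []
    for a, b in itertools.combinations(bset.barcodes, 2):
        d_nt = hamming_nt(a.seq, b.seq)
        ca, cb = bset.colors(a.seq), bset.colors(b.seq)
        d_color = sum(x != y for x, y in zip(ca, cb))
        if d_nt < bset.min_d_nt or d_color < bset.min_d_color or d_nt == 0:
            violations.append((a.id, b.id, d_nt, d_color))
    return violations


def plan_oligos(n_samples: int) -> MultiplexPlan:
    """Minimal pair-barcode oligo budget for ``n_samples``.

    Minimizes n_forward + n_reverse subject to n_forward * n_reverse >=
    n_samples; ties are broken toward the most balanced split with
    n_forward >= n_reverse (10 samples -> 4 F + 3 R = 7 oligos).
    """
    if n_samples < 1:
        raise DesignError("need n_samples >= 1")
    best: tuple[int, int, int, int] | None = None  # (total, imbalance, nF, nR)
    for b in range(1, math.isqrt(n_samples) + 2):
        a = -(-n_samples // b)  # ceil
        a, b = max(a, b), min(a, b)
        key = (a + b, a - b, a, b)
        if best is None or key[:2] < best[:2]:
            best = key
    assert best is not None
    _, _, a, b = best
    return MultiplexPlan(n_samples=n_samples, n_forward=a, n_reverse=b)


def plan_single(n_samples: int) -> int:
    """Oligo count for conventional single-barcode pooling: one tagged oligo
    per sample."""
    if n_samples < 1:
        raise DesignError("need n_samples >= 1")
    return n_samples


def assign_pairs(
    f_set: BarcodeSet, r_set: BarcodeSet, sample_ids: Sequence[str]
) -> PairAssignment:
    """Assign each sample a unique (F,R) barcode pair, row-major: all R
    barcodes for the first F barcode, then the next F."""
    capacity = len(f_set) * len(r_set)
    if capacity < len(sample_ids):
        raise DesignError(
            f"{len(f_set)} F x {len(r_set)} R barcodes address {capacity} samples, "
            f"need {len(sample_ids)}"
        )
    entries = []
    for i, sid in enumerate(sample_ids):
        f = f_set.barcodes[i // len(r_set)]
        r = r_set.barcodes[i % len(r_set)]
        entries.append((sid, f.id, r.id))
    return PairAssignment(entries)


# ---------------------------------------------------------------------------
# barcode set files: TSV (id \t sequence \t role) or FASTA with a role tag
# ---------------------------------------------------------------------------


def write_barcode_tsv(bset: BarcodeSet, handle: TextIO) -> None:
    handle.write("id\tsequence\trole\n")
    for b in bset.barcodes:
        handle.write(f"{b.id}\t{b.seq}\t{b.role}\n")


def read_barcode_tsv(
    handle: TextIO | str, min_d_nt: int = 3, min_d_color: int = 2, anchor: str = "T"
) -> BarcodeSet:
    close = isinstance(handle, str)
    fh = open(handle) if close else handle
    try:
        barcodes = []
        first = True
        for line in fh:
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if first and parts[0].lower() == "id":
                first = False
                continue
            first = False
            bid, seq = parts[0], parts[1].upper()
            role = parts[2] if len(parts) > 2 else "forward"
            barcodes.append(Barcode(bid, seq, role))
    finally:
        if close:
            fh.close()
    return BarcodeSet(barcodes, min_d_nt=min_d_nt, min_d_color=min_d_color, anchor=anchor)


def read_barcode_fasta(
    handle: TextIO | str, min_d_nt: int = 3, min_d_color: int = 2, anchor: str = "T"
) -> BarcodeSet:
    """FASTA barcode set; role taken from a ``role=`` tag in the header if
    present, else "forward"."""
    from Bio import SeqIO

    barcodes = []
    for rec in SeqIO.parse(handle, "fasta"):
        role = "forward"
        for tok in rec.description.split():
            if tok.startswith("role="):
                role = tok[5:]
        barcodes.append(Barcode(rec.id, str(rec.seq).upper(), role))
    return BarcodeSet(barcodes, min_d_nt=min_d_nt, min_d_color=min_d_color, anchor=anchor)


def write_plan_tsv(plans: Iterable[MultiplexPlan], handle: TextIO) -> None:
    """Tabulate pair-barcode vs single-barcode oligo budgets."""
    handle.write("n_samples\tsingle_barcode_oligos\tpair_n_forward\tpair_n_reverse\tpair_total_oligos\n")
    for p in plans:
        handle.write(
            f"{p.n_samples}\t{plan_single(p.n_samples)}\t{p.n_forward}\t{p.n_reverse}\t{p.total_oligos}\n"
        )
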