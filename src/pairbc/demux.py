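"""Sequential dual-barcode demultiplexing.

Each pair-barcoded read carries the forward barcode (and the small-RNA
insert) on the main read and the reverse barcode either on a separate short
tag read — the two-sequencing-primer layout of the SOLiD protocol — or at a
fixed offset of a single read, as in generic dual-index data.  Decoding is
sequential: the F-barcode is matched first with a one-mismatch tolerance, and
only F-decoded reads proceed to R-barcode matching, so the run-level decode
fractions compose as  both/total = (F/total) x (R-of-F/F).  A window that
matches two barcodes at the same minimal distance within tolerance is
*ambiguous* and the read is left unassigned; a decoded (F,R) pair absent from
the sample sheet is counted separately as an unexpected pair, which is the
cross-contamination diagnostic class.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pandas as pd

from .colorspace import hamming
from .design import BarcodeSet, PairAssignment

__all__ = [
    "ReadRecord",
    "ReadLayout",
    "BarcodeMatch",
    "DecodeResult",
    "DemuxStats",
    "match_barcode",
    "decode_read",
    "demux_run",
    "find_adaptor",
    "FAILURE_CLASSES",
]

FAILURE_CLASSES = (
    "f_none",          # no F-barcode within tolerance
    "f_ambiguous",     # >= 2 F-barcodes tie at minimal distance
    "r_none",
    "r_ambiguous",
    "unexpected_pair",  # both decoded but the pair is not on the sheet
    "malformed",       # record too short / missing tag read
)


@dataclass
class ReadRecord:
    """One sequencing read (plus its optional tag mate carrying the
    R-barcode).  In color mode ``seq``/``mate_seq`` hold color digit strings
    and ``anchor`` the csfasta anchor base."""

    id: str
    seq: str
    qual: str | None = None
    mate_seq: str | None = None
    mate_qual: str | None = None
    anchor: str = "T"


@dataclass
class ReadLayout:
    """Where the barcodes live on a read.

    ``f_span``/``r_span`` are 0-based half-open intervals.  ``r_source`` is
    ``"mate"`` (R-barcode on a separate tag read, the pair-barcode default)
    or ``"read"`` (fixed offset on the main read).  ``adaptor3`` is the 3'
    adaptor whose prefix is trimmed from the insert.  ``space`` selects
    nucleotide or color comparison.
    """

    f_span: tuple[int, int] = (0, 6)
    r_source: str = "mate"
    r_span: tuple[int, int] = (0, 6)
    adaptor3: str = ""
    space: str = "nt"  # "nt" | "color"
    anchor: str = "T"

    def __post_init__(self) -> None:
        if self.r_source not in ("mate", "read"):
            raise ValueError("r_source must be 'mate' or 'read'")
        if self.space not in ("nt", "color"):
            raise ValueError("space must be 'nt' or 'color'")
        if self.r_source == "read":
            f0, f1 = self.f_span
            r0, r1 = self.r_span
            if max(f0, r0) < min(f1, r1):
                raise ValueError("f_span and r_span overlap on the same read")


@dataclass(frozen=True)
class BarcodeMatch:
    status: str  # "unique" | "ambiguous" | "none"
    barcode_id: str | None = None
    distance: int | None = None


def match_barcode(
    window: str,
    bset: BarcodeSet,
    max_mm: int = 1,
    space: str = "nt",
) -> BarcodeMatch:
    """Match an observed barcode window against a set with mismatch tolerance.

    Returns the unique barcode within Hamming distance <= ``max_mm``
    (nucleotide or color space per ``space``; in color mode the window must
    already be color digits and barcodes are compared via their cached color
    encodings under the set's anchor).  Two or more barcodes tying at the
    minimal qualifying distance give ``ambiguous``; none within tolerance
    gives ``none``.
    """
    if len(window) != bset.length:
        raise ValueError(f"window length {len(window)} != barcode length {bset.length}")
    best_d = max_mm + 1
    best: str | None = None
    tied = False
    for b in bset.barcodes:
        target = bset.colors(b.seq) if space == "color" else b.seq
        d = hamming(window, target)
        if d < best_d:
            best_d, best, tied = d, b.id, False
            if d == 0:
                break
        elif d == best_d and best is not None:
            tied = True
    if best is None:
        return BarcodeMatch("none")
    if tied:
        return BarcodeMatch("ambiguous", distance=best_d)
    return BarcodeMatch("unique", best, best_d)


def find_adaptor(
    insert_candidate: str,
    adaptor3: str,
    min_overlap: int = 5,
    max_mm_rate: float = 0.2,
    wildcard_first: bool = False,
) -> int:
    """Locate the 3' adaptor junction in a trimmed read.

    Returns the leftmost position at which a prefix of ``adaptor3`` aligns
    with mismatch rate <= ``max_mm_rate`` over an overlap of >=
    ``min_overlap`` symbols, or ``len(insert_candidate)`` when no such
    position exists (no adaptor content detected).

    ``wildcard_first`` skips the first adaptor position in the comparison —
    used in color space, where the junction color depends on the unknown last
    insert base.
    """
    n, m = len(insert_candidate), len(adaptor3)
    if m == 0:
        return n
    for pos in range(0, n - min_overlap + 1):
        overlap = min(m, n - pos)
        start = 1 if wildcard_first else 0
        if overlap - start <= 0:
            continue
        mm = sum(
            insert_candidate[pos + i] != adaptor3[i] for i in range(start, overlap)
        )
        if mm <= max_mm_rate * (overlap - start):
            return pos
    return n


def decode_read(
    read: ReadRecord,
    sheet: PairAssignment | dict[tuple[str, str], str],
    f_set: BarcodeSet,
    r_set: BarcodeSet,
    layout: ReadLayout,
    max_mm: int = 1,
) -> "DecodeResult":
    """Decode one read: F-barcode first, then (only on success) the R-barcode;
    assign the sample iff both are unique and the pair is on the sheet."""
    pair_to_sample = sheet.sample_of() if isinstance(sheet, PairAssignment) else sheet
    f0, f1 = layout.f_span
    res = DecodeResult(read_id=read.id)

    if len(read.seq) < f1:
        res.failure_class = "malformed"
        return res
    f_match = match_barcode(read.seq[f0:f1], f_set, max_mm, layout.space)
    res.f_status, res.f_id = f_match.status, f_match.barcode_id
    if f_match.status != "unique":
        res.failure_class = "f_none" if f_match.status == "none" else "f_ambiguous"
        return res

    if layout.r_source == "mate":
        source = read.mate_seq
    else:
        source = read.seq
    r0, r1 = layout.r_span
    if source is None or len(source) < r1:
        res.failure_class = "malformed"
        return res
    r_match = match_barcode(source[r0:r1], r_set, max_mm, layout.space)
    res.r_status, res.r_id = r_match.status, r_match.barcode_id
    if r_match.status != "unique":
        res.failure_class = "r_none" if r_match.status == "none" else "r_ambiguous"
        return res

    res.insert = _extract_insert(read, layout)
    sample = pair_to_sample.get((f_match.barcode_id, r_match.barcode_id))
    if sample is None:
        res.failure_class = "unexpected_pair"
    else:
        res.sample_id = sample
    return res


def _extract_insert(read: ReadRecord, layout: ReadLayout) -> str:
    """Insert = main read minus the F-barcode span minus the detected 3'
    adaptor suffix (and minus the R span in single-read mode)."""
    _, f1 = layout.f_span
    rest = read.seq[f1:]
    if layout.r_source == "read":
        r0, r1 = layout.r_span
        if r0 >= f1:  # R-barcode downstream: stop before it
            rest = read.seq[f1:r0]
    if layout.adaptor3:
        if layout.space == "color":
            from .colorspace import encode_colors

            adaptor = encode_colors(layout.adaptor3[1:], layout.adaptor3[0]) if len(
                layout.adaptor3
            ) > 1 else ""
            # junction color (last insert base -> first adaptor base) is
            # unknowable without decoding, so skip one leading color
            cut = find_adaptor(rest, "?" + adaptor, wildcard_first=True)
        else:
            cut = find_adaptor(rest, layout.adaptor3)
        rest = rest[:cut]
    return rest


@dataclass
class DecodeResult:
    read_id: str
    f_status: str = "none"
    f_id: str | None = None
    r_status: str = "none"
    r_id: str | None = None
    sample_id: str | None = None
    insert: str | None = None
    failure_class: str | None = None

    @property
    def assigned(self) -> bool:
        return self.sample_id is not None


@dataclass
class DemuxStats:
    """Run-level decode accounting.

    ``pair_counts`` is the F x R matrix of reads whose two barcodes both
    decoded uniquely (the per-pair read count table of a pooled run); its
    grand total equals ``both_decoded``, and
    both_decoded/total = (f_decoded/total) * (r_decoded_of_f/f_decoded).
    """

    total: int = 0
    f_decoded: int = 0
    r_decoded_of_f: int = 0
    both_decoded: int = 0
    assigned: int = 0
    failures: dict[str, int] = field(default_factory=dict)
    pair_counts: pd.DataFrame | None = None
    sample_counts: dict[str, int] = field(default_factory=dict)

    @property
    def both_decoded_fraction(self) -> float:
        return self.both_decoded / self.total if self.total else 0.0

    @property
    def f_decoded_fraction(self) -> float:
        return self.f_decoded / self.total if self.total else 0.0

    def summary(self) -> dict[str, float | int]:
        out: dict[str, float | int] = {
            "total_reads": self.total,
            "f_decoded": self.f_decoded,
            "r_decoded_of_f": self.r_decoded_of_f,
            "both_decoded": self.both_decoded,
            "assigned": self.assigned,
            "f_decoded_fraction": round(self.f_decoded_fraction, 6),
            "both_decoded_fraction": round(self.both_decoded_fraction, 6),
        }
        for cls in FAILURE_CLASSES:
            out[f"failed_{cls}"] = self.failures.get(cls, 0)
        return out


def demux_run(
    reads: Iterable[ReadRecord],
    sheet: PairAssignment,
    f_set: BarcodeSet,
    r_set: BarcodeSet,
    layout: ReadLayout,
    out_dir: str | None = None,
    max_mm: int = 1,
    collect_results: bool = False,
) -> DemuxStats | tuple[DemuxStats, list[DecodeResult]]:
    """Demultiplex a read stream.

    Every input read lands in exactly one sink: a per-sample insert file or
    the unassigned file (when ``out_dir`` is given), and in exactly one
    accounting bin of the returned :class:`DemuxStats`.  With
    ``collect_results`` the per-read :class:`DecodeResult` list is returned
    too (used for truth-based evaluation of simulated runs).
    """
    pair_to_sample = sheet.sample_of()
    f_ids, r_ids = f_set.ids, r_set.ids
    pair_tally: dict[tuple[str, str], int] = {}
    stats = DemuxStats()
    stats.failures = {cls: 0 for cls in FAILURE_CLASSES}
    stats.sample_counts = {s: 0 for s, _, _ in sheet.entries}

    sinks: dict[str, object] = {}
    results: list[DecodeResult] = []

    def _sink(name: str):
        if out_dir is None:
            return None
        fh = sinks.get(name)
        if fh is None:
            fh = open(os.path.join(out_dir, f"{name}.fasta"), "w")
            sinks[name] = fh
        return fh

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)

    try:
        for read in reads:
            stats.total += 1
            res = decode_read(read, pair_to_sample, f_set, r_set, layout, max_mm)
            if res.f_status == "unique":
                stats.f_decoded += 1
                if res.r_status == "unique":
                    stats.r_decoded_of_f += 1
                    stats.both_decoded += 1
                    key = (res.f_id, res.r_id)
                    pair_tally[key] = pair_tally.get(key, 0) + 1
            if res.assigned:
                stats.assigned += 1
                stats.sample_counts[res.sample_id] += 1
                fh = _sink(res.sample_id)
                if fh is not None:
                    fh.write(f">{read.id}\n{res.insert}\n")
            else:
                stats.failures[res.failure_class] += 1
                fh = _sink("unassigned")
                if fh is not None:
                    fh.write(f">{read.id} {res.failure_class}\n{read.seq}\n")
            if collect_results:
                results.append(res)
    finally:
        for fh in sinks.values():
            fh.close()  # type: ignore[attr-defined]

    pair_counts = pd.DataFrame(0, index=f_ids, columns=r_ids, dtype=int)
    for (f, r), n in pair_tally.items():
        pair_counts.loc[f, r] = n
    stats.pair_counts = pair_counts

    if out_dir is not None:
        with open(os.path.join(out_dir, "pair_counts.tsv"), "w") as fh:
            pair_counts.to_csv(fh, sep="\t", index_label="f_barcode")
        with open(os.path.join(out_dir, "summary.tsv"), "w") as fh:
            for k, v in stats.summary().items():
                fh.write(f"{k}\t{v}\n")

    if collect_results:
        return stats, results
    return stats
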