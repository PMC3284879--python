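"""Insert-to-miRNA matching and raw count matrices.

Demultiplexed inserts are full-length small RNAs read from their 5' end, so
matching against the mature-miRNA reference is ungapped and 5'-anchored: the
insert is compared with each reference over their common prefix length.  The
mismatch budget is positional — up to ``head_mm`` mismatches within the first
``head_len`` nt of the insert and up to ``tail_mm`` in the remainder (an
optional total cap collapses the two budgets into one).  Only inserts with a
unique best hit (fewest total mismatches) are counted; equal-best ties are
discarded as multi-mapping, and inserts matching the contaminant set (other
non-coding RNAs) are removed before miRNA matching.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "ReferenceDB",
    "MismatchPolicy",
    "MatchOutcome",
    "match_insert",
    "count_matrix",
    "length_distribution",
    "LengthDistribution",
]


@dataclass
class ReferenceDB:
    """Mature miRNA reference (plus optional contaminant ncRNA set).

    Sequences are stored DNA-style (U converted to T, upper case); names must
    be unique and sequences non-empty.
    """

    names: list[str]
    seqs: list[str]
    contaminant_names: list[str] | None = None
    contaminant_seqs: list[str] | None = None

    def __post_init__(self) -> None:
        if not self.names:
            raise ValueError("empty reference database")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate names in reference database")
        if any(not s for s in self.seqs):
            raise ValueError("empty sequence in reference database")
        self.seqs = [s.upper().replace("U", "T") for s in self.seqs]
        if self.contaminant_seqs:
            self.contaminant_seqs = [
                s.upper().replace("U", "T") for s in self.contaminant_seqs
            ]
        # exact-sequence shortcut: sequence -> unique name or "" when shared
        self._exact: dict[str, str] = {}
        for n, s in zip(self.names, self.seqs):
            self._exact[s] = "" if s in self._exact else n

    def __len__(self) -> int:
        return len(self.names)

    @classmethod
    def from_fasta(cls, mature_path: str, contaminant_path: str | None = None) -> "ReferenceDB":
        from Bio import SeqIO

        names, seqs = [], []
        for rec in SeqIO.parse(mature_path, "fasta"):
            names.append(rec.id)
            seqs.append(str(rec.seq))
        cn, cs = None, None
        if contaminant_path is not None:
            cn, cs = [], []
            for rec in SeqIO.parse(contaminant_path, "fasta"):
                cn.append(rec.id)
                cs.append(str(rec.seq))
        return cls(names, seqs, cn, cs)

    def to_fasta(self, handle) -> None:
        for n, s in zip(self.names, self.seqs):
            handle.write(f">{n}\n{s}\n")


@dataclass(frozen=True)
class MismatchPolicy:
    """Positional mismatch budgets for ungapped insert matching.

    ``head_mm`` mismatches are allowed within insert positions
    ``[0, head_len)`` and ``tail_mm`` in the remainder.  When ``total_mm`` is
    set it additionally caps the sum (use it to read the budgets as one
    overall allowance).  ``min_insert_len`` rejects fragments too short to
    identify a miRNA.
    """

    head_len: int = 18
    head_mm: int = 2
    tail_mm: int = 3
    total_mm: int | None = None
    min_insert_len: int = 15

    def __post_init__(self) -> None:
        if min(self.head_len, self.head_mm, self.tail_mm) < 0:
            raise ValueError("policy fields must be nonnegative")


@dataclass(frozen=True)
class MatchOutcome:
    status: str  # "hit" | "none" | "multi" | "too_short"
    name: str | None = None
    mismatches: int | None = None


def _mismatch_split(insert: str, ref: str, head_len: int) -> tuple[int, int]:
    """Head/tail mismatch counts over the 5'-anchored common prefix."""
    overlap = min(len(insert), len(ref))
    head = min(head_len, overlap)
    mm_head = sum(insert[i] != ref[i] for i in range(head))
    mm_tail = sum(insert[i] != ref[i] for i in range(head, overlap))
    return mm_head, mm_tail


def match_insert(
    insert: str, db: ReferenceDB, policy: MismatchPolicy = MismatchPolicy()
) -> MatchOutcome:
    """Match one insert against the mature reference under the policy.

    A reference qualifies if the 5'-anchored ungapped comparison (insert as a
    prefix of the reference or vice versa) stays within both positional
    budgets.  The unique candidate with the fewest total mismatches is the
    hit; equal-best candidates give ``multi``; no candidate gives ``none``.
    """
    if len(insert) < policy.min_insert_len:
        return MatchOutcome("too_short")
    insert = insert.upper().replace("U", "T")

    exact = db._exact.get(insert)
    if exact:  # unique exact, nothing can beat 0 mismatches — but a second
        # reference could tie at 0 via prefix containment, so verify cheaply
        tied = any(
            s != insert and (s.startswith(insert) or insert.startswith(s))
            for s in db.seqs
        )
        if not tied:
            return MatchOutcome("hit", exact, 0)

    best_mm: int | None = None
    best_name: str | None = None
    tied = False
    for name, ref in zip(db.names, db.seqs):
        mm_head, mm_tail = _mismatch_split(insert, ref, policy.head_len)
        if mm_head > policy.head_mm or mm_tail > policy.tail_mm:
            continue
        total = mm_head + mm_tail
        if policy.total_mm is not None and total > policy.total_mm:
            continue
        if best_mm is None or total < best_mm:
            best_mm, best_name, tied = total, name, False
        elif total == best_mm:
            tied = True
    if best_mm is None:
        return MatchOutcome("none")
    if tied:
        return MatchOutcome("multi", mismatches=best_mm)
    return MatchOutcome("hit", best_name, best_mm)


def _matches_contaminant(insert: str, db: ReferenceDB, policy: MismatchPolicy) -> bool:
    if not db.contaminant_seqs:
        return False
    for ref in db.contaminant_seqs:
        mm_head, mm_tail = _mismatch_split(insert, ref, policy.head_len)
        if mm_head <= policy.head_mm and mm_tail <= policy.tail_mm:
            if policy.total_mm is None or mm_head + mm_tail <= policy.total_mm:
                return True
    return False


CLASS_BINS = ("miRNA", "contaminant", "unmatched", "multi", "too_short")


def count_matrix(
    insert_streams: Mapping[str, Iterable[str]],
    db: ReferenceDB,
    policy: MismatchPolicy = MismatchPolicy(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Raw miRNA count matrix from per-sample insert streams.

    Returns ``(counts, classification)``: ``counts`` is miRNA x sample with
    integer unique-hit counts; ``classification`` is class-bin x sample and
    conserves reads exactly (miRNA + contaminant + unmatched + multi +
    too_short = inserts seen per sample).  Contaminant matching runs before
    miRNA matching with the same policy.
    """
    samples = list(insert_streams)
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample ids")
    counts = pd.DataFrame(0, index=list(db.names), columns=samples, dtype=int)
    classes = pd.DataFrame(0, index=list(CLASS_BINS), columns=samples, dtype=int)
    for sample, stream in insert_streams.items():
        tally: Counter[str] = Counter()
        for insert in stream:
            if len(insert) >= policy.min_insert_len and _matches_contaminant(
                insert, db, policy
            ):
                classes.loc["contaminant", sample] += 1
                continue
            out = match_insert(insert, db, policy)
            if out.status == "hit":
                tally[out.name] += 1
                classes.loc["miRNA", sample] += 1
            elif out.status == "multi":
                classes.loc["multi", sample] += 1
            elif out.status == "too_short":
                classes.loc["too_short", sample] += 1
            else:
                classes.loc["unmatched", sample] += 1
        for name, c in tally.items():
            counts.loc[name, sample] = c
    return counts, classes


@dataclass
class LengthDistribution:
    """Histogram of insert lengths (nt -> read count)."""

    histogram: pd.Series

    @property
    def mode(self) -> int | None:
        if self.histogram.empty:
            return None
        return int(self.histogram.idxmax())

    @property
    def total(self) -> int:
        return int(self.histogram.sum())


def length_distribution(
    inserts: Iterable[str],
    db: ReferenceDB | None = None,
    policy: MismatchPolicy = MismatchPolicy(),
) -> LengthDistribution:
    """Exact length histogram of inserts, optionally restricted to those that
    match the miRNA reference (the adaptor-and-barcode-removed read-length
    profile of a small-RNA run, which peaks at 21-22 nt for mature miRNA)."""
    counter: Counter[int] = Counter()
    for insert in inserts:
        if db is not None and match_insert(insert, db, policy).status != "hit":
            continue
        counter[len(insert)] += 1
    hist = pd.Series(counter, dtype=int).sort_index()
    return LengthDistribution(histogram=hist)
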