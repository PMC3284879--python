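"""Read-stream loading: FASTQ / FASTA (optionally gzipped) and csfasta+QV.

Produces :class:`~pairbc.demux.ReadRecord` streams, pairing a main-read file
with an optional tag-read file (the R-barcode read).  Pairing is positional;
a tag file that ends early raises rather than silently truncating.
"""

from __future__ import annotations

import gzip
import itertools
from typing import Iterator

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .colorspace import read_csfasta
from .demux import ReadRecord

__all__ = ["open_text", "iter_reads", "sniff_format"]


def open_text(path: str):
    """Open a possibly-gzipped text file for reading."""
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def sniff_format(path: str) -> str:
    """Guess fastq / fasta / csfasta from the file name."""
    base = path[:-3] if path.endswith(".gz") else path
    low = base.lower()
    if low.endswith((".fastq", ".fq")):
        return "fastq"
    if low.endswith((".csfasta", ".csfa")):
        return "csfasta"
    if low.endswith((".fasta", ".fa", ".fna")):
        return "fasta"
    raise ValueError(f"cannot infer read format from {path!r}")


def _iter_single(path: str, fmt: str) -> Iterator[ReadRecord]:
    if fmt == "fastq":
        with open_text(path) as fh:
            for title, seq, qual in FastqGeneralIterator(fh):
                yield ReadRecord(id=title.split()[0], seq=seq.upper(), qual=qual)
    elif fmt == "fasta":
        with open_text(path) as fh:
            for title, seq in SimpleFastaParser(fh):
                yield ReadRecord(id=title.split()[0], seq=seq.upper())
    elif fmt == "csfasta":
        with open_text(path) as fh:
            for rid, cs in read_csfasta(fh):
                yield ReadRecord(id=rid, seq=cs.colors, anchor=cs.anchor)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def iter_reads(
    reads_path: str,
    tags_path: str | None = None,
    fmt: str | None = None,
) -> Iterator[ReadRecord]:
    """Stream reads, attaching the tag read (R-barcode) positionally when a
    tag file is given."""
    fmt = fmt or sniff_format(reads_path)
    main = _iter_single(reads_path, fmt)
    if tags_path is None:
        yield from main
        return
    tags = _iter_single(tags_path, fmt if fmt != "fastq" else sniff_format(tags_path))
    for rec, tag in itertools.zip_longest(main, tags):
        if rec is None or tag is None:
            raise ValueError("main and tag read files have different record counts")
        rec.mate_seq = tag.seq
        rec.mate_qual = tag.qual
        yield rec
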