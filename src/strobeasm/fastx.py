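"""Streaming FASTA/FASTQ input and output (plain or gzip, auto-detected)."""

from __future__ import annotations

import gzip
from typing import Iterable, Iterator, Optional

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

Record = tuple[str, str, Optional[str]]  # (id, sequence, quality-or-None)


def _open_text(path):
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fastx(path) -> Iterator[Record]:
    """Yield (id, seq, qual) records; qual is None for FASTA."""
    fh = _open_text(path)
    try:
        first = fh.read(1)
        if not first:
            return
        fh.seek(0)
        if first == ">":
            for title, seq in SimpleFastaParser(fh):
                yield title.split()[0], seq, None
        elif first == "@":
            for title, seq, qual in FastqGeneralIterator(fh):
                yield title.split()[0], seq, qual
        else:
            raise ValueError(f"{path}: not FASTA or FASTQ (starts with {first!r})")
    finally:
        fh.close()


def read_sequences(path) -> list[tuple[str, str]]:
    """(id, sequence) pairs of a FASTA/FASTQ file."""
    return [(rid, seq) for rid, seq, _ in read_fastx(path)]


def write_fasta(records: Iterable[tuple[str, str]], path,
                header_comment: Optional[str] = None) -> None:
    with open(path, "w") as fh:
        first = True
        for rid, seq in records:
            if first and header_comment:
                fh.write(f">{rid} {header_comment}\n{seq}\n")
            else:
                fh.write(f">{rid}\n{seq}\n")
            first = False


def write_fastq(records: Iterable[Record], path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            if qual is None:
                qual = "I" * len(seq)  # flat quality for synthetic reads
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
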