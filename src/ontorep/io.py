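"""Sequence file I/O helpers.

Thin wrappers around Biopython's SeqIO that normalize everything to plain
``(id, sequence)`` pairs.  FASTA output is wrapped at 80 columns.
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_FASTQ_EXT = {".fastq", ".fq"}


def sniff_format(path: str) -> str:
    """Return ``"fasta"`` or ``"fastq"`` for *path* by extension, falling
    back to peeking at the first non-blank character."""
    ext = os.path.splitext(path)[1].lower()
    if ext in _FASTQ_EXT:
        return "fastq"
    if ext in {".fasta", ".fa", ".fna"}:
        return "fasta"
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "fastq" if line.startswith("@") else "fasta"
    return "fasta"


def read_seqs(path: str, fmt: str | None = None) -> Iterator[tuple[str, str]]:
    """Yield ``(id, sequence)`` from a FASTA or FASTQ file.

    Qualities in FASTQ input are parsed and discarded; quality-based
    filtering is expected to happen upstream of this pipeline.
    """
    fmt = fmt or sniff_format(path)
    for rec in SeqIO.parse(path, fmt):
        yield rec.id, str(rec.seq)


def write_fasta(path: str, records: Iterable[tuple[str, str]]) -> int:
    """Write ``(id, sequence)`` pairs as 80-column-wrapped FASTA.

    Returns the number of records written.
    """
    recs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    return SeqIO.write(recs, path, "fasta")


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
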