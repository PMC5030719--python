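"""Germline gene reference libraries.

Loads IMGT-style germline V/D/J/C FASTA files, collapses alleles to genes
(the allele name truncated at ``*``), groups identically-sequenced alleles
(which no alignment-based assignment can distinguish), and annotates the
CDR3 anchor positions: the second conserved cysteine near the 3' end of
each V gene (IMGT position 104) and the conserved Trp/Phe of the
W/F-G-X-G motif in each J gene (IMGT position 118).

Coordinates are 0-based half-open throughout; human-readable output
converts to 1-based inclusive.
"""

from __future__ import annotations

import os
from collections import defaultdict
from dataclasses import dataclass, field, replace

from . import io

SEGMENTS = ("V", "D", "J", "C")
CHAINS = ("heavy", "kappa", "lambda")

_VALID = set("ACGTN")
_STOPS = {"TAA", "TAG", "TGA"}


class ReferenceError(ValueError):
    pass


@dataclass
class GermlineGene:
    """One reference allele.

    ``anchor`` is the 0-based offset of the first nucleotide of the anchor
    codon: the 2nd conserved Cys for V genes, the conserved Trp/Phe of the
    W/F-G-X-G motif for J genes.
    """

    allele_name: str
    segment: str
    chain: str
    sequence: str
    functionality: str = "F"
    anchor: int | None = None
    unanchored: bool = False

    @property
    def gene_name(self) -> str:
        return self.allele_name.split("*")[0]

    def __post_init__(self) -> None:
        if self.segment not in SEGMENTS:
            raise ReferenceError(f"unknown segment {self.segment!r}")
        if self.chain not in CHAINS:
            raise ReferenceError(f"unknown chain {self.chain!r}")
        bad = set(self.sequence) - _VALID
        if bad:
            raise ReferenceError(
                f"record {self.allele_name}: invalid characters {sorted(bad)}"
            )
        if self.anchor is not None and not (
            0 <= self.anchor <= len(self.sequence) - 3
        ):
            raise ReferenceError(
                f"record {self.allele_name}: anchor {self.anchor} out of range"
            )


@dataclass
class GermlineLibrary:
    """A collection of germline alleles with segment and duplicate indexes."""

    genes: list[GermlineGene] = field(default_factory=list)

    @property
    def segment_index(self) -> dict[str, list[GermlineGene]]:
        idx: dict[str, list[GermlineGene]] = defaultdict(list)
        for g in self.genes:
            idx[g.segment].append(g)
        return dict(idx)

    @property
    def duplicate_groups(self) -> list[frozenset[str]]:
        by_seq: dict[tuple[str, str], list[str]] = defaultdict(list)
        for g in self.genes:
            by_seq[(g.segment, g.sequence)].append(g.allele_name)
        return sorted(
            (frozenset(names) for names in by_seq.values()), key=sorted
        )

    def alleles(self, segment: str) -> list[GermlineGene]:
        return [g for g in self.genes if g.segment == segment]

    def get(self, allele_name: str) -> GermlineGene:
        for g in self.genes:
            if g.allele_name == allele_name:
                return g
        raise KeyError(allele_name)

    def merged_with(self, other: "GermlineLibrary") -> "GermlineLibrary":
        return GermlineLibrary(genes=self.genes + other.genes)

    def write_fasta(self, path: str, segment: str | None = None) -> int:
        genes = self.genes if segment is None else self.alleles(segment)
        return io.write_fasta(
            path, ((g.allele_name, g.sequence) for g in genes)
        )


def normalize_sequence(seq: str, name: str) -> str:
    """Uppercase, U->T, strip gap characters; reject anything outside
    A/C/G/T/N with an error naming the record."""
    s = seq.upper().replace("U", "T").replace(".", "").replace("-", "")
    bad = set(s) - _VALID
    if bad:
        raise ReferenceError(f"record {name}: invalid characters {sorted(bad)}")
    return s


def _parse_header(header: str) -> tuple[str, str]:
    """Return (allele_name, functionality) from a FASTA id line.

    Accepts IMGT pipe-delimited headers (field 2 = allele, field 4 =
    functionality) and plain '>IGHV3-30*18' style names.
    """
    if "|" in header:
        fields = header.split("|")
        allele = fields[1].strip() if len(fields) > 1 and fields[1] else fields[0]
        func = fields[3].strip() if len(fields) > 3 else "F"
        func = func.strip("()") or "F"
        return allele, func
    return header.split()[0], "F"


def load_germline_library(
    fasta_path: str,
    segment: str,
    chain: str,
    keep_orf_p: bool = False,
) -> GermlineLibrary:
    """Load one segment's germline alleles from FASTA.

    Alleles flagged ORF or pseudogene (P) in IMGT-style headers are
    excluded unless *keep_orf_p*; duplicate allele names with differing
    sequences are an error.
    """
    if not os.path.exists(fasta_path):
        raise ReferenceError(f"no such file: {fasta_path}")
    seen: dict[str, str] = {}
    genes: list[GermlineGene] = []
    with open(fasta_path) as fh:
        header = None
        chunks: list[str] = []
        records: list[tuple[str, str]] = []
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if header is not None:
                    records.append((header, "".join(chunks)))
                header = line[1:]
                chunks = []
            elif header is not None:
                chunks.append(line.strip())
        if header is not None:
            records.append((header, "".join(chunks)))
    for header, raw in records:
        allele, func = _parse_header(header)
        seq = normalize_sequence(raw, allele)
        if allele in seen:
            if seen[allele] != seq:
                raise ReferenceError(
                    f"duplicate allele {allele} with conflicting sequences"
                )
            continue
        seen[allele] = seq
        if func.upper() in {"ORF", "P"} and not keep_orf_p:
            continue
        genes.append(
            GermlineGene(
                allele_name=allele,
                segment=segment,
                chain=chain,
                sequence=seq,
                functionality=func,
            )
        )
    if not genes:
        raise ReferenceError(f"no usable records in {fasta_path}")
    return GermlineLibrary(genes=genes)


def find_v_anchor(seq: str) -> int | None:
    """Offset of the last in-frame TGT/TGC codon within the final 12
    codons of a V gene (frame 0), or None."""
    last_codon_start = (len(seq) - 3) // 3 * 3
    if last_codon_start < 0:
        return None
    found = None
    start = max(0, last_codon_start - 33)
    for p in range(start, last_codon_start + 1, 3):
        if seq[p : p + 3] in ("TGT", "TGC"):
            found = p
    return found


def find_j_anchor(seq: str) -> int | None:
    """Offset of the first W/F codon of a W/F-G-X-G motif in a J gene
    (any frame), or None."""
    for p in range(len(seq) - 11):
        if (
            seq[p : p + 3] in ("TGG", "TTT", "TTC")
            and seq[p + 3 : p + 5] == "GG"
            and seq[p + 9 : p + 11] == "GG"
        ):
            return p
    return None


def annotate_anchors(lib: GermlineLibrary) -> GermlineLibrary:
    """Return a library with CDR3 anchor offsets set on V and J alleles.

    Alleles in which no anchor motif is found are flagged ``unanchored``
    (excluded from CDR3 extraction, still used for gene assignment).
    """
    out: list[GermlineGene] = []
    for g in lib.genes:
        if g.segment == "V":
            a = find_v_anchor(g.sequence)
        elif g.segment == "J":
            a = find_j_anchor(g.sequence)
        else:
            out.append(g)
            continue
        if a is None:
            out.append(replace(g, anchor=None, unanchored=True))
        else:
            out.append(replace(g, anchor=a, unanchored=False))
    return GermlineLibrary(genes=out)


def load_library_dir(
    lib_dir: str, chain: str = "heavy", keep_orf_p: bool = False
) -> GermlineLibrary:
    """Load a library directory with one file per segment per chain
    (e.g. IGHV.fasta, IGHJ.fasta, IGHD.fasta, IGHC.fasta), returning a
    merged, anchor-annotated library."""
    prefix = {"heavy": "IGH", "kappa": "IGK", "lambda": "IGL"}[chain]
    lib = GermlineLibrary()
    for segment in SEGMENTS:
        for ext in ("fasta", "fa"):
            path = os.path.join(lib_dir, f"{prefix}{segment}.{ext}")
            if os.path.exists(path):
                lib = lib.merged_with(
                    load_germline_library(path, segment, chain, keep_orf_p)
                )
                break
    if not lib.alleles("V") or not lib.alleles("J"):
        raise ReferenceError(
            f"library dir {lib_dir} must provide at least {prefix}V and {prefix}J"
        )
    return annotate_anchors(lib)
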