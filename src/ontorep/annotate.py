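"""Read annotation: germline segment assignment, CDR3 extraction, status
classification, and dereplication.

Each read is assigned a germline V gene by scored local alignment against
the V library (both strands; reverse-strand hits reverse-complement the
working read), then a J gene in the region 3' of the V match, and
optionally a D gene (inside the V-J junction) and constant region (3' of
the J).  The CDR3 is delineated IMGT-style: the nucleotides strictly
between the V gene's 2nd conserved Cys codon and the J gene's conserved
Trp/Phe codon (positions 105-117; both anchors excluded), obtained by
mapping the anchor offsets through the alignments into read coordinates.

A final status is assigned with precedence
``wrong_length > no_V > no_J > no_CDR3 > indel > stop > good``; after
dereplication, retained cluster centroids are re-labelled ``unique``.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq

from . import io
from .align import AlignParams, SegmentHit, best_local_hit, nw_stats
from .reference import GermlineLibrary

log = logging.getLogger(__name__)

STATUSES = (
    "good",
    "unique",
    "indel",
    "stop",
    "no_V",
    "no_J",
    "no_CDR3",
    "wrong_length",
)

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class AnnotatedRead:
    read_id: str
    sequence: str
    timepoint_label: str | None = None
    v_hit: SegmentHit | None = None
    j_hit: SegmentHit | None = None
    d_hit: SegmentHit | None = None
    c_hit: SegmentHit | None = None
    cdr3_nt: str | None = None
    cdr3_aa: str | None = None
    v_divergence_pct: float | None = None
    status: str = "good"
    cluster_size: int | None = None

    @property
    def v_gene(self) -> str | None:
        return self.v_hit.gene_name if self.v_hit else None

    @property
    def j_gene(self) -> str | None:
        return self.j_hit.gene_name if self.j_hit else None


@dataclass
class Cluster:
    centroid_id: str
    member_ids: set[str] = field(default_factory=set)
    size: int = 0
    retained: bool = True


# ---------------------------------------------------------------------------
# assignment


def filter_by_length(
    reads: list[tuple[str, str]], min_len: int = 300, max_len: int = 600
) -> tuple[list[tuple[str, str]], list[str]]:
    """Keep reads with min_len <= length <= max_len (inclusive bounds);
    return (kept, discarded_ids)."""
    if min_len >= max_len:
        raise ValueError("min_len must be < max_len")
    kept, discarded = [], []
    for rid, seq in reads:
        if min_len <= len(seq) <= max_len:
            kept.append((rid, seq))
        else:
            discarded.append(rid)
    return kept, discarded


def assign_v(
    read: str,
    lib: GermlineLibrary,
    params: AlignParams = AlignParams(),
    both_strands: bool = True,
) -> SegmentHit | None:
    """Best V hit over both strands.  A reverse-strand hit is reported
    with strand '-' and coordinates on the reverse complement of the
    input read (the caller re-orients the read)."""
    alleles = lib.alleles("V")
    fwd = best_local_hit(read, alleles, params, params.min_score_v, params.min_cover_v)
    if not both_strands:
        return fwd
    rc = io.revcomp(read)
    rev = best_local_hit(rc, alleles, params, params.min_score_v, params.min_cover_v)
    if rev is not None and (fwd is None or rev.score > fwd.score):
        rev.strand = "-"
        return rev
    return fwd


def assign_j(
    read: str,
    v_hit: SegmentHit,
    lib: GermlineLibrary,
    params: AlignParams = AlignParams(),
) -> SegmentHit | None:
    """Best J hit in the region 3' of the V match; coordinates are
    reported in full-read space."""
    return best_local_hit(
        read,
        lib.alleles("J"),
        params,
        params.min_score_j,
        window=(v_hit.read_interval[1], len(read)),
    )


def assign_d_and_c(
    read: str,
    v_hit: SegmentHit,
    j_hit: SegmentHit,
    lib: GermlineLibrary,
    params: AlignParams = AlignParams(),
    find_d: bool = True,
    find_c: bool = True,
) -> tuple[SegmentHit | None, SegmentHit | None]:
    """D gene searched inside the V-J junction, constant region 3' of the
    J match; either search can be disabled."""
    d_hit = c_hit = None
    if find_d and lib.alleles("D"):
        lo, hi = v_hit.read_interval[1], j_hit.read_interval[0]
        if hi - lo >= 5:
            d_hit = best_local_hit(
                read, lib.alleles("D"), params, params.min_score_d, window=(lo, hi)
            )
    if find_c and lib.alleles("C"):
        lo = j_hit.read_interval[1]
        if len(read) - lo >= 5:
            c_hit = best_local_hit(
                read, lib.alleles("C"), params, params.min_score_c, window=(lo, len(read))
            )
    return d_hit, c_hit


def extract_cdr3(
    read: str, v_hit: SegmentHit, j_hit: SegmentHit, lib: GermlineLibrary
) -> tuple[str, str | None] | None:
    """CDR3 nucleotides strictly between the V Cys codon and the J
    Trp/Phe codon, with translation when in frame.  None if either
    germline anchor is unset or falls outside its alignment."""
    v = lib.get(v_hit.allele_name)
    j = lib.get(j_hit.allele_name)
    if v.anchor is None or j.anchor is None:
        return None
    start = v_hit.map_ref_to_read(v.anchor + 3)
    end = j_hit.map_ref_to_read(j.anchor)
    if start is None or end is None or end <= start:
        return None
    cdr3_nt = read[start:end]
    cdr3_aa = None
    if len(cdr3_nt) % 3 == 0 and cdr3_nt:
        cdr3_aa = str(Seq(cdr3_nt).translate())
    return cdr3_nt, cdr3_aa


def _has_frameshift(read: AnnotatedRead, strict: bool = False) -> bool:
    for hit in (read.v_hit, read.j_hit):
        if hit is None:
            continue
        if hit.gaps % 3 != 0:
            return True
        if strict and hit is read.v_hit and hit.gaps > 0:
            return True
    return False


def _has_stop(read: AnnotatedRead) -> bool:
    """Scan for in-frame stop codons over the V-J span, in the reading
    frame propagated from the germline V through the alignment."""
    v, j = read.v_hit, read.j_hit
    rs = v.read_interval[0]
    phase = v.ref_interval[0] % 3
    first = rs + ((3 - phase) % 3)
    stop_at = j.read_interval[1]
    seq = read.sequence
    for p in range(first, stop_at - 2, 3):
        if seq[p : p + 3] in _STOPS:
            return True
    return False


def classify_status(read: AnnotatedRead, strict_indel: bool = False) -> str:
    """Final disposition with precedence
    wrong_length > no_V > no_J > no_CDR3 > indel > stop > good."""
    if read.status == "wrong_length":
        return "wrong_length"
    if read.v_hit is None:
        return "no_V"
    if read.j_hit is None:
        return "no_J"
    if read.cdr3_nt is None:
        return "no_CDR3"
    if _has_frameshift(read, strict_indel):
        return "indel"
    if _has_stop(read):
        return "stop"
    return "good"


def annotate_read(
    read_id: str,
    seq: str,
    lib: GermlineLibrary,
    params: AlignParams = AlignParams(),
    timepoint_label: str | None = None,
    find_d: bool = True,
    find_c: bool = True,
) -> AnnotatedRead:
    """Run the full assignment cascade on one length-filtered read."""
    ann = AnnotatedRead(read_id=read_id, sequence=seq, timepoint_label=timepoint_label)
    v_hit = assign_v(seq, lib, params)
    if v_hit is not None and v_hit.strand == "-":
        ann.sequence = io.revcomp(seq)
    ann.v_hit = v_hit
    if v_hit is not None:
        ref = lib.get(v_hit.allele_name)
        rs, re_ = v_hit.read_interval
        qs, qe = v_hit.ref_interval
        dist, cols = nw_stats(ann.sequence[rs:re_], ref.sequence[qs:qe])
        ann.v_divergence_pct = 100.0 * dist / cols if cols else 0.0
        ann.j_hit = assign_j(ann.sequence, v_hit, lib, params)
        if ann.j_hit is not None:
            ann.d_hit, ann.c_hit = assign_d_and_c(
                ann.sequence, v_hit, ann.j_hit, lib, params, find_d, find_c
            )
            cdr3 = extract_cdr3(ann.sequence, v_hit, ann.j_hit, lib)
            if cdr3 is not None:
                ann.cdr3_nt, ann.cdr3_aa = cdr3
    ann.status = classify_status(ann)
    return ann


def annotate_reads(
    reads: list[tuple[str, str]],
    lib: GermlineLibrary,
    params: AlignParams = AlignParams(),
    min_len: int = 300,
    max_len: int = 600,
    timepoint_label: str | None = None,
    find_d: bool = True,
    find_c: bool = True,
) -> list[AnnotatedRead]:
    if min_len >= max_len:
        raise ValueError("min_len must be < max_len")
    out = []
    n_discarded = 0
    for rid, seq in reads:
        if not (min_len <= len(seq) <= max_len):
            out.append(
                AnnotatedRead(
                    read_id=rid, sequence=seq, timepoint_label=timepoint_label,
                    status="wrong_length",
                )
            )
            n_discarded += 1
        else:
            out.append(
                annotate_read(rid, seq, lib, params, timepoint_label, find_d, find_c)
            )
    if n_discarded:
        log.info(
            "discarded %d reads outside [%d, %d] nt", n_discarded, min_len, max_len
        )
    return out


# ---------------------------------------------------------------------------
# dereplication


def dereplicate(
    reads: list[AnnotatedRead],
    identity: float = 0.99,
    min_size: int = 3,
) -> tuple[list[Cluster], list[AnnotatedRead]]:
    """Greedy centroid dereplication of good reads.

    Exact duplicates are collapsed first (and counted into cluster size);
    remaining distinct sequences are sorted by decreasing (duplicate
    count, length), then id, and each joins the first existing centroid
    with global identity >= *identity* (matches/columns, gaps as
    mismatch) or founds a new centroid.  Clusters smaller than *min_size*
    are flagged not retained; centroids of retained clusters are returned
    with status "unique" and their cluster size.
    """
    if not 0 < identity <= 1:
        raise ValueError("identity must be in (0, 1]")
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    by_seq: dict[str, list[AnnotatedRead]] = defaultdict(list)
    for r in reads:
        by_seq[r.sequence].append(r)
    entries = []  # (seq, ids sorted, count)
    for seq, members in by_seq.items():
        ids = sorted(m.read_id for m in members)
        entries.append((seq, ids, len(members)))
    entries.sort(key=lambda e: (-e[2], -len(e[0]), e[1][0]))

    clusters: list[Cluster] = []
    centroid_seqs: list[str] = []
    for seq, ids, count in entries:
        placed = False
        for cl, cseq in zip(clusters, centroid_seqs):
            dist, cols = nw_stats(seq, cseq)
            if cols and (cols - dist) / cols >= identity:
                cl.member_ids.update(ids)
                cl.size += count
                placed = True
                break
        if not placed:
            clusters.append(Cluster(centroid_id=ids[0], member_ids=set(ids), size=count))
            centroid_seqs.append(seq)
    by_id = {r.read_id: r for r in reads}
    unique_reads: list[AnnotatedRead] = []
    for cl in clusters:
        cl.retained = cl.size >= min_size
        if cl.retained:
            centroid = by_id[cl.centroid_id]
            centroid.status = "unique"
            centroid.cluster_size = cl.size
            unique_reads.append(centroid)
    return clusters, unique_reads


# ---------------------------------------------------------------------------
# tables and subsets


def master_table(reads: list[AnnotatedRead]) -> pd.DataFrame:
    """Per-read disposition table (the pipeline's central output)."""
    rows = []
    for r in reads:
        rows.append(
            {
                "read_id": r.read_id,
                "timepoint": r.timepoint_label,
                "length": len(r.sequence),
                "v_gene": r.v_gene,
                "v_allele": r.v_hit.allele_name if r.v_hit else None,
                "j_gene": r.j_gene,
                "j_allele": r.j_hit.allele_name if r.j_hit else None,
                "d_gene": r.d_hit.gene_name if r.d_hit else None,
                "c_gene": r.c_hit.gene_name if r.c_hit else None,
                "cdr3_nt": r.cdr3_nt,
                "cdr3_aa": r.cdr3_aa,
                "cdr3_len_aa": len(r.cdr3_aa) if r.cdr3_aa else None,
                "v_divergence_pct": r.v_divergence_pct,
                "status": r.status,
                "cluster_size": r.cluster_size,
            }
        )
    return pd.DataFrame(rows)


def usage_summary(reads: list[AnnotatedRead], segment: str = "V") -> pd.DataFrame:
    attr = {"V": "v_hit", "J": "j_hit", "D": "d_hit", "C": "c_hit"}[segment]
    counts = Counter(
        getattr(r, attr).gene_name for r in reads if getattr(r, attr) is not None
    )
    return pd.DataFrame(
        sorted(counts.items()), columns=[f"{segment.lower()}_gene", "count"]
    )


def sequence_subsets(reads: list[AnnotatedRead]) -> dict[str, list[tuple[str, str]]]:
    """FASTA subsets mirroring the pipeline stages: allOK (V+J assigned),
    goodVJ (plus CDR3), goodCDR3 (plus no indel/stop), unique."""
    subsets: dict[str, list[tuple[str, str]]] = {
        "allOK": [], "goodVJ": [], "goodCDR3": [], "unique": []
    }
    for r in reads:
        if r.v_hit is not None and r.j_hit is not None:
            subsets["allOK"].append((r.read_id, r.sequence))
            if r.cdr3_nt is not None:
                subsets["goodVJ"].append((r.read_id, r.sequence))
                if r.status in ("good", "unique"):
                    subsets["goodCDR3"].append((r.read_id, r.sequence))
        if r.status == "unique":
            subsets["unique"].append((r.read_id, r.sequence))
    if not subsets["unique"]:  # dereplication has not run yet
        del subsets["unique"]
    return subsets
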