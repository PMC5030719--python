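"""Pairwise alignment engine.

Two flavours of alignment are used throughout the pipeline:

* **Scored local alignment** (BLASTN-like: match +5, mismatch -4, gap open
  -8, gap extend -2) for germline segment assignment.  Backed by
  :class:`Bio.Align.PairwiseAligner`, using the BLAST gap-cost convention:
  a gap of length k costs open + k*extend (a 1-nt gap scores -10).
* **Unit-cost global alignment** for identity and divergence percentages
  (dereplication, CDR3 clustering, identity-divergence tables), backed by
  edlib.  Identity = matches / alignment columns, gap columns counted as
  mismatches.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache

import edlib
from Bio import Align


@dataclass(frozen=True)
class AlignParams:
    """Scoring and acceptance parameters for local segment assignment."""

    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = -8.0
    gap_extend: float = -2.0
    min_score_v: float = 400.0
    min_cover_v: float = 0.5
    min_score_j: float = 30.0
    min_score_d: float = 25.0  # equivalent of >=5 consecutive matches
    min_score_c: float = 25.0
    # terminal aligned fragments shorter than this and separated from the
    # alignment body by a gap are trimmed (junctional chewback otherwise
    # shows up as spurious gapped overextension of the V/J alignment)
    min_terminal_block: int = 5


@dataclass
class SegmentHit:
    """Best local alignment of a read against one germline allele.

    Intervals are 0-based half-open; ``read_interval`` is in the
    coordinates of the (possibly reverse-complemented) working read.
    """

    allele_name: str
    gene_name: str
    score: float
    read_interval: tuple[int, int]
    ref_interval: tuple[int, int]
    strand: str = "+"
    mismatches: int = 0
    gaps: int = 0
    blocks: list[tuple[tuple[int, int], tuple[int, int]]] = field(
        default_factory=list, repr=False
    )
    ref_length: int = 0

    @property
    def evalue_like(self) -> float:
        # Karlin-Altschul-style surrogate: decays exponentially with score.
        import math

        return math.exp(-0.192 * self.score)

    @property
    def identity_pct(self) -> float:
        cols = sum(re - rs for (rs, re), _ in self.blocks) + self.gaps
        if cols == 0:
            return 0.0
        return 100.0 * (cols - self.gaps - self.mismatches) / cols

    def map_ref_to_read(self, ref_pos: int) -> int | None:
        """Map a reference coordinate into read coordinates through the
        alignment.  ``ref_pos`` equal to a block end maps to the block's
        read end (half-open convention); positions inside ref-side gaps or
        outside the aligned span return None."""
        for (rs, re_), (qs, qe) in self.blocks:
            if qs <= ref_pos < qe:
                return rs + (ref_pos - qs)
            if ref_pos == qe:
                return re_
        return None


@lru_cache(maxsize=8)
def _aligner(
    mode: str, match: float, mismatch: float, gap_open: float, gap_extend: float
) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = mode
    a.match_score = match
    a.mismatch_score = mismatch
    a.open_gap_score = gap_open
    a.extend_gap_score = gap_extend
    return a


def local_aligner(params: AlignParams) -> Align.PairwiseAligner:
    # Biopython scores the first gap position with open_gap_score; BLAST
    # charges open + extend for a length-1 gap, so fold one extension in.
    return _aligner(
        "local",
        params.match,
        params.mismatch,
        params.gap_open + params.gap_extend,
        params.gap_extend,
    )


def _gap_cost(length: int, params: AlignParams) -> float:
    return 0.0 if length <= 0 else -(params.gap_open + params.gap_extend * length)


def _hit_from_alignment(
    aln, read: str, ref: str, allele: str, gene: str, strand: str,
    params: AlignParams,
) -> SegmentHit:
    read_blocks, ref_blocks = aln.aligned
    blocks = [
        ((int(r0), int(r1)), (int(q0), int(q1)))
        for (r0, r1), (q0, q1) in zip(read_blocks, ref_blocks)
    ]
    # trim short gap-separated terminal fragments (alignment noise over
    # chewed-back germline termini)
    while len(blocks) > 1 and (
        blocks[0][0][1] - blocks[0][0][0] < params.min_terminal_block
    ):
        blocks = blocks[1:]
    while len(blocks) > 1 and (
        blocks[-1][0][1] - blocks[-1][0][0] < params.min_terminal_block
    ):
        blocks = blocks[:-1]
    mismatches = 0
    matches = 0
    for (r0, r1), (q0, q1) in blocks:
        mm = sum(1 for a, b in zip(read[r0:r1], ref[q0:q1]) if a != b)
        mismatches += mm
        matches += (r1 - r0) - mm
    gaps = 0
    score = matches * params.match + mismatches * params.mismatch
    for i in range(1, len(blocks)):
        g_read = blocks[i][0][0] - blocks[i - 1][0][1]
        g_ref = blocks[i][1][0] - blocks[i - 1][1][1]
        gaps += g_read + g_ref
        score -= _gap_cost(g_read, params) + _gap_cost(g_ref, params)
    return SegmentHit(
        allele_name=allele,
        gene_name=gene,
        score=float(score),
        read_interval=(blocks[0][0][0], blocks[-1][0][1]),
        ref_interval=(blocks[0][1][0], blocks[-1][1][1]),
        strand=strand,
        mismatches=mismatches,
        gaps=gaps,
        blocks=blocks,
        ref_length=len(ref),
    )


def best_local_hit(
    read: str,
    alleles: list,
    params: AlignParams,
    min_score: float,
    min_cover: float = 0.0,
    window: tuple[int, int] | None = None,
) -> SegmentHit | None:
    """Best-scoring local hit of *read* against a list of GermlineGene.

    *window* restricts the search to ``read[start:end)``; returned
    coordinates are always in full-read space.  Score ties are broken by
    fewer gaps, then lexicographic allele name.
    """
    if window is not None:
        off = window[0]
        sub = read[window[0] : window[1]]
    else:
        off = 0
        sub = read
    if not sub:
        return None
    aligner = local_aligner(params)
    scores: list[tuple[float, str]] = []
    for g in alleles:
        try:
            s = aligner.score(sub, g.sequence)
        except ValueError:
            continue
        scores.append((s, g.allele_name))
    if not scores:
        return None
    best = max(s for s, _ in scores)
    if best < min_score:
        return None
    by_name = {g.allele_name: g for g in alleles}
    candidates = []
    for s, name in scores:
        if s == best:
            g = by_name[name]
            aln = next(iter(aligner.align(sub, g.sequence)))
            hit = _hit_from_alignment(
                aln, sub, g.sequence, name, g.gene_name, "+", params
            )
            candidates.append(hit)
    candidates.sort(key=lambda h: (h.gaps, h.allele_name))
    hit = candidates[0]
    if min_cover > 0:
        span = hit.ref_interval[1] - hit.ref_interval[0]
        if span < min_cover * hit.ref_length:
            return None
    if off:
        hit.read_interval = (hit.read_interval[0] + off, hit.read_interval[1] + off)
        hit.blocks = [
            ((r0 + off, r1 + off), (q0, q1)) for (r0, r1), (q0, q1) in hit.blocks
        ]
    return hit


# ---------------------------------------------------------------------------
# unit-cost global alignment (edlib)

_CIG = re.compile(r"(\d+)([=XIDM])")


def nw_stats(a: str, b: str) -> tuple[int, int]:
    """(edit distance, alignment columns) of the optimal unit-cost global
    alignment of *a* and *b*.  Columns include gap columns.  The argument
    order is canonicalized so the statistic is symmetric (co-optimal
    paths can differ in column count)."""
    if not a or not b:
        return max(len(a), len(b)), max(len(a), len(b))
    if b < a:
        a, b = b, a
    res = edlib.align(a, b, mode="NW", task="path")
    cols = sum(int(n) for n, _ in _CIG.findall(res["cigar"]))
    return res["editDistance"], cols


def identity_pct(a: str, b: str) -> float:
    """Global identity of two sequences in percent: matches / columns,
    gaps counted as mismatch."""
    dist, cols = nw_stats(a, b)
    if cols == 0:
        return 100.0
    return 100.0 * (cols - dist) / cols


def divergence_pct(a: str, b: str) -> float:
    """Mismatch percentage (100 - identity) of a unit-cost global
    alignment."""
    return 100.0 - identity_pct(a, b)


def global_align_strings(query: str, target: str) -> tuple[str, str]:
    """Gapped strings of the optimal unit-cost global alignment
    (query row, target row)."""
    res = edlib.align(query, target, mode="NW", task="path")
    qa, ta = [], []
    qi = ti = 0
    for n, op in _CIG.findall(res["cigar"]):
        n = int(n)
        if op in "=XM":
            qa.append(query[qi : qi + n])
            ta.append(target[ti : ti + n])
            qi += n
            ti += n
        elif op == "I":  # extra bases in query
            qa.append(query[qi : qi + n])
            ta.append("-" * n)
            qi += n
        elif op == "D":  # extra bases in target
            qa.append("-" * n)
            ta.append(target[ti : ti + n])
            ti += n
    return "".join(qa), "".join(ta)
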