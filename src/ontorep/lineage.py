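"""Clonal lineage identification.

Three complementary strategies for deciding which transcripts belong to
the lineage of one or more known "seed" antibodies:

* **identity-divergence**: tabulate each read's divergence from its
  assigned germline V gene against its full-length identity to each seed,
  then extract the high-identity "island" the lineage forms on that plot;
* **intradonor analysis**: iteratively build germline-rooted
  neighbor-joining trees on random chunks of the reads plus the seeds and
  keep only reads inside the minimal clade spanning all seeds, until 95%
  of a round's input survives;
* **CDR3 clustering**: partition reads into lineages by V gene, J gene,
  and CDR3 nucleotide identity (seeded when seed antibodies are clustered
  along with the reads).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import global_align_strings, identity_pct, nw_stats
from .annotate import AnnotatedRead
from .phylo import mrca, neighbor_joining, reroot_on_leaf
from .reference import GermlineLibrary

log = logging.getLogger(__name__)

__all__ = [
    "IdDivRecord",
    "Island",
    "Lineage",
    "calc_id_div",
    "get_island",
    "neighbor_joining",
    "has_converged",
    "intradonor_analysis",
    "cluster_cdr3_lineages",
    "star_msa",
    "p_distance_matrix",
]


@dataclass
class IdDivRecord:
    read_id: str
    v_gene: str
    divergence_pct: float
    identity_pct: dict[str, float] = field(default_factory=dict)


@dataclass
class Island:
    """Closed rectangle on the identity-divergence plane."""

    seed_name: str
    min_identity: float
    max_identity: float = 100.0
    min_divergence: float = 0.0
    max_divergence: float = 100.0

    def __post_init__(self) -> None:
        if self.min_identity > self.max_identity:
            raise ValueError("min_identity > max_identity")
        if self.min_divergence > self.max_divergence:
            raise ValueError("min_divergence > max_divergence")

    def contains(self, divergence: float, identity: float) -> bool:
        return (
            self.min_divergence <= divergence <= self.max_divergence
            and self.min_identity <= identity <= self.max_identity
        )


@dataclass
class CdrRecord:
    """Minimal read surface for CDR3 clustering (what a master-table row
    retains); AnnotatedRead satisfies the same attributes."""

    read_id: str
    v_gene: str
    j_gene: str
    cdr3_nt: str


@dataclass
class Lineage:
    lineage_id: str
    v_gene: str
    j_gene: str
    member_ids: set[str]
    representative_cdr3: str
    method: str  # island | intradonor | cdr3_cluster
    seed_names: set[str] = field(default_factory=set)


# ---------------------------------------------------------------------------
# identity-divergence


def calc_id_div(
    reads: list[AnnotatedRead],
    seeds: list[tuple[str, str]],
    lib: GermlineLibrary,
) -> list[IdDivRecord]:
    """Per-read germline-V divergence and full-length identity to each
    seed antibody (gaps counted as mismatches in both).  Reads without a
    V assignment are skipped."""
    records = []
    skipped = 0
    for r in reads:
        if r.v_hit is None:
            skipped += 1
            continue
        if r.v_divergence_pct is not None:
            div = r.v_divergence_pct
        else:
            ref = lib.get(r.v_hit.allele_name)
            rs, re_ = r.v_hit.read_interval
            qs, qe = r.v_hit.ref_interval
            dist, cols = nw_stats(r.sequence[rs:re_], ref.sequence[qs:qe])
            div = 100.0 * dist / cols if cols else 0.0
        ident = {name: identity_pct(r.sequence, seq) for name, seq in seeds}
        records.append(
            IdDivRecord(
                read_id=r.read_id,
                v_gene=r.v_gene,
                divergence_pct=div,
                identity_pct=ident,
            )
        )
    if skipped:
        log.info("calc_id_div: skipped %d reads without V assignment", skipped)
    return records


def id_div_table(records: list[IdDivRecord]) -> pd.DataFrame:
    seed_names = sorted({s for r in records for s in r.identity_pct})
    rows = []
    for r in records:
        row = {"read_id": r.read_id, "v_gene": r.v_gene, "divergence": r.divergence_pct}
        for s in seed_names:
            row[f"identity_{s}"] = r.identity_pct.get(s)
        rows.append(row)
    return pd.DataFrame(rows)


def get_island(records: list[IdDivRecord], island: Island) -> set[str]:
    """Read ids whose (divergence, identity-to-seed) point falls inside
    the closed island rectangle."""
    known = {s for r in records for s in r.identity_pct}
    if island.seed_name not in known:
        raise KeyError(f"unknown seed {island.seed_name!r}")
    return {
        r.read_id
        for r in records
        if island.seed_name in r.identity_pct
        and island.contains(r.divergence_pct, r.identity_pct[island.seed_name])
    }


# ---------------------------------------------------------------------------
# star multiple alignment and p-distances


def star_msa(ref: tuple[str, str], seqs: list[tuple[str, str]]) -> dict[str, str]:
    """Progressive multiple alignment seeded on a star around *ref*.

    Each sequence is globally aligned to the reference; insertions
    relative to the reference are merged into shared columns (padded to
    the longest insertion at each reference position).
    """
    ref_name, ref_seq = ref
    L = len(ref_seq)
    per_seq: dict[str, tuple[list[str], list[str]]] = {}
    ins_len = np.zeros(L + 1, dtype=int)  # insertions before ref position i
    for name, seq in seqs:
        q_row, t_row = global_align_strings(seq, ref_seq)
        aligned: list[str] = [""] * (L + 1)  # insertion slots
        match: list[str] = [""] * L
        ref_i = 0
        for qc, tc in zip(q_row, t_row):
            if tc == "-":
                aligned[ref_i] += qc
            else:
                match[ref_i] = qc
                ref_i += 1
        per_seq[name] = (aligned, match)
        lens = np.fromiter((len(s) for s in aligned), dtype=int, count=L + 1)
        np.maximum(ins_len, lens, out=ins_len)

    def build(aligned: list[str], match: list[str]) -> str:
        parts = []
        for i in range(L):
            parts.append(aligned[i].ljust(ins_len[i], "-"))
            parts.append(match[i] if match[i] else "-")
        parts.append(aligned[L].ljust(ins_len[L], "-"))
        return "".join(parts)

    out = {ref_name: build([""] * (L + 1), list(ref_seq))}
    for name, (aligned, match) in per_seq.items():
        out[name] = build(aligned, match)
    return out


def p_distance_matrix(msa: dict[str, str]) -> tuple[list[str], np.ndarray]:
    """Pairwise p-distances on a multiple alignment, with gap-containing
    columns deleted pairwise.  Pairs with no comparable columns get
    distance 1.0."""
    names = list(msa)
    arr = np.frombuffer(
        "".join(msa[n] for n in names).encode(), dtype="S1"
    ).reshape(len(names), -1)
    valid = np.isin(arr, [b"A", b"C", b"G", b"T"])
    n = len(names)
    D = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        diff = (arr[i] != arr[i + 1 :]) & both
        counts = both.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(counts > 0, diff.sum(axis=1) / np.maximum(counts, 1), 1.0)
        D[i, i + 1 :] = d
        D[i + 1 :, i] = d
    return names, D


# ---------------------------------------------------------------------------
# intradonor analysis


def has_converged(n_survivors: int, n_input: int, converge: float = 0.95) -> bool:
    """Intradonor stopping rule: a round converges when the survivors are
    at least the *converge* fraction of that round's input."""
    return n_input > 0 and n_survivors / n_input >= converge


def intradonor_analysis(
    reads: list[tuple[str, str]],
    seeds: list[tuple[str, str]],
    germline_v: tuple[str, str],
    group_size: int = 250,
    converge: float = 0.95,
    max_iters: int = 15,
    rng_seed: int = 0,
    trace: list[set[str]] | None = None,
) -> set[str]:
    """Iterative seeded lineage assignment.

    Each round, the surviving reads are shuffled and split into chunks of
    at most *group_size*; every chunk is aligned together with the seed
    antibodies and the germline V, a neighbor-joining tree is built on
    p-distances and rooted on the germline leaf, and reads inside the
    minimal clade containing all seeds survive.  The procedure has
    converged when at least ``converge`` of a round's input survives.
    Returns the surviving read ids; *trace*, if given, collects the
    survivor id set of every round.
    """
    if not seeds:
        raise ValueError("at least one seed antibody is required")
    if group_size < 2 * len(seeds):
        raise ValueError("group_size must be >= 2 x number of seeds")
    germ_name, germ_seq = germline_v
    seed_names = {n for n, _ in seeds}
    reserved = seed_names | {germ_name}
    if any(rid in reserved for rid, _ in reads):
        raise ValueError("read ids collide with seed/germline names")
    rng = np.random.default_rng(rng_seed)
    log.info(
        "intradonor: %d reads, %d seeds, group_size=%d, rng_seed=%d",
        len(reads), len(seeds), group_size, rng_seed,
    )
    surviving = list(reads)
    for it in range(1, max_iters + 1):
        if not surviving:
            break
        n_in = len(surviving)
        order = rng.permutation(n_in)
        shuffled = [surviving[i] for i in order]
        chunks = [
            shuffled[i : i + group_size] for i in range(0, n_in, group_size)
        ]
        survivors: list[tuple[str, str]] = []
        for chunk in chunks:
            taxa = chunk + seeds
            msa = star_msa((germ_name, germ_seq), taxa)
            names, D = p_distance_matrix(msa)
            if len(names) < 3:
                survivors.extend(chunk)
                continue
            tree = neighbor_joining(names, D)
            rooted = reroot_on_leaf(tree, germ_name)
            clade = mrca(rooted, seed_names)
            inside = clade.leaf_names() - reserved
            survivors.extend((rid, s) for rid, s in chunk if rid in inside)
        log.info(
            "intradonor round %d: %d/%d survive (%.1f%%)",
            it, len(survivors), n_in, 100.0 * len(survivors) / n_in,
        )
        surviving = survivors
        if trace is not None:
            trace.append({rid for rid, _ in surviving})
        if has_converged(len(survivors), n_in, converge):
            return {rid for rid, _ in surviving}
    if surviving:
        log.warning("intradonor did not converge in %d rounds", max_iters)
    return {rid for rid, _ in surviving}


# ---------------------------------------------------------------------------
# CDR3 clustering into lineages


def cluster_cdr3_lineages(
    reads: list[AnnotatedRead],
    identity: float = 0.90,
    seeds: list[AnnotatedRead] | None = None,
) -> list[Lineage]:
    """Partition CDR3-bearing reads into lineages.

    Reads are grouped by assigned V and J **gene** (alleles of one gene
    are pooled), then greedily clustered on CDR3 nucleotide identity with
    the same deterministic ordering as dereplication.  Seed antibodies,
    if given, are clustered along with the reads and mark their lineage
    as seeded.
    """
    seeds = seeds or []
    seed_ids = {s.read_id for s in seeds}
    pool = list(reads) + list(seeds)
    groups: dict[tuple[str, str], list[AnnotatedRead]] = defaultdict(list)
    skipped = 0
    for r in pool:
        if r.v_gene is None or r.j_gene is None or not r.cdr3_nt:
            skipped += 1
            continue
        groups[(r.v_gene, r.j_gene)].append(r)
    if skipped:
        log.info("cluster_cdr3_lineages: skipped %d reads without V/J/CDR3", skipped)

    lineages: list[Lineage] = []
    for (v_gene, j_gene) in sorted(groups):
        members = groups[(v_gene, j_gene)]
        by_cdr3: dict[str, list[str]] = defaultdict(list)
        for r in members:
            by_cdr3[r.cdr3_nt].append(r.read_id)
        entries = sorted(
            ((cdr3, sorted(ids)) for cdr3, ids in by_cdr3.items()),
            key=lambda e: (-len(e[1]), -len(e[0]), e[1][0]),
        )
        clusters: list[tuple[str, set[str]]] = []  # (centroid cdr3, member ids)
        for cdr3, ids in entries:
            for k, (centroid, bag) in enumerate(clusters):
                if identity_pct(cdr3, centroid) >= 100.0 * identity:
                    bag.update(ids)
                    break
            else:
                clusters.append((cdr3, set(ids)))
        for centroid, bag in clusters:
            lineages.append(
                Lineage(
                    lineage_id="",
                    v_gene=v_gene,
                    j_gene=j_gene,
                    member_ids=bag,
                    representative_cdr3=centroid,
                    method="cdr3_cluster",
                    seed_names=bag & seed_ids,
                )
            )
    lineages.sort(key=lambda l: (-len(l.member_ids), l.v_gene, l.j_gene, l.representative_cdr3))
    for i, l in enumerate(lineages, 1):
        l.lineage_id = f"L{i:05d}"
    return lineages


def lineage_table(lineages: list[Lineage]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lineage_id": l.lineage_id,
                "v_gene": l.v_gene,
                "j_gene": l.j_gene,
                "size": len(l.member_ids),
                "representative_cdr3_nt": l.representative_cdr3,
                "seeded": bool(l.seed_names),
                "seed_names": ",".join(sorted(l.seed_names)),
                "method": l.method,
            }
            for l in lineages
        ]
    )
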