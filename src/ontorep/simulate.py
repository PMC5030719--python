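"""Synthetic germline libraries and longitudinal BCR repertoires.

Emulates V(D)J recombination (junctional chewback and non-templated N
insertions), clonal expansion with somatic hypermutation accumulating
across time points (optional WRC/GYW hotspot bias), persistence of exact
sequences across time points, and a 454-style sequencing error layer
(substitutions plus rare 1-nt indels).  Every read carries a ground-truth
record (germline alleles, junction, lineage, first-emergence time point,
mutation load), so each pipeline stage can be tested without external
data.

All output is byte-deterministic given ``rng_seed``.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io
from .reference import GermlineGene, GermlineLibrary, annotate_anchors

_NT = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_NONSTOP = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


@dataclass
class SimConfig:
    """Study conditions for one synthetic longitudinal experiment."""

    rng_seed: int
    n_v: int = 8
    n_d: int = 6
    n_j: int = 4
    n_c: int = 2
    n_lineages: int = 3
    lineage_sizes: tuple[int, ...] = (15, 20, 25)
    timepoints: tuple[str, ...] = ("wk16", "wk34", "wk59")
    n_background: int = 30
    shm_rate: float = 0.02
    background_shm_rate: float | None = None
    sub_error_rate: float = 0.0
    indel_rate: float = 0.0
    chewback_max: int = 6
    n_insert_max: int = 12
    hotspot_multiplier: float = 2.0
    persist_prob: float = 0.15
    background_same_v: bool = False
    cdr3_aa_lens: tuple[int, ...] | None = None
    chain: str = "heavy"

    def __post_init__(self) -> None:
        for name in ("shm_rate", "sub_error_rate", "indel_rate", "persist_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_v < 1 or self.n_j < 1:
            raise ValueError("need at least one V and one J gene")
        if len(self.lineage_sizes) != len(self.timepoints):
            raise ValueError("lineage_sizes must match timepoints")
        if any(s < 0 for s in self.lineage_sizes) or self.n_background < 0:
            raise ValueError("sizes must be >= 0")

    @classmethod
    def from_file(cls, path: str) -> "SimConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("lineage_sizes", "timepoints", "cdr3_aa_lens"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=list)


@dataclass
class TruthRecord:
    read_id: str
    lineage_id: str
    timepoint: str
    v_allele: str
    d_allele: str | None
    j_allele: str | None
    junction_nt: str
    first_timepoint: str
    n_shm: int
    has_artifact_indel: bool


# ---------------------------------------------------------------------------
# germline synthesis


def _rand_codons(rng: np.random.Generator, n: int) -> str:
    return "".join(_NONSTOP[i] for i in rng.integers(0, len(_NONSTOP), size=n))


def _rand_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(_NT[rng.integers(0, 4, size=n)])


def make_germline(config: SimConfig) -> GermlineLibrary:
    """Synthetic germline library: V alleles of 296 nt ending in a
    conserved-Cys codon context, J alleles of ~50 nt containing a
    W-G-X-G motif, short D segments, and constant-region stubs.  A
    subset of V genes carries a second allele one substitution away."""
    rng = np.random.default_rng([config.rng_seed, 1])
    genes: list[GermlineGene] = []
    prefix = {"heavy": "IGH", "kappa": "IGK", "lambda": "IGL"}[config.chain]

    for g in range(config.n_v):
        body = _rand_codons(rng, 95)
        seq = body + "TGT" + "GCGAGAGA"  # Cys-104 codon at offset 285
        name = f"{prefix}V{g + 1}-1"
        genes.append(GermlineGene(f"{name}*01", "V", config.chain, seq))
        if g % 2 == 0:
            pos = int(rng.integers(0, 240))
            pos -= pos % 3  # keep the codon grid; swap the whole codon
            alt = seq[:pos] + _NONSTOP[rng.integers(0, len(_NONSTOP))] + seq[pos + 3 :]
            if alt != seq:
                genes.append(GermlineGene(f"{name}*02", "V", config.chain, alt))

    for g in range(config.n_j):
        while True:
            p = int(rng.integers(4, 11))
            # the 5' region upstream of the anchor sits in the anchor's
            # reading frame in a productive junction: build it backward
            # from the anchor out of non-stop codons
            pre = _rand_nt(rng, p % 3) + _rand_codons(rng, p // 3)
            motif = "TGGGGC" + _NONSTOP[rng.integers(0, len(_NONSTOP))] + "GGG"
            tail_codons = (50 - p - len(motif)) // 3
            tail = _rand_codons(rng, max(tail_codons, 4))
            seq = pre + motif + tail
            from .reference import find_j_anchor

            if find_j_anchor(seq) == p:
                break
        genes.append(GermlineGene(f"{prefix}J{g + 1}*01", "J", config.chain, seq))

    if config.chain == "heavy":
        for g in range(config.n_d):
            seq = _rand_nt(rng, int(rng.integers(10, 26)))
            genes.append(GermlineGene(f"{prefix}D{g + 1}-1*01", "D", config.chain, seq))
        for g in range(config.n_c):
            seq = _rand_nt(rng, 60)
            genes.append(GermlineGene(f"{prefix}G{g + 1}*01", "C", config.chain, seq))
    lib = annotate_anchors(GermlineLibrary(genes=genes))
    assert all(not g.unanchored for g in lib.genes if g.segment in "VJ")
    return lib


# ---------------------------------------------------------------------------
# mutation models


def shm_mutate(
    rng: np.random.Generator,
    seq: str,
    rate: float,
    hotspot_multiplier: float = 2.0,
) -> str:
    """Somatic hypermutation: Poisson(rate * L) substitutions at
    positions drawn with weight *hotspot_multiplier* on WRC/GYW motif
    targets (the mutated C of WRC, the G of GYW)."""
    L = len(seq)
    n = min(int(rng.poisson(rate * L)), L)
    if n == 0:
        return seq
    w = np.ones(L)
    if hotspot_multiplier != 1.0:
        for i in range(L):
            if (
                i >= 2
                and seq[i] == "C"
                and seq[i - 1] in "AG"
                and seq[i - 2] in "AT"
            ):
                w[i] = hotspot_multiplier
            elif (
                i + 2 < L
                and seq[i] == "G"
                and seq[i + 1] in "CT"
                and seq[i + 2] in "AT"
            ):
                w[i] = hotspot_multiplier
    pos = rng.choice(L, size=n, replace=False, p=w / w.sum())
    chars = list(seq)
    for p in pos:
        alts = [b for b in "ACGT" if b != chars[p]]
        chars[p] = alts[rng.integers(0, 3)]
    return "".join(chars)


def _frame0_stop(seq: str, upto: int) -> bool:
    return any(seq[p : p + 3] in _STOPS for p in range(0, upto - 2, 3))


def mutate_productive(
    rng: np.random.Generator,
    seq: str,
    rate: float,
    hotspot_multiplier: float,
    vdj_end: int,
) -> str:
    """SHM draw conditioned on the receptor staying productive: draws
    that introduce an in-frame stop codon in the V(D)J region are
    rejected (B cells with nonsense mutations are selected out)."""
    for _ in range(50):
        m = shm_mutate(rng, seq, rate, hotspot_multiplier)
        if not _frame0_stop(m, vdj_end):
            return m
    return seq


def sequencing_errors(
    rng: np.random.Generator, seq: str, sub_rate: float, indel_rate: float
) -> tuple[str, bool]:
    """Platform error layer: per-base substitutions plus (with
    probability *indel_rate* per read) one 1-nt insertion or deletion."""
    chars = list(seq)
    if sub_rate > 0:
        hits = np.nonzero(rng.random(len(chars)) < sub_rate)[0]
        for p in hits:
            alts = [b for b in "ACGT" if b != chars[p]]
            chars[p] = alts[rng.integers(0, 3)]
    has_indel = False
    if indel_rate > 0 and rng.random() < indel_rate:
        has_indel = True
        p = int(rng.integers(0, len(chars)))
        if rng.random() < 0.5:
            chars.insert(p, str(_NT[rng.integers(0, 4)]))
        else:
            del chars[p]
    return "".join(chars), has_indel


# ---------------------------------------------------------------------------
# recombination


def _recombine(
    rng: np.random.Generator,
    lib: GermlineLibrary,
    v: GermlineGene,
    d: GermlineGene | None,
    j: GermlineGene,
    c: GermlineGene | None,
    config: SimConfig,
    target_cdr3_aa: int | None = None,
) -> tuple[str, int, int]:
    """One naive V(D)J recombination; returns (sequence, cdr3_start,
    cdr3_end) with the CDR3 interval between (excluding) the V Cys codon
    and the J Trp codon, in frame and free of stop codons."""
    tail = len(v.sequence) - (v.anchor + 3)
    for _ in range(200):
        chew_v = int(rng.integers(0, min(config.chewback_max, tail) + 1))
        core = v.sequence[: len(v.sequence) - chew_v]
        chew_j = int(rng.integers(0, min(config.chewback_max, j.anchor) + 1))
        j_part = j.sequence[chew_j:]
        d_seq = ""
        if d is not None:
            cd5 = int(rng.integers(0, 3))
            cd3 = int(rng.integers(0, 3))
            d_seq = d.sequence[cd5 : len(d.sequence) - cd3]
        cdr3_start = v.anchor + 3
        fixed = (len(core) - cdr3_start) + len(d_seq) + (j.anchor - chew_j)
        n1 = int(rng.integers(0, config.n_insert_max + 1))
        if target_cdr3_aa is not None:
            n2 = 3 * target_cdr3_aa - fixed - n1
            if n2 < 0:
                continue
        else:
            n2 = int(rng.integers(0, config.n_insert_max + 1))
            n2 += (-(fixed + n1 + n2)) % 3
        seq = core + _rand_nt(rng, n1) + d_seq + _rand_nt(rng, n2) + j_part
        cdr3_end = cdr3_start + fixed + n1 + n2
        if any(
            seq[p : p + 3] in _STOPS for p in range(0, len(seq) - 2, 3)
        ):
            continue
        if c is not None:
            seq = seq + c.sequence
        return seq, cdr3_start, cdr3_end
    raise RuntimeError("could not generate a stop-free junction")


# ---------------------------------------------------------------------------
# repertoire simulation


def simulate_repertoire(
    config: SimConfig, lib: GermlineLibrary
) -> tuple[dict[str, list[tuple[str, str]]], pd.DataFrame]:
    """Simulate a longitudinal repertoire.

    Returns (per-timepoint reads, truth table).  Lineage reads descend
    from one naive recombination per lineage via a mutating trunk plus
    private mutations; exact earlier sequences are re-emitted at later
    time points with probability ``persist_prob``.  Background reads are
    independent singleton recombinations.
    """
    rng = np.random.default_rng([config.rng_seed, 2])
    vs = lib.alleles("V")
    ds = lib.alleles("D")
    js = lib.alleles("J")
    cs = lib.alleles("C")
    reads: dict[str, list[tuple[str, str]]] = {t: [] for t in config.timepoints}
    truth: list[TruthRecord] = []

    def pick(pool):
        return pool[int(rng.integers(0, len(pool)))] if pool else None

    lineage_founders = []
    for l in range(config.n_lineages):
        v, j = pick(vs), pick(js)
        d, c = pick(ds), pick(cs)
        target = (
            config.cdr3_aa_lens[l % len(config.cdr3_aa_lens)]
            if config.cdr3_aa_lens
            else None
        )
        naive, c3s, c3e = _recombine(rng, lib, v, d, j, c, config, target)
        vdj_end = len(naive) - (len(c.sequence) if c else 0)
        lineage_founders.append((v, d, j, naive, c3s, c3e, vdj_end))

    trunks = [f[3] for f in lineage_founders]
    vdj_ends = [f[6] for f in lineage_founders]
    emitted: list[dict[str, str]] = [dict() for _ in range(config.n_lineages)]
    pools: list[list[str]] = [[] for _ in range(config.n_lineages)]
    bg_rate = (
        config.background_shm_rate
        if config.background_shm_rate is not None
        else config.shm_rate
    )
    bg_v = lineage_founders[0][0] if (config.background_same_v and lineage_founders) else None

    for t, label in enumerate(config.timepoints):
        for l in range(config.n_lineages):
            v, d, j, naive, c3s, c3e, vdj_end = lineage_founders[l]
            trunks[l] = mutate_productive(
                rng, trunks[l], config.shm_rate, config.hotspot_multiplier, vdj_end
            )
            for i in range(config.lineage_sizes[t]):
                if pools[l] and rng.random() < config.persist_prob:
                    clean = pools[l][int(rng.integers(0, len(pools[l])))]
                else:
                    clean = mutate_productive(
                        rng, trunks[l], config.shm_rate * 0.5,
                        config.hotspot_multiplier, vdj_end,
                    )
                first = emitted[l].setdefault(clean, label)
                pools[l].append(clean)
                obs, has_indel = sequencing_errors(
                    rng, clean, config.sub_error_rate, config.indel_rate
                )
                rid = f"{label}_L{l:02d}_{i:04d}"
                reads[label].append((rid, obs))
                truth.append(
                    TruthRecord(
                        read_id=rid,
                        lineage_id=f"L{l:02d}",
                        timepoint=label,
                        v_allele=v.allele_name,
                        d_allele=d.allele_name if d else None,
                        j_allele=j.allele_name,
                        junction_nt=clean[c3s:c3e],
                        first_timepoint=first,
                        n_shm=sum(a != b for a, b in zip(clean, naive)),
                        has_artifact_indel=has_indel,
                    )
                )
        for b in range(config.n_background):
            v = bg_v if bg_v is not None else pick(vs)
            d, j, c = pick(ds), pick(js), pick(cs)
            naive, c3s, c3e = _recombine(rng, lib, v, d, j, c, config)
            clean = mutate_productive(
                rng, naive, bg_rate * (t + 1), config.hotspot_multiplier,
                len(naive) - (len(c.sequence) if c else 0),
            )
            obs, has_indel = sequencing_errors(
                rng, clean, config.sub_error_rate, config.indel_rate
            )
            rid = f"{label}_bg_{b:04d}"
            reads[label].append((rid, obs))
            truth.append(
                TruthRecord(
                    read_id=rid,
                    lineage_id=f"bg_{label}_{b:04d}",
                    timepoint=label,
                    v_allele=v.allele_name,
                    d_allele=d.allele_name if d else None,
                    j_allele=j.allele_name,
                    junction_nt=clean[c3s:c3e],
                    first_timepoint=label,
                    n_shm=sum(a != b_ for a, b_ in zip(clean, naive)),
                    has_artifact_indel=has_indel,
                )
            )
    truth_df = pd.DataFrame([dataclasses.asdict(r) for r in truth])
    return reads, truth_df


def write_outputs(
    out_dir: str,
    config: SimConfig,
    reads: dict[str, list[tuple[str, str]]],
    truth: pd.DataFrame,
) -> None:
    os.makedirs(out_dir, exist_ok=True)
    for label, recs in reads.items():
        io.write_fasta(os.path.join(out_dir, f"{label}.fasta"), recs)
    truth.to_csv(os.path.join(out_dir, "truth.tsv"), sep="\t", index=False)
    with open(os.path.join(out_dir, "sim_config.json"), "w") as fh:
        fh.write(config.to_json() + "\n")
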