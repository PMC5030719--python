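"""Shared fixtures: small simulated repertoires and hand-built germline
references used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from ontorep.annotate import annotate_reads
from ontorep.reference import GermlineGene, GermlineLibrary, annotate_anchors
from ontorep.simulate import SimConfig, make_germline, simulate_repertoire

# deterministic 61-codon alphabet for hand-built references
_NONSTOP = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def rand_codons(rng: np.random.Generator, n: int) -> str:
    return "".join(_NONSTOP[i] for i in rng.integers(0, len(_NONSTOP), size=n))


@pytest.fixture(scope="session")
def tiny_lib() -> GermlineLibrary:
    """Two V genes ending exactly at the conserved Cys codon and two J
    genes starting at the W-G-X-G motif, for constructed-read tests."""
    rng = np.random.default_rng(1234)
    genes = []
    for i in (1, 2):
        seq = rand_codons(rng, 95) + "TGT"
        genes.append(GermlineGene(f"IGHV{i}-1*01", "V", "heavy", seq))
    j1 = "TGGGGCCAAGGGACCACGGTCACCGTCTCCTCA"  # anchor at offset 0
    j2 = "TTTGGCCAGGGGACAATGGTCACCGTCTCTTCA"  # Phe variant
    genes.append(GermlineGene("IGHJ1*01", "J", "heavy", j1))
    genes.append(GermlineGene("IGHJ2*01", "J", "heavy", j2))
    genes.append(GermlineGene("IGHD1-1*01", "D", "heavy", "GTATTACGATTTTTGGAGTGGT"))
    genes.append(GermlineGene("IGHG1*01", "C", "heavy", rand_codons(rng, 20)))
    return annotate_anchors(GermlineLibrary(genes=genes))


@pytest.fixture(scope="session")
def sim_small():
    """Small error-free longitudinal repertoire with ground truth."""
    cfg = SimConfig(
        rng_seed=11,
        n_lineages=2,
        lineage_sizes=(8, 10),
        timepoints=("wk16", "wk34"),
        n_background=10,
        persist_prob=0.2,
    )
    lib = make_germline(cfg)
    reads, truth = simulate_repertoire(cfg, lib)
    return cfg, lib, reads, truth


@pytest.fixture(scope="session")
def annotated_small(sim_small):
    cfg, lib, reads, truth = sim_small
    flat = [r for recs in reads.values() for r in recs]
    return annotate_reads(flat, lib), lib, truth
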