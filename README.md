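# ontorep

Annotation, seeded lineage identification, and longitudinal ontogeny
analysis of B-cell receptor (BCR) repertoires.

## The problem

Affinity maturation turns a naive B cell's receptor into a potent
antibody through rounds of somatic hypermutation (SHM) and selection.
Tracking one antibody lineage — say, a broadly neutralizing antibody
isolated from an infected donor — through bulk BCR sequencing taken at
several time points requires three things that general-purpose
repertoire annotators do not provide together:

1. **Annotation**: assign each read its germline V/(D)/J genes by local
   alignment, extract the CDR3 (the V–D–J junction, the classic
   signature of clonal identity), and classify each read
   (`good`/`indel`/`stop`/`no_V`/…).
2. **Seeded lineage identification**: find the reads that belong to the
   *same clonal lineage* as one or more known "seed" antibodies — via
   identity–divergence islands (each read's % divergence from its
   germline V vs % identity to the seed), via iterative germline-rooted
   neighbor-joining ("intradonor") analysis, or via V/J + CDR3
   clustering.
3. **Ontogeny**: merge lineage members across time points (each distinct
   sequence gets a "birthday" — the first time point it was observed),
   build a germline-rooted maximum-likelihood tree with inferred
   ancestral sequences, pick developmental intermediates from the
   unmutated common ancestor (UCA) to an antibody of interest, collapse
   minor branches for display, and emit region/codon partitions for
   evolutionary-rate analysis.

A first-class synthetic-repertoire module (`ontorep.simulate`) emulates
V(D)J recombination, SHM accumulation across time points, and platform
sequencing error, recording full ground truth — so the entire pipeline
is testable without any external download.

## Core methods

- **Segment assignment** — affine-gap local alignment (match +5,
  mismatch −4, gap open −8, gap extend −2, BLAST gap-cost convention)
  of each read against the germline library; top allele reported, gene
  used downstream. CDR3 is delineated IMGT-style (positions 105–117):
  the nucleotides strictly between the V gene's 2nd conserved Cys codon
  (104) and the J gene's conserved Trp/Phe (118), mapped through the
  alignments.
- **Dereplication** — greedy centroid clustering at 99% global identity
  (gaps count as mismatches); clusters with fewer than 3 members are
  discarded as likely PCR/sequencing artifacts.
- **Intradonor analysis** — reads are shuffled into groups of ≤250,
  each group is star-aligned with the seeds and the germline V,
  a Saitou–Nei neighbor-joining tree is built on p-distances and rooted
  on the germline leaf, and reads inside the minimal clade spanning all
  seeds survive to the next round; convergence when ≥95% of a round's
  input survives.
- **ML trees** — HKY85 with empirical base frequencies, Felsenstein
  pruning over compressed site patterns, stepwise-addition starting
  trees from 3 random taxon orders, NNI hill climbing, outgroup rooting
  on the germline, and marginal ancestral reconstruction (per-site
  posterior argmax).

## Worked example

```python
from ontorep.simulate import SimConfig, make_germline, simulate_repertoire
from ontorep.annotate import annotate_reads, master_table

cfg = SimConfig(rng_seed=11, n_lineages=2, lineage_sizes=(8, 10),
                timepoints=("wk16", "wk34"), n_background=10)
lib = make_germline(cfg)                      # synthetic germline V/D/J/C
reads, truth = simulate_repertoire(cfg, lib)  # reads + ground truth
flat = [r for recs in reads.values() for r in recs]
ann = annotate_reads(flat, lib)
table = master_table(ann)
print(table["status"].value_counts().to_dict())
print(table[["read_id", "v_gene", "j_gene", "cdr3_aa"]].head(3).to_string(index=False))
```

prints

```
{'good': 56}
      read_id  v_gene j_gene            cdr3_aa
wk16_L00_0000 IGHV1-1  IGHJ4 ATFTVGLTPYLDPIHKDG
wk16_L00_0001 IGHV1-1  IGHJ4 ATFTVGLTPYLDPIHKDG
wk16_L00_0002 IGHV1-1  IGHJ4 ATFTVGLTPYLDPIHKDG
```

— all 56 reads are cleanly annotated (this configuration adds no
sequencing errors), the two planted lineages keep their germline gene
assignments, and within a lineage the CDR3s differ only by SHM.

The same pipeline is available from the shell via a single `ontorep`
entry point with one subcommand per stage (the numbered scripts of
classic annotation pipelines map onto `annotate`, `derep`, `id-div`,
`island`, `intradonor`, `lineages`, `merge`, `tree`, `intermediates`,
`collapse`, `partitions`, `plot`):

```
ontorep simulate --config sim.yaml --out sim/
ontorep annotate sim/wk34.fasta sim/wk59.fasta --lib-dir sim/germline --project-dir proj
ontorep derep --project-dir proj
ontorep id-div --seeds seeds.fasta --project-dir proj
ontorep intradonor --seeds seeds.fasta --germline IGHV3-30 --lib-dir sim/germline --project-dir proj
ontorep merge -F wk34.fasta -F wk59.fasta -l wk34 -l wk59 --project-dir proj
ontorep tree --aln merged_aln.fasta --germline-id germline --project-dir proj
```

Each stage writes into `output/{tables,sequences,plots,logs}` under the
project directory and refuses to overwrite existing outputs unless
`--force` is given.

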