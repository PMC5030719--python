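# Methods

This note documents the models, algorithms, parameter choices, and
known limitations of the package, in the order the pipeline runs.

## Germline references

A germline library is a set of alleles (`IGHV3-30*18` style names)
collapsed to genes at the `*` boundary. Alleles with identical
sequences are grouped: no alignment-based assigner can distinguish
them, so downstream analyses always work at the gene level, with the
top allele reported for completeness. IMGT-style pipe-delimited headers
are parsed for the functionality field; ORF and pseudogene (P) alleles
are excluded by default (retainable with a flag).

CDR3 anchors are found by motif heuristics rather than full IMGT gapped
numbering: for a V gene, the last in-frame TGT/TGC codon within the
final 12 codons (the 2nd conserved Cys, IMGT 104); for a J gene, the
first W/F-G-X-G motif (TGG/TTT/TTC followed by GG at +3 and +9; the
conserved Trp/Phe, IMGT 118). Alleles without a recognizable anchor are
flagged `unanchored` and excluded from CDR3 extraction but still used
for gene assignment. Coordinates are 0-based half-open internally;
emitted tables are 1-based inclusive.

## Annotation

**Alignment engine.** Scored local alignment uses Biopython's
`PairwiseAligner` with match +5, mismatch −4, gap open −8, gap
extend −2, under the BLAST gap-cost convention (a length-k gap costs
8 + 2k). Acceptance thresholds: V hits need score ≥ 400 and ≥ 50%
reference coverage (measured separation: random 400-mers top out near
220 against a 296-nt V library, while genuine reads at 20% SHM score
above 800); J ≥ 30; D ≥ 25 (≈5 consecutive matches); C ≥ 25. All
values are config-exposed (`AlignParams`). Reverse-strand V hits cause
the working read to be reverse-complemented.

Terminal aligned fragments shorter than 5 nt that are separated from
the alignment body by a gap are trimmed from each hit. Without this,
the local alignment routinely bridges a gap to match the chewed-off
germline terminus of the J (or V) against junction nucleotides; the
spurious gap would then trip the frameshift rule below. The hit score
is recomputed over the trimmed blocks.

**CDR3.** The V anchor's codon end and the J anchor's codon start are
mapped through the respective alignments into read coordinates; the
CDR3 is the read segment strictly between them (IMGT 105–117, anchors
excluded) and is translated when its length is a multiple of 3.
Extraction returns nothing when an anchor falls outside its alignment
or the mapped interval is empty.

**Status.** Precedence: `wrong_length` > `no_V` > `no_J` > `no_CDR3` >
`indel` > `stop` > `good`. Frameshift rule: total gap length in the V
or J alignment not divisible by 3 (a strict mode flags any V gap).
Stop-codon scan: the germline V's reading frame is propagated through
the alignment and the full V–J span is scanned; the frame is not
re-derived by ORF search. Length window default 300–600 nt (an
antibody variable region plus primers is ≈350–470 nt).

**Dereplication.** Identity is computed on a unit-cost global
(edit-distance) alignment: matches / alignment columns, gap columns
counting as mismatches; the argument order is canonicalized because
co-optimal paths can differ in column count. Exact duplicates collapse
first; distinct sequences are processed in decreasing (duplicate
count, length), then id, order — a fixed ordering that makes the
greedy clustering deterministic, unlike input-order-dependent UCLUST —
and each joins the first centroid at ≥ 99% identity. Clusters with
fewer than 3 members (defaults; both adjustable) are dropped, which
suppresses PCR/sequencing artifacts; surviving centroids are restatused
`unique`.

## Lineage identification

**Identity–divergence.** Divergence is the mismatch fraction of a
global alignment of the read's V-matched region against the matched
germline span (so partial V coverage is not penalized); identity to
each seed uses the full read. Island extraction takes a closed
rectangle on the (divergence, identity) plane.

**Intradonor analysis.** Each round: shuffle the surviving reads with
a seeded stream, split into chunks of ≤ 250 (`group_size`), align each
chunk plus the seed antibodies by a star multiple alignment around the
germline V (every sequence globally aligned to the germline;
insertions merged into shared padded columns), compute p-distances
with gap-containing columns pairwise-deleted, build a Saitou–Nei
neighbor-joining tree, root it on the germline leaf, and keep reads in
the minimal clade containing all seeds. Convergence: ≥ 95% of a
round's input survives. NJ ties in the Q matrix break on lexicographic
taxon-pair order; negative branch lengths are clamped to zero with the
deficit moved to the sister branch.

On simulations with a 50-member lineage at ~15% SHM among 450 same-V
background reads at ~5% SHM, recall of true members is typically high
but varies by seed (≈0.6–1.0 over random replicates, ~0.94 at the
fixed benchmark instance): when the within-lineage private mutation
load approaches the shared trunk, the seeds' minimal clade can exclude
genuine members or absorb background. This mirrors the method's known
behaviour on real data, where roughly a third of calls can be false
positives and manual curation is advised; the package reports
precision/recall against simulation truth and applies no automatic
filter.

**CDR3 clustering.** Reads group by assigned V and J gene (not
allele), then greedily cluster on CDR3 nucleotide identity (default
0.90, exposed) with the same deterministic ordering as dereplication.
Seed antibodies may be clustered along with the reads; any lineage
containing one is flagged seeded.

## Ontogeny

**Merging.** Sequences equal after uppercasing/degapping collapse into
one record whose `birthday` is the earliest time-point label (labels
are taken in the order supplied, never parsed); ids become
`<birthday>-<original id>` and `copies` counts all collapsed records.
Cross-time-point collapsing is exact equality — a fuzzier rule would
conflate SHM variants.

**ML tree.** HKY85 with empirical base frequencies (pseudocount 1) and
transition/transversion rate ratio κ = 2.0 (exposed). Likelihoods are
computed by Felsenstein pruning over unique site patterns with
per-node scaling; gaps and ambiguous bases are missing data. The
search runs stepwise addition (each insertion scored by optimizing
only the three branches it creates) followed by greedy NNI hill
climbing (candidates scored by optimizing the branches around the
swapped edge; accepted trees fully re-optimized, so the reported
likelihood never decreases), from 3 random taxon addition orders,
keeping the best. Branch lengths use bounded Brent per branch
(bounds [1e-9, 10], xatol 1e-6). The tree is rooted on the germline
edge (its length split evenly) and marginal ancestral states are
reconstructed by an up–down pass; per-site posterior argmax with ties
broken by base order A<C<G<T. For ≤ 7 taxa an exhaustive enumeration
over all unrooted topologies under the identical likelihood serves as
the oracle in tests; two topologies attaining the same optimum within
1e-5 log-units are treated as co-optimal.

**Intermediates.** The path runs from the UCA (the root child opposite
the germline) to the target leaf. Amino-acid changes between
consecutive node translations are accumulated codon-wise, skipping
codons containing gaps, ambiguity, or stops. "n approximately equally
spaced intermediates" selects the path nodes nearest the even
quantiles i·total/(n+1), ties to the earlier node; spacing mode emits
greedily every ≥ `spacing_aa` changes. The UCA is always first.

**Collapsing.** Post-order traversal; a clade is collapsible iff it
contains no keep-listed or non-NGS leaf and every member CDR3 is
within the identity threshold of the clade's plurality CDR3 (ties to
the lexicographically smallest). Maximal collapsible clades of ≥
`min_size` leaves become one pseudo-leaf labeled
`<representative>|<size>`; smaller ones are pruned. The summary table
reports each major branch's size, birthday span (temporal
persistence), and representative CDR3; the pruned-leaf count is kept
in the table's `attrs`.

**Partitions.** Given per-column region labels (FWR1–4, CDR1–3,
`junction` counting as CDR), five partitions are emitted — full
V(D)J, CDR union, FWR union, codon positions 1+2, position 3 — as a
NEXUS sets block with 1-based inclusive charset ranges (the
computation a rate-analysis configuration needs; emitting any
particular tool's XML dialect is out of scope).

## Synthetic repertoires

The generator emulates, per lineage: one naive V(D)J recombination
(chewback ≤ 6 nt per junction side, N insertions ≤ 12 nt, junction
forced in-frame and stop-free — junctions that would be unproductive
are redrawn, as selection discards such cells); a mutating trunk
accumulating `shm_rate` substitutions/site per time step plus
per-read private mutations at half that rate, with a 2× weight on
WRC/GYW hotspot motifs and nonsense draws rejected; re-emission of
exact earlier sequences at later time points with probability
`persist_prob` (0.15), which exercises cross-time-point collapsing;
and a sequencing layer of per-base substitutions plus (with per-read
probability `indel_rate`) one 1-nt indel, 454-style. Background reads
are independent singleton recombinations. Default study conditions:
3 lineages sampled (15, 20, 25) reads across 3 time points plus 30
background reads per time point, `shm_rate` 0.02, error rates 0.
Ground truth records germline alleles, the junction (always a
substring of the error-free read), lineage membership, first-emergence
time point, mutation count, and the indel flag; all output is
byte-deterministic given `rng_seed`.

What the simulator does **not** model — and hence what passing tests
cannot show about real data: realistic gene-usage frequencies, allele
polymorphism between donors, class switching, paired heavy/light
chains, position-specific mutability profiles beyond the 2× hotspot
weight, homopolymer-length errors, and primer/barcode artifacts.

## Problem sizes

The shipped test-and-benchmark workloads use: 200 random 5–8-taxon
additive trees for NJ; 50 alignments of 5 taxa × 600 sites for ML vs
exhaustive search; ~2,000 error-free simulated reads for annotation
truth recovery; 500 reads (50 lineage + 450 background) for the
intradonor benchmark; 500 reads for the dereplication oracle. These
sizes make every oracle exact or exhaustive while keeping a full run
in minutes on one CPU core.

## Known limitations

- The ML engine recomputes the full tree likelihood per branch
  evaluation; it is meant for lineage-sized trees (tens to a few
  hundred leaves), not repertoire-scale phylogenies.
- The frameshift rule sees only alignment gaps; a sequencing indel
  pair that restores frame within one codon is invisible to it.
- The stop-codon scan assumes the frame survives across mod-3 gap
  patterns; pathological double-indel reads can be misscanned (they
  are flagged `indel` first in practice).
- Identity arithmetic is defined on unit-cost alignments; scores from
  affine-gap alignments are not comparable to it.
- Intradonor results depend on seed choice and chunking randomness
  (see above); the rng seed is a required, logged parameter.
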