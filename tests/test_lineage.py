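"""Identity-divergence tables and islands, neighbor joining, intradonor
analysis, and CDR3 lineage clustering."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from ontorep.align import divergence_pct
from ontorep.annotate import annotate_reads
from ontorep.lineage import (
    CdrRecord,
    Island,
    calc_id_div,
    cluster_cdr3_lineages,
    get_island,
    has_converged,
    intradonor_analysis,
    neighbor_joining,
    p_distance_matrix,
    star_msa,
)
from ontorep.phylo import (
    Node,
    additive_tree_distances,
    mrca,
    reroot_on_leaf,
    same_topology,
)
from ontorep.simulate import SimConfig, make_germline, simulate_repertoire


def random_additive_tree(names, rng, lo=0.05, hi=1.0):
    nodes = [Node(n, float(rng.uniform(lo, hi))) for n in names]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = Node(None, float(rng.uniform(lo, hi)))
        parent.add(nodes[i])
        parent.add(nodes[j])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    root = Node()
    for x in nodes:
        root.add(x)
    return root


class TestIdDiv:
    def test_unmutated_copy_of_germline_against_itself(self, sim_small):
        _, lib, _, _ = sim_small
        g = lib.alleles("V")[0]
        read = g.sequence + "GCGAGAGAT" + lib.alleles("J")[0].sequence
        ann = annotate_reads([("r1", read)], lib, min_len=100)
        recs = calc_id_div(ann, [("seedX", read)], lib)
        assert recs[0].divergence_pct == pytest.approx(0.0)
        assert recs[0].identity_pct["seedX"] == pytest.approx(100.0)

    def test_divergence_arithmetic(self):
        # 12 substitutions over a 300-column gap-free alignment = 4%
        rng = np.random.default_rng(2)
        a = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        chars = list(a)
        for p in rng.choice(300, 12, replace=False):
            chars[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[chars[p]]
        assert divergence_pct("".join(chars), a) == pytest.approx(4.0)

    def test_reads_without_v_are_skipped(self, sim_small):
        _, lib, _, _ = sim_small
        from ontorep.annotate import AnnotatedRead

        recs = calc_id_div(
            [AnnotatedRead(read_id="x", sequence="ACGT", status="no_V")],
            [("s", "ACGT")],
            lib,
        )
        assert recs == []

    def test_island_bounds_are_closed(self):
        isl = Island("s", min_identity=85.0)
        recs = [
            type("R", (), {"read_id": "a", "divergence_pct": 4.0, "identity_pct": {"s": 90.0}})(),
            type("R", (), {"read_id": "b", "divergence_pct": 4.0, "identity_pct": {"s": 85.0}})(),
            type("R", (), {"read_id": "c", "divergence_pct": 4.0, "identity_pct": {"s": 84.9}})(),
        ]
        assert get_island(recs, isl) == {"a", "b"}
        with pytest.raises(KeyError):
            get_island(recs, Island("unknown", 85.0))

    def test_two_population_island_recovers_truth(self):
        cfg = SimConfig(
            rng_seed=21, n_lineages=1, lineage_sizes=(20,), timepoints=("wk34",),
            n_background=60, background_same_v=True, shm_rate=0.06,
            background_shm_rate=0.04, persist_prob=0.0,
        )
        lib = make_germline(cfg)
        reads, truth = simulate_repertoire(cfg, lib)
        ann = annotate_reads(reads["wk34"], lib)
        members = set(truth[truth.lineage_id == "L00"].read_id)
        seed_read = next(a for a in ann if a.read_id in members)
        recs = calc_id_div(ann, [("seed", seed_read.sequence)], lib)
        picked = get_island(recs, Island("seed", min_identity=88.0))
        assert picked == members

    def test_lineage_occupies_high_identity_region(self, annotated_small):
        ann, lib, truth = annotated_small
        members = set(truth[truth.lineage_id == "L00"].read_id)
        seed = next(a for a in ann if a.read_id in members)
        recs = calc_id_div([a for a in ann if a.v_hit], [("s", seed.sequence)], lib)
        inside = [r.identity_pct["s"] for r in recs if r.read_id in members]
        outside = [r.identity_pct["s"] for r in recs if r.read_id not in members]
        assert min(inside) > max(outside)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = np.array([[0.0, 5, 9], [5, 0, 10], [9, 10, 0]])
        tree = neighbor_joining(["a", "b", "c"], D)
        bl = {n.name: n.length for n in tree.children}
        assert bl["a"] == pytest.approx((5 + 9 - 10) / 2, abs=1e-9)
        assert bl["b"] == pytest.approx((5 + 10 - 9) / 2, abs=1e-9)
        assert bl["c"] == pytest.approx((9 + 10 - 5) / 2, abs=1e-9)

    @pytest.mark.parametrize("rep", range(20))
    def test_additive_tree_topology_recovered(self, rep):
        rng = np.random.default_rng(100 + rep)
        k = int(rng.integers(5, 9))
        tree = random_additive_tree([f"t{i}" for i in range(k)], rng)
        names, D = additive_tree_distances(tree)
        assert same_topology(neighbor_joining(names, D), tree)

    def test_zero_distance_pair_merged_first(self):
        # a and b are identical: they must come out as a cherry
        D = np.array(
            [
                [0.0, 0.0, 4.0, 6.0],
                [0.0, 0.0, 4.0, 6.0],
                [4.0, 4.0, 0.0, 6.0],
                [6.0, 6.0, 6.0, 0.0],
            ]
        )
        tree = neighbor_joining(["a", "b", "c", "d"], D)
        cherry = next(n for n in tree.postorder() if not n.is_leaf and n.parent)
        assert cherry.leaf_names() == {"a", "b"}

    def test_matches_independent_skbio_implementation(self):
        skbio = pytest.importorskip("skbio")
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(4)
        for _ in range(5):
            k = 7
            names = [f"t{i}" for i in range(k)]
            tree = random_additive_tree(names, rng)
            _, D = additive_tree_distances(tree)
            D += rng.uniform(0, 0.05, D.shape)  # mild noise
            D = (D + D.T) / 2
            np.fill_diagonal(D, 0.0)
            ours = neighbor_joining(names, D)
            theirs = skbio_nj(skbio.DistanceMatrix(D, names))
            their_splits = set()
            for node in theirs.non_tips():
                side = frozenset(t.name for t in node.tips())
                other = frozenset(names) - side
                if len(side) >= 2 and len(other) >= 2:
                    their_splits.add(min(side, other, key=lambda s: sorted(s)))
            from ontorep.phylo import splits

            assert splits(ours) == their_splits

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            neighbor_joining(["a", "b"], np.zeros((2, 2)))


class TestStarMsa:
    def test_alignment_columns_and_pdistance(self):
        msa = star_msa(("ref", "ACGTACGT"), [("a", "ACGTACGT"), ("b", "ACGAACGT"), ("c", "ACGTTACGT")])
        lengths = {len(s) for s in msa.values()}
        assert len(lengths) == 1
        names, D = p_distance_matrix(msa)
        i, j = names.index("ref"), names.index("a")
        assert D[i, j] == pytest.approx(0.0)
        k = names.index("b")
        assert D[i, k] == pytest.approx(1 / 8)


@pytest.fixture(scope="module")
def scenario():
    cfg = SimConfig(
        rng_seed=7, n_lineages=1, lineage_sizes=(28,), timepoints=("wk34",),
        n_background=120, background_same_v=True, shm_rate=0.10,
        background_shm_rate=0.05, persist_prob=0.0,
    )
    lib = make_germline(cfg)
    reads, truth = simulate_repertoire(cfg, lib)
    members = set(truth[truth.lineage_id == "L00"].read_id)
    lin = [(r, s) for r, s in reads["wk34"] if r in members]
    seeds = [(f"mAb{i}", s) for i, (_, s) in enumerate(lin[:3])]
    pool = lin[3:] + [(r, s) for r, s in reads["wk34"] if r not in members]
    germ = lib.get(truth[truth.lineage_id == "L00"].v_allele.iloc[0])
    return pool, seeds, (germ.allele_name, germ.sequence), {r for r, _ in lin[3:]}


class TestIntradonor:
    def test_recall_and_monotone_shrinkage(self, scenario):
        pool, seeds, germ, true_members = scenario
        trace: list[set] = []
        surv = intradonor_analysis(
            pool, seeds, germ, group_size=100, rng_seed=42, trace=trace
        )
        assert len(surv & true_members) / len(true_members) >= 0.9
        for earlier, later in zip(trace, trace[1:]):
            assert later <= earlier

    def test_pure_lineage_converges_in_one_round(self):
        # a serial-accumulation lineage bracketed by two seed antibodies:
        # every read lies inside the seeds' minimal clade, so one round
        # retains everything
        rng = np.random.default_rng(3)
        germ_seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 150))

        def ladder(k):
            chars = list(germ_seq)
            for p in range(2 * k):
                chars[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[chars[p]]
            return "".join(chars)

        seeds = [("mAbLo", ladder(1)), ("mAbHi", ladder(20))]
        pool = [(f"r{k:02d}", ladder(k)) for k in range(2, 20)]
        trace: list[set] = []
        surv = intradonor_analysis(
            pool, seeds, ("germV", germ_seq), group_size=100, rng_seed=1,
            trace=trace,
        )
        assert len(trace) == 1
        assert surv == {r for r, _ in pool}

    def test_single_chunk_max_one_iter_equals_one_shot_mrca(self, scenario):
        pool, seeds, germ, _ = scenario
        surv = intradonor_analysis(
            pool, seeds, germ, group_size=len(pool) + len(seeds) + 1,
            converge=1.0, max_iters=1, rng_seed=5,
        )
        # oracle: one star alignment, one NJ tree, one clade extraction
        msa = star_msa(germ, pool + seeds)
        names, D = p_distance_matrix(msa)
        tree = neighbor_joining(names, D)
        rooted = reroot_on_leaf(tree, germ[0])
        clade = mrca(rooted, {n for n, _ in seeds})
        expect = clade.leaf_names() - {n for n, _ in seeds} - {germ[0]}
        assert surv == expect

    def test_convergence_rule_is_95_percent(self):
        assert has_converged(96, 100)
        assert not has_converged(94, 100)
        assert has_converged(95, 100)

    def test_group_size_must_cover_seeds(self, scenario):
        pool, seeds, germ, _ = scenario
        with pytest.raises(ValueError):
            intradonor_analysis(pool, seeds, germ, group_size=2 * len(seeds) - 1)


class TestCdr3Clustering:
    def test_identical_cdr3_same_genes_is_one_lineage(self):
        reads = [
            CdrRecord("a", "IGHV1-1", "IGHJ1", "GCGAGAGAT"),
            CdrRecord("b", "IGHV1-1", "IGHJ1", "GCGAGAGAT"),
        ]
        out = cluster_cdr3_lineages(reads)
        assert len(out) == 1 and out[0].member_ids == {"a", "b"}

    def test_grouping_by_gene_precedes_clustering(self):
        reads = [
            CdrRecord("a", "IGHV1-1", "IGHJ1", "GCGAGAGAT"),
            CdrRecord("b", "IGHV2-1", "IGHJ1", "GCGAGAGAT"),
        ]
        assert len(cluster_cdr3_lineages(reads)) == 2

    def test_planted_lineages_recovered_exactly(self, annotated_small):
        ann, _, truth = annotated_small
        good = [a for a in ann if a.status == "good" and a.cdr3_nt]
        out = cluster_cdr3_lineages(good, identity=0.90)
        assign = {}
        for l in out:
            for m in l.member_ids:
                assign[m] = l.lineage_id
        tmap = truth.set_index("read_id")["lineage_id"]
        ids = [a.read_id for a in good]
        ari = adjusted_rand_score(
            [tmap[i] for i in ids], [assign[i] for i in ids]
        )
        assert ari == pytest.approx(1.0)

    def test_output_partitions_cdr3_bearing_reads(self, annotated_small):
        ann, _, _ = annotated_small
        good = [a for a in ann if a.status == "good" and a.cdr3_nt]
        out = cluster_cdr3_lineages(good)
        members = [m for l in out for m in l.member_ids]
        assert sorted(members) == sorted(a.read_id for a in good)

    def test_seeded_lineage_is_flagged(self):
        reads = [CdrRecord(f"r{i}", "IGHV1-1", "IGHJ1", "GCGAGAGAT") for i in range(3)]
        seeds = [CdrRecord("mAb1", "IGHV1-1", "IGHJ1", "GCGAGAGAT")]
        out = cluster_cdr3_lineages(reads, seeds=seeds)
        assert len(out) == 1
        assert out[0].seed_names == {"mAb1"}
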