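"""Timepoint merging, ML trees with ancestors, intermediate selection,
branch collapsing, and rate-analysis partitions."""

import numpy as np
import pytest

from ontorep.mltree import (
    HKYModel,
    TreeLikelihood,
    empirical_freqs,
    encode_alignment,
    enumerate_topologies,
    exhaustive_ml_tree,
    search_ml_tree,
)
from ontorep.ontogeny import (
    OntogenyTree,
    aa_changes,
    build_ml_tree,
    collapse_minor_branches,
    merge_timepoints,
    mrca_node,
    parse_nexus_charsets,
    partition_alignment,
    pick_intermediates,
    write_nexus_charsets,
)
from ontorep.phylo import Node, from_newick, reroot_on_leaf, same_topology


class TestMergeTimepoints:
    def test_sequence_seen_twice_gets_earliest_birthday(self):
        rec = merge_timepoints(
            [[("x", "ACGT")], [("y", "ACGT")]], ["wk34", "wk59"]
        )
        assert len(rec) == 1
        t = rec[0]
        assert t.birthday == "wk34"
        assert t.observed_at == {"wk34", "wk59"}
        assert t.copies == 2
        assert t.seq_id == "wk34-x"

    def test_distinct_sequences_stay_distinct(self):
        rec = merge_timepoints([[("x", "ACGT")], [("y", "ACGA")]], ["a", "b"])
        assert {t.seq_id for t in rec} == {"a-x", "b-y"}

    def test_duplicate_id_within_one_file_is_an_error(self):
        with pytest.raises(ValueError, match="duplicate"):
            merge_timepoints([[("x", "ACGT"), ("x", "ACGA")]], ["a"])

    def test_copies_are_conserved(self, sim_small):
        cfg, _, reads, _ = sim_small
        rec = merge_timepoints(
            [reads[t] for t in cfg.timepoints], list(cfg.timepoints)
        )
        assert sum(t.copies for t in rec) == sum(len(v) for v in reads.values())
        assert all(t.observed_at <= set(cfg.timepoints) for t in rec)

    def test_birthdays_match_recorded_first_emergence(self, sim_small):
        cfg, _, reads, truth = sim_small
        rec = merge_timepoints(
            [reads[t] for t in cfg.timepoints], list(cfg.timepoints)
        )
        first = truth.set_index("read_id")["first_timepoint"]
        seq_first = {}
        by_id = truth.set_index("read_id")
        seqs = {rid: s for recs in reads.values() for rid, s in recs}
        for t in rec:
            # the truth's first emergence of this exact sequence
            expected = min(
                (first[rid] for rid, s in seqs.items() if s == t.sequence),
                key=list(cfg.timepoints).index,
            )
            assert t.birthday == expected


@pytest.fixture(scope="module")
def model5():
    return HKYModel(np.array([0.3, 0.2, 0.25, 0.25]), kappa=2.0)


def sim_alignment(tree, L, model, rng):
    """Simulate sequences down a tree under the HKY transition matrices
    (the independent generator for ML tests)."""
    seqs = {}

    def visit(node, anc):
        P = model.P(node.length)
        out = np.array([rng.choice(4, p=P[s]) for s in anc])
        if node.is_leaf:
            seqs[node.name] = "".join("ACGT"[i] for i in out)
        for c in node.children:
            visit(c, out)

    root_state = rng.choice(4, size=L, p=model.freqs)
    for c in tree.children:
        visit(c, root_state)
    return seqs


def random_topology(names, rng, lo=0.02, hi=0.3):
    nodes = [Node(n, float(rng.uniform(lo, hi))) for n in names]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        p = Node(None, float(rng.uniform(lo, hi)))
        p.add(nodes[i])
        p.add(nodes[j])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [p]
    root = Node()
    for x in nodes:
        root.add(x)
    return root


class TestMlTree:
    def test_identical_sequences_collapse_to_zero_branches(self):
        aln = {f"s{i}": "ACGTACGTACGTACGTACGT" for i in range(4)}
        aln["germ"] = aln["s0"]
        result = build_ml_tree(aln, "germ", n_orders=1, rng_seed=0)
        for n in result.root.postorder():
            if n.parent is not None:
                assert n.length < 1e-6
        for seq in result.ancestor_seqs.values():
            assert seq == aln["germ"]

    def test_enumeration_counts(self):
        assert len(enumerate_topologies(list("abcde"))) == 15
        assert len(enumerate_topologies(list("abcd"))) == 3

    @pytest.mark.parametrize("rep", range(4))
    def test_search_matches_exhaustive_on_5_taxa(self, rep, model5):
        rng = np.random.default_rng(500 + rep)
        tree = random_topology([f"t{i}" for i in range(5)], rng)
        aln = sim_alignment(tree, 600, model5, rng)
        found, ll_s, _, _ = search_ml_tree(aln, n_orders=3, rng_seed=rep)
        best, ll_e = exhaustive_ml_tree(aln)
        assert same_topology(found, best) or abs(ll_s - ll_e) < 1e-5

    def test_likelihood_nondecreasing_over_nni(self, model5):
        from ontorep.mltree import nni_search, stepwise_addition

        rng = np.random.default_rng(9)
        tree = random_topology([f"t{i}" for i in range(6)], rng)
        aln = sim_alignment(tree, 300, model5, rng)
        codes, w, _ = encode_alignment(aln)
        calc = TreeLikelihood(codes, w, HKYModel(empirical_freqs(aln)))
        start = stepwise_addition(sorted(aln), calc)
        ll0 = calc.loglik(start)
        _, ll1 = nni_search(start, calc)
        assert ll1 >= ll0 - 1e-9

    def test_ancestral_states_match_brute_force_marginalization(self):
        seqs = {"germ": "ACGTACGTAC", "a": "ACGTACGTAT", "b": "ACGAACGTAC"}
        codes, w, _ = encode_alignment(seqs)
        model = HKYModel(empirical_freqs(seqs))
        calc = TreeLikelihood(codes, w, model)
        tree, _, _, _ = search_ml_tree(seqs, n_orders=1, rng_seed=0)
        rooted = reroot_on_leaf(tree, "germ")
        post = calc.marginal_posteriors(rooted)
        v = next(c for c in rooted.children if c.name != "germ")
        germ = next(c for c in rooted.children if c.name == "germ")
        Pg, Pv = model.P(germ.length), model.P(v.length)
        Pa, Pb = model.P(v.children[0].length), model.P(v.children[1].length)
        la = calc._leaf_partials[v.children[0].name]
        lb = calc._leaf_partials[v.children[1].name]
        lg = calc._leaf_partials["germ"]
        brute = np.zeros((len(w), 4))
        for p in range(len(w)):
            for x in range(4):
                for y in range(4):
                    brute[p, y] += (
                        model.freqs[x]
                        * (Pg[x] @ lg[p])
                        * Pv[x, y]
                        * (Pa[y] @ la[p])
                        * (Pb[y] @ lb[p])
                    )
        brute /= brute.sum(axis=1, keepdims=True)
        assert np.abs(brute - post[id(v)]).max() < 1e-9

    def test_unaligned_input_is_an_error(self):
        with pytest.raises(ValueError):
            build_ml_tree({"a": "ACGT", "b": "ACG", "germ": "ACGT"}, "germ")

    def test_too_few_taxa_is_an_error(self):
        with pytest.raises(ValueError):
            build_ml_tree({"a": "ACGT", "germ": "ACGT"}, "germ")


def chain_tree(aa_steps, base_len=60):
    """OntogenyTree whose UCA->target path has the given per-edge
    amino-acid changes, built from synthetic codon sequences."""
    rng = np.random.default_rng(0)
    codons = ["GCT", "TGT", "GAT", "GAA", "TTT", "GGT", "CAT", "ATT", "AAA", "CTT"]
    n_codons = base_len // 3
    seq = ["GCT"] * n_codons
    seqs = ["".join(seq)]
    pos = 0
    for step in aa_steps:
        for _ in range(step):
            pos += 1
            seq[pos] = codons[1 + pos % 9]
        seqs.append("".join(seq))

    germ = Node("germline", 0.01)
    root = Node()
    root.add(germ)
    parent = root
    names = []
    anc = {}
    for i, s in enumerate(seqs[:-1]):
        node = Node(f"anc{i:03d}", 0.01)
        parent.add(node)
        anc[node.name] = s
        parent = node
        names.append(node.name)
    target = Node("mAb1", 0.01)
    parent.add(target)
    aln = {"mAb1": seqs[-1], "germline": seqs[0]}
    return OntogenyTree(
        root=root, germline_id="germline", alignment=aln,
        ancestor_seqs=anc, loglik=0.0,
    ), names


class TestIntermediates:
    def test_even_quantile_selection(self):
        # cumulative changes 0,2,5,8,12; n=3 -> targets 3,6,9 -> 2,5,8
        tree, names = chain_tree([2, 3, 3, 4])
        picks = pick_intermediates(tree, "mAb1", n=3)
        assert picks[0] == (names[0], 0)
        assert [c for _, c in picks[1:]] == [2, 5, 8]

    def test_spacing_mode(self):
        tree, names = chain_tree([2, 3, 3, 4])
        picks = pick_intermediates(tree, "mAb1", spacing_aa=5)
        assert [c for _, c in picks] == [0, 5, 12]

    def test_no_change_returns_only_the_uca(self):
        tree, names = chain_tree([0, 0])
        picks = pick_intermediates(tree, "mAb1", n=3)
        assert picks == [(names[0], 0)]

    def test_cumulative_changes_nondecreasing(self):
        tree, _ = chain_tree([1, 4, 0, 2, 3])
        picks = pick_intermediates(tree, "mAb1", n=4)
        cums = [c for _, c in picks]
        assert cums == sorted(cums)

    def test_exactly_one_mode_required(self):
        tree, _ = chain_tree([2, 3])
        with pytest.raises(ValueError):
            pick_intermediates(tree, "mAb1")
        with pytest.raises(ValueError):
            pick_intermediates(tree, "mAb1", n=2, spacing_aa=3)

    def test_mrca_of_two_leaves(self):
        root = Node()
        root.add(Node("germline", 0.1))
        u = Node("u", 0.1)
        root.add(u)
        a = Node("a", 0.1)
        inner = Node("inner", 0.1)
        u.add(a)
        u.add(inner)
        inner.add(Node("b", 0.1))
        inner.add(Node("c", 0.1))
        tree = OntogenyTree(
            root=root, germline_id="germline", alignment={}, ancestor_seqs={},
            loglik=0.0,
        )
        assert mrca_node(tree, {"b", "c"}).name == "inner"
        assert mrca_node(tree, {"a", "b"}).name == "u"

    def test_stop_containing_codons_are_excluded(self):
        assert aa_changes("TAAGCT", "TAAGAT") == 1
        assert aa_changes("TAAGCT", "TGAGCT") == 0


def display_tree(clades, keep_extra=None):
    """Rooted tree: germline + one subtree per (cdr3, n_leaves) clade."""
    root = Node()
    root.add(Node("germline", 0.01))
    uca = Node("uca", 0.01)
    root.add(uca)
    cdr3_map = {}
    for ci, (cdr3, n) in enumerate(clades):
        clade = Node(f"cl{ci}", 0.01)
        uca.add(clade)
        for i in range(n):
            name = f"c{ci}_leaf{i:02d}"
            clade.add(Node(name, 0.01))
            cdr3_map[name] = cdr3
    for name, sibling_cdr3 in (keep_extra or []):
        clade = Node(None, 0.01)
        uca.add(clade)
        clade.add(Node(name, 0.01))
        sib = Node(f"{name}_sib", 0.01)
        clade.add(sib)
        cdr3_map[sib.name] = sibling_cdr3
    tree = OntogenyTree(
        root=root, germline_id="germline", alignment={}, ancestor_seqs={},
        loglik=0.0,
    )
    return tree, cdr3_map


class TestCollapse:
    def test_single_shared_cdr3_collapses_to_one_major_branch(self):
        tree, cdr3_map = display_tree([("GCGAGAGATTTT", 10)])
        collapsed, table = collapse_minor_branches(
            tree, cdr3_map, identity=0.85, min_size=3
        )
        assert len(table) == 1
        assert table.iloc[0]["size"] == 10

    def test_keep_leaf_survives_and_sibling_is_pruned(self):
        tree, cdr3_map = display_tree(
            [("GCGAGAGATTTT", 6)], keep_extra=[("mAb1", "TTTTTTTTTTTT")]
        )
        collapsed, table = collapse_minor_branches(
            tree, cdr3_map, identity=0.85, min_size=5, keep={"mAb1"}
        )
        names = collapsed.leaf_names()
        assert "mAb1" in names
        assert "mAb1_sib" not in names

    def test_planted_clades_below_min_size_are_dropped(self):
        tree, cdr3_map = display_tree(
            [("GCGAGAGATTTT", 20), ("TTTACGTACGTA", 15), ("CCCCCCGGGGGG", 2)]
        )
        collapsed, table = collapse_minor_branches(
            tree, cdr3_map, identity=0.85, min_size=5
        )
        assert sorted(table["size"]) == [15, 20]

    def test_leaf_bookkeeping(self):
        tree, cdr3_map = display_tree(
            [("GCGAGAGATTTT", 7), ("CCCCCCGGGGGG", 2)]
        )
        n_leaves = len(tree.root.leaves())
        collapsed, table = collapse_minor_branches(
            tree, cdr3_map, identity=0.85, min_size=5
        )
        pruned = table.attrs["n_pruned"]
        kept_single = len([l for l in collapsed.leaves() if "|" not in (l.name or "")])
        assert table["size"].sum() + pruned + kept_single == n_leaves


class TestPartitions:
    LABELS = ["FWR1"] * 12 + ["CDR1"] * 6 + ["FWR2"] * 9

    def test_codon_position_arithmetic(self):
        parts = partition_alignment(self.LABELS)
        assert len(parts["pos12"]) == 18
        assert len(parts["pos3"]) == 9

    def test_partitions_cover_and_are_disjoint(self):
        parts = partition_alignment(self.LABELS)
        L = len(self.LABELS)
        assert sorted(parts["CDR"] + parts["FWR"]) == list(range(L))
        assert set(parts["CDR"]) & set(parts["FWR"]) == set()
        assert sorted(parts["pos12"] + parts["pos3"]) == list(range(L))
        assert set(parts["pos12"]) & set(parts["pos3"]) == set()
        assert parts["VDJ"] == list(range(L))

    def test_nexus_charsets_round_trip(self):
        parts = partition_alignment(self.LABELS)
        text = write_nexus_charsets(parts)
        again = parse_nexus_charsets(text)
        assert again == {k: sorted(v) for k, v in parts.items()}

    def test_bad_labels_are_an_error(self):
        with pytest.raises(ValueError, match="region label"):
            partition_alignment(["FWR1", "??", "FWR1"])
        with pytest.raises(ValueError, match="divisible"):
            partition_alignment(["FWR1"] * 4)


class TestEndToEndTree:
    def test_simulated_lineage_tree_recovers_birthdays_and_root(self, sim_small):
        cfg, lib, reads, truth = sim_small
        members = truth[truth.lineage_id == "L00"]
        chosen = set(members.read_id)
        per_tp = [
            [(r, s) for r, s in reads[t] if r in chosen] for t in cfg.timepoints
        ]
        merged = merge_timepoints(per_tp, list(cfg.timepoints))
        # align trivially: substitution-only simulation keeps lengths equal
        lens = {len(t.sequence) for t in merged}
        assert len(lens) == 1
        germ = lib.get(members.v_allele.iloc[0])
        aln = {t.seq_id: t.sequence for t in merged}
        aln["germline"] = (germ.sequence + "N" * 1000)[: lens.pop()]
        birthdays = {t.seq_id: t.birthday for t in merged}
        result = build_ml_tree(aln, "germline", n_orders=1, rng_seed=0,
                               birthdays=birthdays)
        assert result.root.children[0].name == "germline" or (
            result.root.children[1].name == "germline"
        )
        assert result.uca.name.startswith("anc")
        # newick round-trips through the parser
        again = from_newick(result.root.to_newick())
        assert again.leaf_names() == result.root.leaf_names()
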