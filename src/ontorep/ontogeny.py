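"""Longitudinal lineage ontogeny.

Merges lineage members collected at multiple time points (assigning each
distinct sequence a "birthday": the first time point at which it was
observed), builds a germline-rooted maximum-likelihood tree with inferred
ancestral sequences, selects developmental intermediates along the path
from the unmutated common ancestor (UCA) to an antibody of interest,
collapses minor branches for display, and emits region/codon-position
partitions for evolutionary-rate analysis.
"""

from __future__ import annotations

import itertools
import re
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq

from . import io
from .align import identity_pct
from .mltree import encode_alignment, search_ml_tree
from .phylo import Node, mrca

REGION_LABELS = ("FWR1", "CDR1", "FWR2", "CDR2", "FWR3", "CDR3", "FWR4")


@dataclass
class TimedSequence:
    seq_id: str
    sequence: str
    birthday: str
    observed_at: set[str] = field(default_factory=set)
    copies: int = 1


def merge_timepoints(
    files: list, labels: list[str]
) -> list[TimedSequence]:
    """Collapse identical sequences observed at multiple time points.

    *files* are per-time-point FASTA paths (or in-memory lists of
    ``(id, seq)``); *labels* give the temporal order.  Sequences equal
    after uppercasing and degapping are merged; the birthday is the
    earliest label, ids become ``"<birthday>-<original id>"``, and
    ``copies`` counts every collapsed record.
    """
    if len(files) != len(labels):
        raise ValueError("need exactly one label per file")
    if len(set(labels)) != len(labels):
        raise ValueError("labels must be unique")
    order = {lab: i for i, lab in enumerate(labels)}
    merged: dict[str, TimedSequence] = {}
    for src, label in zip(files, labels):
        records = list(io.read_seqs(src)) if isinstance(src, str) else list(src)
        seen_ids = set()
        for rid, raw in records:
            if rid in seen_ids:
                raise ValueError(f"duplicate sequence id {rid!r} in {label}")
            seen_ids.add(rid)
            seq = raw.upper().replace("-", "").replace(".", "")
            if seq in merged:
                ts = merged[seq]
                ts.observed_at.add(label)
                ts.copies += 1
                ts.birthday = min(ts.birthday, label, key=order.__getitem__)
            else:
                merged[seq] = TimedSequence(
                    seq_id=rid, sequence=seq, birthday=label, observed_at={label}
                )
    out = []
    for seq, ts in merged.items():
        ts.seq_id = f"{ts.birthday}-{ts.seq_id}"
        out.append(ts)
    out.sort(key=lambda t: (order[t.birthday], t.seq_id))
    return out


def birthday_of(seq_id: str, labels: list[str]) -> str | None:
    """Recover the birthday label from a merged sequence id."""
    for lab in labels:
        if seq_id.startswith(f"{lab}-"):
            return lab
    return None


# ---------------------------------------------------------------------------
# ML tree with ancestors


@dataclass
class OntogenyTree:
    """Rooted lineage tree: the germline outgroup hangs directly off the
    root, internal nodes carry inferred ancestral sequences."""

    root: Node
    germline_id: str
    alignment: dict[str, str]
    ancestor_seqs: dict[str, str]
    loglik: float
    birthdays: dict[str, str] = field(default_factory=dict)

    @property
    def uca(self) -> Node:
        """Unmutated common ancestor: the root child opposite the
        germline outgroup leaf."""
        for c in self.root.children:
            if c.name != self.germline_id:
                return c
        raise ValueError("degenerate tree: only the germline below the root")

    def sequence_of(self, node: Node) -> str:
        if node.is_leaf and node.name in self.alignment:
            return self.alignment[node.name]
        return self.ancestor_seqs[node.name]


def build_ml_tree(
    aln: dict[str, str],
    germline_id: str,
    n_orders: int = 3,
    rng_seed: int = 0,
    kappa: float = 2.0,
    birthdays: dict[str, str] | None = None,
) -> OntogenyTree:
    """Maximum-likelihood lineage tree rooted on the germline outgroup.

    The search runs stepwise addition plus NNI hill climbing from
    *n_orders* random taxon orders and keeps the best likelihood; the
    tree is then rooted on the germline edge and marginal ancestral
    sequences are reconstructed at every internal node (per-site
    posterior argmax; ties broken by base order A<C<G<T).
    """
    if germline_id not in aln:
        raise ValueError(f"germline id {germline_id!r} missing from alignment")
    tree, ll, model, calc = search_ml_tree(
        aln, n_orders=n_orders, rng_seed=rng_seed, kappa=kappa
    )
    from .phylo import reroot_on_leaf

    rooted = reroot_on_leaf(tree, germline_id)
    counter = itertools.count(1)
    for node in rooted.preorder():
        if not node.is_leaf and node.name is None:
            node.name = f"anc{next(counter):03d}"
    _, _, col_to_pat = encode_alignment(aln)
    posteriors = calc.marginal_posteriors(rooted)
    ancestor_seqs = {}
    for node in rooted.preorder():
        if node.is_leaf:
            continue
        post = posteriors[id(node)]
        states = post.argmax(axis=1)  # first max wins: A<C<G<T tie-break
        ancestor_seqs[node.name] = "".join("ACGT"[states[p]] for p in col_to_pat)
    return OntogenyTree(
        root=rooted,
        germline_id=germline_id,
        alignment=dict(aln),
        ancestor_seqs=ancestor_seqs,
        loglik=ll,
        birthdays=dict(birthdays or {}),
    )


# ---------------------------------------------------------------------------
# intermediates


def _codon_translate(seq: str) -> list[str | None]:
    """Per-codon amino acids; codons containing gaps, N, or encoding a
    stop are None (excluded from comparisons)."""
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        if set(codon) - set("ACGT"):
            out.append(None)
            continue
        aa = str(Seq(codon).translate())
        out.append(None if aa == "*" else aa)
    return out


def aa_changes(a: str, b: str) -> int:
    """Amino-acid differences between two nucleotide sequences of equal
    length, over codons translatable in both."""
    ta, tb = _codon_translate(a), _codon_translate(b)
    return sum(
        1 for x, y in zip(ta, tb) if x is not None and y is not None and x != y
    )


def path_to_leaf(tree: OntogenyTree, target: str) -> list[Node]:
    """Nodes from the UCA down to (and including) the target leaf."""
    leaf = tree.root.find(target)
    if not leaf.is_leaf:
        raise ValueError(f"{target!r} is not a leaf")
    chain = []
    n = leaf
    while n is not None and n is not tree.root:
        chain.append(n)
        n = n.parent
    chain.reverse()  # UCA ... target
    if not chain or chain[0] is not tree.uca:
        raise ValueError(f"{target!r} is not below the UCA")
    return chain


def pick_intermediates(
    tree: OntogenyTree,
    target: str,
    n: int | None = None,
    spacing_aa: int | None = None,
) -> list[tuple[str, int]]:
    """Developmental intermediates along the UCA -> target path.

    Returns ``(node name, cumulative aa changes from the UCA)`` pairs,
    always starting with the UCA.  With *n*, the nodes whose cumulative
    amino-acid change is nearest to the even quantiles i*total/(n+1) are
    chosen (ties to the earlier node); with *spacing_aa*, nodes are
    emitted greedily whenever the change since the last emitted node
    reaches the spacing.
    """
    if (n is None) == (spacing_aa is None):
        raise ValueError("specify exactly one of n / spacing_aa")
    path = path_to_leaf(tree, target)
    seqs = [tree.sequence_of(node) for node in path]
    cum = [0]
    for a, b in zip(seqs, seqs[1:]):
        cum.append(cum[-1] + aa_changes(a, b))
    uca_entry = (path[0].name, 0)
    total = cum[-1]
    if total == 0:
        return [uca_entry]
    picked: list[int] = []
    if n is not None:
        for i in range(1, n + 1):
            goal = i * total / (n + 1)
            best = min(
                range(len(path)), key=lambda k: (abs(cum[k] - goal), cum[k], k)
            )
            picked.append(best)
    else:
        last = 0
        for k in range(1, len(path)):
            if cum[k] - cum[last] >= spacing_aa:
                picked.append(k)
                last = k
    out = [uca_entry]
    for k in sorted(set(picked)):
        if k == 0:
            continue
        out.append((path[k].name, cum[k]))
    return out


def mrca_node(tree: OntogenyTree, leaf_ids: set[str]) -> Node:
    """Most recent common ancestor of several antibodies of interest."""
    return mrca(tree.root, set(leaf_ids))


# ---------------------------------------------------------------------------
# collapsing minor branches


def collapse_minor_branches(
    tree: OntogenyTree,
    cdr3_map: dict[str, str],
    identity: float = 0.85,
    min_size: int = 5,
    keep: set[str] | None = None,
) -> tuple[Node, pd.DataFrame]:
    """Phylogenetically aware CDR3 clustering for display.

    A clade is collapsible iff it contains no keep-listed or non-NGS
    leaf and every member's CDR3 is within the identity threshold of the
    clade's plurality CDR3.  Maximal collapsible clades of at least
    *min_size* leaves become a single "major branch" pseudo-leaf; smaller
    ones are pruned.  Returns the collapsed tree and a summary table with
    each major branch's size, birthday span, and representative CDR3.
    """
    keep = set(keep or set())
    keep.add(tree.germline_id)
    root = tree.root.copy()
    rows = []
    n_pruned = 0

    def plurality(cdr3s: list[str]) -> str:
        counts = Counter(cdr3s)
        top = max(counts.values())
        return min(c for c, k in counts.items() if k == top)

    def collapsible(node: Node) -> bool:
        leaves = node.leaves()
        for l in leaves:
            if l.name in keep or l.name not in cdr3_map:
                return False
        cdr3s = [cdr3_map[l.name] for l in leaves]
        rep = plurality(cdr3s)
        return all(
            identity_pct(c, rep) >= 100.0 * identity for c in set(cdr3s)
        )

    def visit(node: Node) -> Node | None:
        """Return replacement node (pseudo-leaf), the node itself, or
        None when pruned."""
        nonlocal n_pruned
        if collapsible(node):
            leaves = node.leaves()
            cdr3s = [cdr3_map[l.name] for l in leaves]
            rep = plurality(cdr3s)
            if len(leaves) >= min_size:
                rep_leaf = min(l.name for l in leaves if cdr3_map[l.name] == rep)
                label = f"{rep_leaf}|{len(leaves)}"
                pseudo = Node(label, node.length)
                rows.append(
                    {
                        "branch_id": label,
                        "size": len(leaves),
                        "birthday_span": "-".join(
                            _birthday_span(tree, leaves)
                        ),
                        "representative_cdr3": rep,
                    }
                )
                return pseudo
            n_pruned += len(leaves)
            return None
        if node.is_leaf:
            return node
        new_children = []
        for c in node.children:
            r = visit(c)
            if r is not None:
                r.parent = node
                new_children.append(r)
        node.children = new_children
        if not new_children:
            n_pruned += 0
            return None
        if len(new_children) == 1 and node.parent is not None:
            child = new_children[0]
            child.length += node.length
            return child
        return node

    collapsed = visit(root)
    if collapsed is None:
        collapsed = Node()
    table = pd.DataFrame(
        rows, columns=["branch_id", "size", "birthday_span", "representative_cdr3"]
    )
    table.attrs["n_pruned"] = n_pruned
    return collapsed, table


def _birthday_span(tree: OntogenyTree, leaves: list[Node]) -> tuple[str, str]:
    labels = [tree.birthdays[l.name] for l in leaves if l.name in tree.birthdays]
    if not labels:
        return ("", "")
    order = {lab: i for i, lab in enumerate(dict.fromkeys(tree.birthdays.values()))}
    ordered = sorted(set(labels), key=lambda x: order.get(x, 0))
    return (ordered[0], ordered[-1])


# ---------------------------------------------------------------------------
# partitions for rate analysis


def partition_alignment(
    region_labels: list[str],
) -> dict[str, list[int]]:
    """Column partitions for evolutionary-rate analysis.

    *region_labels* assigns every alignment column an antibody region
    (FWR1..FWR4, CDR1..CDR3; ``junction`` counts as CDR3, ``V``/``D``/
    ``J`` count as framework context only if prefixed FWR/CDR).  Returns
    five partitions: the full V(D)J region, the CDR union, the FWR
    union, codon positions 1+2, and codon position 3.
    """
    L = len(region_labels)
    if L % 3 != 0:
        raise ValueError("alignment length must be divisible by 3")
    bad = [
        i
        for i, lab in enumerate(region_labels)
        if not (str(lab).startswith("FWR") or str(lab).startswith("CDR") or lab == "junction")
    ]
    if bad:
        raise ValueError(f"columns without a valid region label: {bad[:10]}")
    cdr = [
        i
        for i, lab in enumerate(region_labels)
        if str(lab).startswith("CDR") or lab == "junction"
    ]
    fwr = [i for i, lab in enumerate(region_labels) if str(lab).startswith("FWR")]
    return {
        "VDJ": list(range(L)),
        "CDR": cdr,
        "FWR": fwr,
        "pos12": [i for i in range(L) if i % 3 != 2],
        "pos3": [i for i in range(L) if i % 3 == 2],
    }


def _ranges(cols: list[int]) -> list[tuple[int, int]]:
    out = []
    for _, grp in itertools.groupby(enumerate(sorted(cols)), lambda t: t[1] - t[0]):
        block = [c for _, c in grp]
        out.append((block[0], block[-1]))
    return out


def write_nexus_charsets(partitions: dict[str, list[int]]) -> str:
    """NEXUS sets block with 1-based inclusive charset ranges."""
    lines = ["#NEXUS", "begin sets;"]
    for name in partitions:
        parts = []
        for a, b in _ranges(partitions[name]):
            parts.append(f"{a + 1}" if a == b else f"{a + 1}-{b + 1}")
        lines.append(f"    charset {name} = {' '.join(parts)};")
    lines.append("end;")
    return "\n".join(lines) + "\n"


_CHARSET = re.compile(r"charset\s+(\S+)\s*=\s*([^;]+);")


def parse_nexus_charsets(text: str) -> dict[str, list[int]]:
    """Inverse of :func:`write_nexus_charsets` (0-based columns out)."""
    out: dict[str, list[int]] = {}
    for name, body in _CHARSET.findall(text):
        cols: list[int] = []
        for tok in body.split():
            if "-" in tok:
                a, b = tok.split("-")
                cols.extend(range(int(a) - 1, int(b)))
            else:
                cols.append(int(tok) - 1)
        out[name] = sorted(cols)
    return out
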