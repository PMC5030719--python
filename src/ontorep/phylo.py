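"""Tree structure, Newick I/O, rerooting, and neighbor joining.

The tree container is a minimal mutable node class; Newick parsing is
delegated to dendropy and converted.  ``neighbor_joining`` is the classic
Saitou-Nei agglomeration with deterministic tie-breaking (lexicographic
taxon-pair order on Q-matrix ties) and non-negative branch lengths
(negatives clamped to zero, the deficit transferred to the sister
branch).
"""

from __future__ import annotations

import itertools
from typing import Iterator

import numpy as np


class Node:
    """A rooted (or conventionally-rooted unrooted) tree node."""

    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name: str | None = None, length: float = 0.0):
        self.name = name
        self.length = length
        self.children: list[Node] = []
        self.parent: Node | None = None

    # -- structure ---------------------------------------------------------
    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Node"]:
        for c in self.children:
            yield from c.postorder()
        yield self

    def preorder(self) -> Iterator["Node"]:
        yield self
        for c in self.children:
            yield from c.preorder()

    def leaves(self) -> list["Node"]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> set[str]:
        return {n.name for n in self.leaves()}

    def find(self, name: str) -> "Node":
        for n in self.postorder():
            if n.name == name:
                return n
        raise KeyError(name)

    def copy(self) -> "Node":
        clone = Node(self.name, self.length)
        for c in self.children:
            clone.add(c.copy())
        return clone

    # -- newick ------------------------------------------------------------
    def to_newick(self, lengths: bool = True) -> str:
        return self._nwk(lengths) + ";"

    def _nwk(self, lengths: bool) -> str:
        label = self.name or ""
        bl = f":{self.length:.9g}" if lengths and self.parent is not None else ""
        if self.is_leaf:
            return f"{label}{bl}"
        inner = ",".join(c._nwk(lengths) for c in self.children)
        return f"({inner}){label}{bl}"

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Node {self.name or '*'} {len(self.leaves())} leaves>"


def from_newick(text: str) -> Node:
    """Parse a Newick string (dendropy-backed) into a Node tree."""
    import dendropy

    dt = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)

    def convert(dn) -> Node:
        n = Node(
            name=(dn.taxon.label if dn.taxon else dn.label),
            length=dn.edge.length or 0.0,
        )
        for ch in dn.child_nodes():
            n.add(convert(ch))
        return n

    return convert(dt.seed_node)


# ---------------------------------------------------------------------------
# topology comparison


def splits(tree: Node) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an (un)rooted tree, each written as the
    smaller-by-sorted-name side; used for topology equality."""
    all_names = frozenset(tree.leaf_names())
    out: set[frozenset[str]] = set()
    for n in tree.postorder():
        if n.parent is None or n.is_leaf:
            continue
        side = frozenset(n.leaf_names())
        other = all_names - side
        if len(side) < 2 or len(other) < 2:
            continue
        out.add(min(side, other, key=lambda s: sorted(s)))
    return out


def same_topology(a: Node, b: Node) -> bool:
    if a.leaf_names() != b.leaf_names():
        return False
    return splits(a) == splits(b)


# ---------------------------------------------------------------------------
# rerooting


def reroot_on_leaf(tree: Node, leaf_name: str) -> Node:
    """Return a new tree rooted on the edge leading to *leaf_name*: the
    root has two children, the named leaf and the rest of the tree.  The
    leaf's branch length is split evenly across the root."""
    tree = tree.copy()
    leaf = tree.find(leaf_name)
    if leaf.parent is None:
        raise ValueError("cannot root on the current root")
    bl = leaf.length
    pivot = leaf.parent
    # detach the leaf; reorient everything else to hang below its old parent
    pivot.children.remove(leaf)
    leaf.parent = None
    rest = _reorient(pivot)
    root = Node(name=None)
    leaf.length = bl / 2.0
    rest.length = bl / 2.0
    root.add(leaf)
    root.add(rest)
    rest = _suppress_unifurcations(rest)
    return root


def _reorient(node: Node) -> Node:
    """Make *node* the root by reversing parent links above it."""
    path = []
    n = node
    while n is not None:
        path.append(n)
        n = n.parent
    orig_len = [n.length for n in path]
    for (child, parent), child_len in zip(zip(path, path[1:]), orig_len):
        parent.children.remove(child)
        child.add(parent)
        parent.length = child_len
    node.parent = None
    node.length = 0.0
    return node


def _suppress_unifurcations(node: Node) -> Node:
    for n in list(node.postorder()):
        if not n.is_leaf and len(n.children) == 1 and n.parent is not None:
            child = n.children[0]
            child.length += n.length
            p = n.parent
            i = p.children.index(n)
            p.children[i] = child
            child.parent = p
    return node


def mrca(root: Node, leaf_names: set[str]) -> Node:
    """Most recent common ancestor of the named leaves under *root*."""
    want = set(leaf_names)
    missing = want - root.leaf_names()
    if missing:
        raise KeyError(f"leaves not in tree: {sorted(missing)}")
    node = root
    while True:
        for c in node.children:
            names = c.leaf_names()
            if want <= names:
                node = c
                break
        else:
            return node


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(names: list[str], D: np.ndarray) -> Node:
    """Saitou-Nei neighbor joining.

    *D* is a symmetric matrix with zero diagonal over *names* (>= 3
    taxa).  Returns the unrooted tree as a trifurcating root node.
    Q-matrix ties are broken by lexicographic taxon-pair order; negative
    branch lengths are clamped to zero with the deficit moved to the
    sister branch.
    """
    D = np.asarray(D, dtype=float)
    n = len(names)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match names")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0.0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")

    nodes = [Node(name) for name in names]
    labels = list(names)  # current label used for tie-breaking
    D = D.copy()
    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(np.isclose(Q, qmin, rtol=0.0, atol=1e-12))
        i, j = min(
            (tuple(sorted((int(a), int(b)))) for a, b in ties),
            key=lambda ij: tuple(sorted((labels[ij[0]], labels[ij[1]]))),
        )
        vi = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = D[i, j] - vi
        vi, vj = _clamp_pair(vi, vj)
        new = Node()
        a, b = nodes[i], nodes[j]
        a.length, b.length = vi, vj
        new.add(a)
        new.add(b)
        dnew = 0.5 * (D[:, i] + D[:, j] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = dnew[keep]
        D2[:-1, -1] = dnew[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[k] for k in keep] + [new]
        labels = [labels[k] for k in keep] + [min(labels[i], labels[j])]

    root = Node()
    (a, b, c) = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    va = 0.5 * (dab + dac - dbc)
    vb = 0.5 * (dab + dbc - dac)
    vc = 0.5 * (dac + dbc - dab)
    va, vb, vc = _clamp_triple(va, vb, vc)
    for node, v in zip((a, b, c), (va, vb, vc)):
        node.length = v
        root.add(node)
    return root


def _clamp_pair(vi: float, vj: float) -> tuple[float, float]:
    if vi < 0:
        vj += vi
        vi = 0.0
    if vj < 0:
        vi += vj
        vj = 0.0
    return max(vi, 0.0), max(vj, 0.0)


def _clamp_triple(va: float, vb: float, vc: float) -> tuple[float, float, float]:
    v = [va, vb, vc]
    for i in range(3):
        if v[i] < 0:
            j = int(np.argmax(v))
            v[j] += v[i]
            v[i] = 0.0
    return tuple(max(x, 0.0) for x in v)


def additive_tree_distances(tree: Node) -> tuple[list[str], np.ndarray]:
    """Patristic (path-length) distance matrix between the leaves of a
    tree; the NJ oracle input for additive-tree recovery tests."""
    leaves = tree.leaves()
    names = [l.name for l in leaves]
    # distance from each node to root
    depth: dict[int, float] = {id(tree): 0.0}
    for n in tree.preorder():
        if n.parent is not None:
            depth[id(n)] = depth[id(n.parent)] + n.length
    # ancestor chains
    def chain(n: Node) -> list[Node]:
        out = []
        while n is not None:
            out.append(n)
            n = n.parent
        return out

    chains = {l.name: chain(l) for l in leaves}
    m = len(names)
    D = np.zeros((m, m))
    for i, j in itertools.combinations(range(m), 2):
        ci = chains[names[i]]
        cj = set(id(x) for x in chains[names[j]])
        lca = next(x for x in ci if id(x) in cj)
        d = (
            depth[id(ci[0])]
            + depth[id(chains[names[j]][0])]
            - 2.0 * depth[id(lca)]
        )
        D[i, j] = D[j, i] = d
    return names, D
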