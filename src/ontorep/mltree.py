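"""Native maximum-likelihood tree machinery.

A small, exact ML engine for the lineage-sized trees this pipeline works
with: HKY substitution model with empirical base frequencies, Felsenstein
pruning over compressed site patterns, per-branch Brent optimization,
stepwise-addition starting trees, NNI hill climbing, exhaustive topology
enumeration for small taxon sets, and marginal ancestral state
reconstruction.

Gaps and ambiguous bases are treated as missing data.  All searches are
deterministic given the taxon addition order.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar

from .phylo import Node

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
MISSING = 4

MIN_BL = 1e-9
MAX_BL = 10.0


class HKYModel:
    """HKY85: transition/transversion rate ratio *kappa*, stationary
    frequencies *freqs*; rate matrix scaled to one expected substitution
    per site per unit branch length."""

    def __init__(self, freqs: np.ndarray, kappa: float = 2.0):
        freqs = np.asarray(freqs, dtype=float)
        freqs = freqs / freqs.sum()
        self.freqs = freqs
        self.kappa = float(kappa)
        Q = np.empty((4, 4))
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                rate = freqs[j]
                if {i, j} in ({0, 2}, {1, 3}):  # A<->G, C<->T transitions
                    rate *= kappa
                Q[i, j] = rate
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        scale = -np.dot(freqs, np.diag(Q))
        Q /= scale
        # symmetrize for a stable eigendecomposition (model is reversible)
        sp = np.sqrt(freqs)
        B = (sp[:, None] * Q) / sp[None, :]
        w, V = np.linalg.eigh((B + B.T) / 2.0)
        self._w = w
        self._left = V / sp[:, None]          # rows scaled
        self._right = V.T * sp[None, :]

    def P(self, t: float) -> np.ndarray:
        """Transition probability matrix exp(Qt); rows = from-state."""
        return (self._left * np.exp(self._w * max(t, 0.0))) @ self._right


def encode_alignment(
    seqs: dict[str, str]
) -> tuple[dict[str, np.ndarray], np.ndarray, np.ndarray]:
    """Compress aligned sequences into site patterns.

    Returns (per-taxon pattern codes, pattern weights, column->pattern
    index) with codes 0-3 for ACGT and 4 for missing (gap/N/other).
    """
    names = list(seqs)
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError("sequences are not aligned (unequal lengths)")
    L = lengths.pop()
    mat = np.full((len(names), L), MISSING, dtype=np.int8)
    for i, nm in enumerate(names):
        for j, ch in enumerate(seqs[nm].upper()):
            mat[i, j] = _CODE.get(ch, MISSING)
    cols, col_to_pat, counts = np.unique(
        mat.T, axis=0, return_inverse=True, return_counts=True
    )
    codes = {nm: cols[:, i].copy() for i, nm in enumerate(names)}
    return codes, counts.astype(float), col_to_pat


def empirical_freqs(seqs: dict[str, str]) -> np.ndarray:
    counts = np.zeros(4)
    for s in seqs.values():
        for ch in s.upper():
            i = _CODE.get(ch)
            if i is not None:
                counts[i] += 1
    return (counts + 1.0) / (counts + 1.0).sum()


class TreeLikelihood:
    """Log-likelihood of a tree under an HKY model with compressed
    patterns; also provides marginal ancestral posteriors."""

    def __init__(
        self, codes: dict[str, np.ndarray], weights: np.ndarray, model: HKYModel
    ):
        self.codes = codes
        self.weights = weights
        self.model = model
        npat = len(weights)
        self._leaf_partials: dict[str, np.ndarray] = {}
        eye = np.eye(4)
        for nm, c in codes.items():
            F = np.ones((npat, 4))
            obs = c < 4
            F[obs] = eye[c[obs]]
            self._leaf_partials[nm] = F

    def _partial(self, node: Node) -> tuple[np.ndarray, np.ndarray]:
        """(partial likelihoods (npat,4), per-pattern log scaling)."""
        if node.is_leaf:
            return self._leaf_partials[node.name], np.zeros(len(self.weights))
        F = np.ones((len(self.weights), 4))
        logscale = np.zeros(len(self.weights))
        for c in node.children:
            Fc, lsc = self._partial(c)
            P = self.model.P(c.length)
            F = F * (Fc @ P.T)
            logscale += lsc
        mx = F.max(axis=1)
        mx[mx == 0.0] = 1.0
        F = F / mx[:, None]
        logscale += np.log(mx)
        return F, logscale

    def loglik(self, root: Node) -> float:
        F, logscale = self._partial(root)
        site = F @ self.model.freqs
        return float(np.dot(self.weights, np.log(site) + logscale))

    # -- branch length optimization ------------------------------------
    def optimize_branches(
        self, root: Node, sweeps: int = 2, only: set[int] | None = None
    ) -> float:
        """Coordinate-wise Brent optimization of branch lengths;
        *only* restricts the sweep to nodes with those ids (used to score
        candidate rearrangements cheaply)."""
        best = self.loglik(root)
        for _ in range(sweeps):
            sweep_start = best
            for node in root.postorder():
                if node.parent is None:
                    continue
                if only is not None and id(node) not in only:
                    continue
                t0 = node.length

                def nll(t: float, n=node) -> float:
                    n.length = t
                    return -self.loglik(root)

                res = minimize_scalar(
                    nll,
                    bounds=(MIN_BL, MAX_BL),
                    method="bounded",
                    options={"xatol": 1e-6, "maxiter": 40},
                )
                if -res.fun > best + 1e-10:
                    node.length = float(res.x)
                    best = -res.fun
                else:
                    node.length = t0
            if best <= sweep_start + 1e-8:
                break
        return best

    # -- ancestral reconstruction --------------------------------------
    def marginal_posteriors(self, root: Node) -> dict[int, np.ndarray]:
        """Per-node marginal posterior state probabilities (npat, 4),
        keyed by id(node), for a rooted tree."""
        down: dict[int, np.ndarray] = {}
        msgs: dict[int, np.ndarray] = {}  # child message to its parent

        def down_pass(node: Node) -> np.ndarray:
            if node.is_leaf:
                F = self._leaf_partials[node.name]
            else:
                F = np.ones((len(self.weights), 4))
                for c in node.children:
                    Fc = down_pass(c)
                    m = Fc @ self.model.P(c.length).T
                    msgs[id(c)] = m
                    F = F * m
                mx = F.max(axis=1)
                mx[mx == 0.0] = 1.0
                F = F / mx[:, None]
            down[id(node)] = F
            return F

        down_pass(root)
        out: dict[int, np.ndarray] = {}
        up: dict[int, np.ndarray] = {id(root): np.tile(self.model.freqs, (len(self.weights), 1))}

        def norm_rows(M: np.ndarray) -> np.ndarray:
            s = M.sum(axis=1)
            s[s == 0.0] = 1.0
            return M / s[:, None]

        for node in root.preorder():
            post = norm_rows(up[id(node)] * down[id(node)])
            out[id(node)] = post
            for c in node.children:
                S = up[id(node)].copy()
                for w in node.children:
                    if w is not c:
                        S = S * msgs[id(w)]
                up[id(c)] = norm_rows(S @ self.model.P(c.length))
        return out


# ---------------------------------------------------------------------------
# topology search


def _star(names: list[str], bl: float = 0.1) -> Node:
    root = Node()
    for nm in names:
        leaf = Node(nm, bl)
        root.add(leaf)
    return root


def _edges(root: Node) -> list[Node]:
    """Every node carrying an edge to its parent, in stable postorder."""
    return [n for n in root.postorder() if n.parent is not None]


def _insert_leaf(
    root: Node, edge_index: int, name: str, bl: float = 0.1
) -> tuple[Node, set[int]]:
    """Copy the tree and attach *name* in the middle of the indexed edge;
    also return the ids of the three branches the insertion created."""
    tree = root.copy()
    target = _edges(tree)[edge_index]
    parent = target.parent
    i = parent.children.index(target)
    mid = Node(length=target.length / 2.0)
    target.length /= 2.0
    parent.children[i] = mid
    mid.parent = parent
    mid.add(target)
    leaf = mid.add(Node(name, bl))
    return tree, {id(mid), id(target), id(leaf)}


def stepwise_addition(
    order: list[str], calc: TreeLikelihood, quick_sweeps: int = 1
) -> Node:
    """Stepwise-addition starting tree: taxa added in the given order at
    the edge that maximizes the (branch-optimized) likelihood."""
    tree = _star(order[:3])
    calc.optimize_branches(tree, sweeps=2)
    for nm in order[3:]:
        best = None
        best_ll = -np.inf
        for e in range(len(_edges(tree))):
            cand, new_ids = _insert_leaf(tree, e, nm)
            ll = calc.optimize_branches(cand, sweeps=quick_sweeps, only=new_ids)
            if ll > best_ll + 1e-10:
                best_ll = ll
                best = cand
        tree = best
        calc.optimize_branches(tree, sweeps=1)
    return tree


def _nni_candidates(root: Node) -> list[tuple[int, int]]:
    """(node index in postorder, alternative 0/1) for every internal edge."""
    out = []
    nodes = list(root.postorder())
    for idx, v in enumerate(nodes):
        if v.is_leaf or v.parent is None or len(v.children) < 2:
            continue
        u = v.parent
        n_sib = len(u.children) - 1
        if u.parent is None and n_sib < 2:
            continue
        out.append((idx, 0))
        out.append((idx, 1))
    return out


def _apply_nni(root: Node, idx: int, alt: int) -> tuple[Node, set[int]]:
    tree = root.copy()
    nodes = list(tree.postorder())
    v = nodes[idx]
    u = v.parent
    sibs = [c for c in u.children if c is not v]
    if u.parent is None and len(sibs) >= 2:
        a, b = v.children[0], sibs[alt]
    else:
        a, b = v.children[alt], sibs[0]
    ia, ib = v.children.index(a), u.children.index(b)
    v.children[ia], u.children[ib] = b, a
    a.parent, b.parent = u, v
    touched = {id(v), id(a), id(b)} | {id(c) for c in v.children}
    touched |= {id(c) for c in u.children}
    return tree, touched


def nni_search(tree: Node, calc: TreeLikelihood, max_rounds: int = 30) -> tuple[Node, float]:
    """Greedy nearest-neighbor-interchange hill climbing; the likelihood
    is non-decreasing across accepted moves."""
    current = tree
    current_ll = calc.optimize_branches(current, sweeps=2)
    for _ in range(max_rounds):
        best = None
        best_ll = current_ll
        for idx, alt in _nni_candidates(current):
            cand, touched = _apply_nni(current, idx, alt)
            ll = calc.optimize_branches(cand, sweeps=1, only=touched)
            if ll > best_ll + 1e-7:
                best_ll = ll
                best = cand
        if best is None:
            break
        current = best
        current_ll = calc.optimize_branches(current, sweeps=2)
    return current, current_ll


def search_ml_tree(
    seqs: dict[str, str],
    n_orders: int = 3,
    rng_seed: int = 0,
    kappa: float = 2.0,
) -> tuple[Node, float, HKYModel, "TreeLikelihood"]:
    """Best ML tree over *n_orders* random taxon addition orders
    (stepwise addition + NNI each), reporting the max-likelihood result."""
    names = sorted(seqs)
    if len(names) < 3:
        raise ValueError("need at least 3 sequences")
    codes, weights, _ = encode_alignment(seqs)
    model = HKYModel(empirical_freqs(seqs), kappa=kappa)
    calc = TreeLikelihood(codes, weights, model)
    rng = np.random.default_rng(rng_seed)
    best_tree, best_ll = None, -np.inf
    for _ in range(max(1, n_orders)):
        order = [names[i] for i in rng.permutation(len(names))]
        start = stepwise_addition(order, calc)
        tree, ll = nni_search(start, calc)
        if ll > best_ll + 1e-9:
            best_tree, best_ll = tree, ll
    return best_tree, best_ll, model, calc


def enumerate_topologies(names: list[str]) -> list[Node]:
    """All distinct unrooted topologies over *names* (3, 15, 105, ... for
    3, 5, 6, ... taxa), by recursive edge insertion in a fixed order."""
    names = list(names)
    trees = [_star(names[:3])]
    for nm in names[3:]:
        trees = [
            _insert_leaf(t, e, nm)[0]
            for t in trees
            for e in range(len(_edges(t)))
        ]
    return trees


def exhaustive_ml_tree(
    seqs: dict[str, str], kappa: float = 2.0
) -> tuple[Node, float]:
    """Brute-force ML search over every unrooted topology; tractable for
    <= 7 taxa.  Ties keep the first topology in enumeration order."""
    names = sorted(seqs)
    codes, weights, _ = encode_alignment(seqs)
    model = HKYModel(empirical_freqs(seqs), kappa=kappa)
    calc = TreeLikelihood(codes, weights, model)
    best, best_ll = None, -np.inf
    for t in enumerate_topologies(names):
        ll = calc.optimize_branches(t, sweeps=3)
        if ll > best_ll + 1e-9:
            best, best_ll = t, ll
    return best, best_ll
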