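"""Maximum-likelihood tree inference: pruning likelihood, branch-length
optimization, exhaustive quartet ML, and NJ+NNI search.

The engine computes the Felsenstein pruning likelihood over site patterns
(columns compressed to unique patterns), with discrete-gamma categories
averaged and gap states marginalized.  Branch lengths are optimized one at
a time by bounded scalar minimization in log-length space, cycling until
the log-likelihood improvement falls below tolerance; the lower bound
1e-10 lets estimated internal branches fall far below the 1e-5 polytomy
threshold used by the short-branch remedy.

Quartet inference scores all three resolved topologies and returns the
argmax; ties within 1e-9 log-units are resolved by the tie rule — a seeded
uniform choice by default (mimicking programs forced to bifurcate) or an
explicit STAR result.  For larger trees the search starts from neighbor
joining on JC distances and hill-climbs over nearest-neighbor interchanges.
"""

from __future__ import annotations

from dataclasses import dataclass
import math
import warnings

import numpy as np
from scipy.optimize import minimize_scalar

from sba.seqsim import Alignment, GAP
from sba.trees import Node, Tree, QuartetTopology

__all__ = [
    "MLFit",
    "MIN_BRANCH_LENGTH",
    "MAX_BRANCH_LENGTH",
    "TIE_TOL",
    "loglik",
    "optimize_branch_lengths",
    "ml_quartet",
    "ml_search",
    "ml_tree",
    "jc_distance",
    "jc_distance_matrix",
]

MIN_BRANCH_LENGTH = 1e-10
MAX_BRANCH_LENGTH = 10.0
TIE_TOL = 1e-9

_LOG_MIN = math.log(MIN_BRANCH_LENGTH)
_LOG_MAX = math.log(MAX_BRANCH_LENGTH)


@dataclass
class MLFit:
    """Result of an ML fit: the fitted tree (branch lengths optimized),
    its maximized log-likelihood, and for quartets the chosen topology,
    the three per-topology log-likelihoods, and the internal branch
    length."""

    tree: Tree
    loglik: float
    topology: QuartetTopology | None = None
    candidate_logliks: dict | None = None
    internal_length: float | None = None
    converged: bool = True


# ---------------------------------------------------------------------------
# Pruning engine


class _Engine:
    """Pruning likelihood over compressed site patterns.

    Caches are keyed by node object so the tree may be rearranged in place
    (NNI) between passes; ``full_pass`` recomputes the traversal order
    from the current structure.
    """

    def __init__(self, tree: Tree, alignment: Alignment, model):
        self.tree = tree
        self.model = model
        self.rates = np.asarray(model.category_rates, dtype=float)
        self.ncat = len(self.rates)
        self.pi = np.asarray(model.pi, dtype=float)

        labels = tree.leaf_labels()
        if set(labels) != set(alignment.labels):
            raise ValueError("alignment taxa must match tree leaves")
        rows = np.stack([alignment.row(lab) for lab in labels])
        patterns, weights = np.unique(rows, axis=1, return_counts=True)
        self.patterns = patterns
        self.weights = weights.astype(float)
        self.npat = patterns.shape[1]

        # leaf conditional likelihoods: identity rows, gaps marginalized
        eye = np.vstack([np.eye(4), np.ones(4)])  # state 4 = gap
        self.leaf_down = {}
        for r, lab in enumerate(labels):
            for leaf in tree.leaves():
                if leaf.label == lab:
                    self.leaf_down[id(leaf)] = np.broadcast_to(
                        eye[patterns[r]][:, None, :], (self.npat, self.ncat, 4)
                    )
        self.down: dict[int, np.ndarray] = {}
        self.up: dict[int, np.ndarray] = {}
        self.msg: dict[int, np.ndarray] = {}
        self.mats: dict[int, np.ndarray] = {}

    def _branch_mats(self, t: float) -> np.ndarray:
        return self.model.transition_matrices(t, self.rates)

    def full_pass(self) -> float:
        """Recompute downward partials and per-edge messages in postorder;
        return the current log-likelihood."""
        for node in self.tree.postorder():
            if node.is_leaf:
                down = self.leaf_down[id(node)]
            else:
                down = np.ones((self.npat, self.ncat, 4))
                for child in node.children:
                    down = down * self.msg[id(child)]
            self.down[id(node)] = down
            if node.parent is not None:
                mats = self._branch_mats(node.length)
                self.mats[id(node)] = mats
                self.msg[id(node)] = np.einsum("cij,pcj->pci", mats, down)
        site = np.einsum("i,pci->pc", self.pi, self.down[id(self.tree.root)]).mean(axis=1)
        return float(self.weights @ np.log(np.maximum(site, 1e-300)))

    def up_pass(self) -> None:
        """Outside-subtree partials for every edge; needs a fresh
        full_pass."""
        g = {
            id(self.tree.root): np.broadcast_to(
                self.pi[None, None, :], (self.npat, self.ncat, 4)
            )
        }
        for node in self.tree.preorder():
            if node.parent is None:
                continue
            a = g[id(node.parent)]
            for sib in node.parent.children:
                if sib is not node:
                    a = a * self.msg[id(sib)]
            self.up[id(node)] = a
            if not node.is_leaf:
                g[id(node)] = np.einsum("cij,pci->pcj", self.mats[id(node)], a)

    def edge_loglik(self, node: Node, t: float) -> float:
        """Loglik as a function of one edge's length, from cached partials
        (valid until any other branch or the topology changes)."""
        mats = self._branch_mats(t)
        site = np.einsum(
            "pci,cij,pcj->pc", self.up[id(node)], mats, self.down[id(node)]
        ).mean(axis=1)
        return float(self.weights @ np.log(np.maximum(site, 1e-300)))

    def optimize_edge(self, node: Node, xatol: float = 1e-5) -> None:
        res = minimize_scalar(
            lambda u: -self.edge_loglik(node, math.exp(u)),
            bounds=(_LOG_MIN, _LOG_MAX),
            method="bounded",
            options={"xatol": xatol},
        )
        if -res.fun >= self.edge_loglik(node, node.length):
            node.length = math.exp(res.x)

    def optimize_all(
        self,
        tol: float = 1e-8,
        max_sweeps: int = 50,
        edges: list[Node] | None = None,
        xatol: float = 1e-5,
    ) -> tuple[float, bool]:
        """Coordinate-wise branch optimization cycled to convergence
        (per-sweep gain < ``tol``); returns (loglik, converged)."""
        current = self.full_pass()
        converged = False
        for _ in range(max_sweeps):
            targets = edges if edges is not None else [
                n for n in self.tree.postorder() if n.parent is not None
            ]
            for node in targets:
                self.full_pass()
                self.up_pass()
                self.optimize_edge(node, xatol=xatol)
            new = self.full_pass()
            if new - current < tol:
                converged = True
                current = max(new, current)
                break
            current = new
        return current, converged


# ---------------------------------------------------------------------------
# Public operations


def loglik(tree: Tree, alignment: Alignment, model) -> float:
    """Pruning log-likelihood of ``alignment`` on ``tree`` under ``model``
    (gamma categories averaged, gaps marginalized, patterns compressed)."""
    return _Engine(tree, alignment, model).full_pass()


def optimize_branch_lengths(
    topology: Tree,
    alignment: Alignment,
    model,
    tol: float = 1e-8,
    max_sweeps: int = 50,
) -> MLFit:
    """Optimize all branch lengths of a fixed topology.

    Bounded scalar optimization per branch in [1e-10, 10], cycled until
    the per-sweep log-likelihood gain is below ``tol`` (warns and returns
    best-so-far after ``max_sweeps`` sweeps).
    """
    tree = topology.copy()
    engine = _Engine(tree, alignment, model)
    value, converged = engine.optimize_all(tol=tol, max_sweeps=max_sweeps)
    if not converged:
        warnings.warn("branch-length optimization did not converge; returning best so far")
    return MLFit(tree=tree, loglik=value, converged=converged)


def _quartet_tree(labels, pair_second, tip_init=0.05, internal_init=0.01) -> Tree:
    """Rooted-trifurcation storage of the quartet grouping labels[0] with
    labels[pair_second]."""
    a = labels[0]
    partner = labels[pair_second]
    others = [x for x in labels[1:] if x != partner]
    root = Node()
    cherry = Node(length=internal_init)
    cherry.add_child(Node(a, tip_init))
    cherry.add_child(Node(partner, tip_init))
    root.add_child(cherry)
    for lab in others:
        root.add_child(Node(lab, tip_init))
    return Tree(root, rooted=False)


def _star_tree(labels, lengths) -> Tree:
    root = Node()
    for lab, t in zip(labels, lengths):
        root.add_child(Node(lab, t))
    return Tree(root, rooted=False)


def ml_quartet(
    alignment: Alignment,
    model,
    tie_rule: str = "random",
    rng: np.random.Generator | None = None,
    tol: float = 1e-8,
    max_sweeps: int = 50,
) -> MLFit:
    """Exhaustive ML over the three resolved quartet topologies.

    Topologies are enumerated relative to the alignment's taxon order
    (a, b, c, d): T1 = ab|cd, T2 = ac|bd, T3 = ad|bc.  Log-likelihood ties
    within 1e-9 are resolved per ``tie_rule``: ``'random'`` draws uniformly
    among the tied topologies (seeded via ``rng``), ``'star'`` returns an
    unresolved quartet.
    """
    if alignment.n_taxa != 4:
        raise ValueError("ml_quartet needs exactly 4 taxa")
    if tie_rule not in ("random", "star"):
        raise ValueError("tie_rule must be 'random' or 'star'")
    labels = list(alignment.labels)
    fits: dict[QuartetTopology, MLFit] = {}
    for topo, second in (
        (QuartetTopology.T1, 1),
        (QuartetTopology.T2, 2),
        (QuartetTopology.T3, 3),
    ):
        tree = _quartet_tree(labels, second)
        engine = _Engine(tree, alignment, model)
        value, converged = engine.optimize_all(tol=tol, max_sweeps=max_sweeps)
        cherry = next(c for c in tree.root.children if not c.is_leaf)
        fits[topo] = MLFit(
            tree=tree,
            loglik=value,
            topology=topo,
            internal_length=cherry.length,
            converged=converged,
        )
    scores = {t: f.loglik for t, f in fits.items()}
    best_value = max(scores.values())
    tied = [t for t, v in scores.items() if v >= best_value - TIE_TOL]
    if len(tied) == 1:
        choice = tied[0]
    elif tie_rule == "random":
        if rng is None:
            rng = np.random.default_rng()
        choice = tied[int(rng.integers(len(tied)))]
    else:
        ref = fits[tied[0]].tree
        tip_lengths = {n.label: n.length for n in ref.leaves()}
        star = _star_tree(labels, [tip_lengths[l] for l in labels])
        return MLFit(
            tree=star,
            loglik=best_value,
            topology=QuartetTopology.STAR,
            candidate_logliks=scores,
            internal_length=0.0,
        )
    fit = fits[choice]
    fit.candidate_logliks = scores
    return fit


# ---------------------------------------------------------------------------
# Distances and NJ+NNI search


def jc_distance(row_i: np.ndarray, row_j: np.ndarray, max_distance: float = 10.0) -> float:
    """JC69 distance -3/4 ln(1 - 4 p_hat / 3); gap columns skipped;
    saturated pairs (p_hat >= 3/4) clamped to ``max_distance``."""
    row_i = np.asarray(row_i)
    row_j = np.asarray(row_j)
    ok = (row_i != GAP) & (row_j != GAP)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no comparable (gap-free) sites")
    p_hat = float((row_i[ok] != row_j[ok]).mean())
    if p_hat >= 0.75:
        return max_distance
    d = -0.75 * math.log1p(-4.0 * p_hat / 3.0)
    return min(d, max_distance)


def jc_distance_matrix(alignment: Alignment) -> np.ndarray:
    n = alignment.n_taxa
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = jc_distance(alignment.matrix[i], alignment.matrix[j])
    return d


def _nni_moves(tree: Tree) -> list[tuple[Node, Node, Node]]:
    """The two NNI moves around each internal edge of the unrooted tree,
    as (edge_child_node, subtree_below, subtree_on_parent_side): swapping
    the two subtrees produces the rearranged topology."""
    moves = []
    for node in tree.postorder():
        if node.parent is None or node.is_leaf:
            continue
        target = next(c for c in node.parent.children if c is not node)
        for child in node.children:
            moves.append((node, child, target))
    return moves


def _apply_swap(a: Node, b: Node) -> None:
    """Exchange two subtrees; each keeps its branch length."""
    pa, pb = a.parent, b.parent
    i = pa.children.index(a)
    j = pb.children.index(b)
    pa.children[i] = b
    pb.children[j] = a
    a.parent, b.parent = pb, pa


def _local_edges(node: Node) -> list[Node]:
    """The five edges around an NNI edge: the edge itself, its child
    edges, and the parent's other edges."""
    edges = [node] + list(node.children)
    edges += [c for c in node.parent.children if c is not node]
    if node.parent.parent is not None:
        edges.append(node.parent)
    return edges


def ml_search(
    alignment: Alignment,
    model,
    rng: np.random.Generator | None = None,
    tol: float = 1e-8,
    max_rounds: int = 20,
) -> MLFit:
    """ML tree search for n >= 4 taxa: NJ starting tree on JC distances,
    then NNI hill-climbing with branch lengths re-optimized per candidate.

    Candidates are pre-scored with a short local optimization of the five
    branches around the rearranged edge; the most promising are then fully
    re-optimized and accepted when they improve the maximized
    log-likelihood.  Deterministic given the alignment: the taxon order is
    canonicalized internally, so permuting alignment rows does not change
    the returned unrooted topology.
    """
    from sba.njst import DistanceMatrix, neighbor_joining

    if alignment.n_taxa < 4:
        raise ValueError("ml_search needs at least 4 taxa")
    order = sorted(alignment.labels)
    aln = alignment.take(order)
    dmat = DistanceMatrix(order, jc_distance_matrix(aln))
    tree = neighbor_joining(dmat).deroot()
    for node in tree.postorder():
        if node.parent is not None:
            node.length = min(max(node.length, 1e-6), MAX_BRANCH_LENGTH)

    engine = _Engine(tree, aln, model)
    best, _ = engine.optimize_all(tol=tol, max_sweeps=20)

    for _ in range(max_rounds):
        scored = []
        for node, a, b in _nni_moves(tree):
            saved = {id(n): n.length for n in tree.postorder()}
            _apply_swap(a, b)
            score, _ = engine.optimize_all(
                tol=1e-4, max_sweeps=1, edges=_local_edges(node), xatol=1e-3
            )
            _apply_swap(b, a)
            for n in tree.postorder():
                n.length = saved[id(n)]
            scored.append((score, a, b))
        scored.sort(key=lambda s: -s[0])
        improved = False
        for score, a, b in scored[:3]:
            if score < best - 1.0:
                continue  # local score hopelessly below the optimum
            saved = {id(n): n.length for n in tree.postorder()}
            _apply_swap(a, b)
            value, _ = engine.optimize_all(tol=tol, max_sweeps=20)
            if value > best + TIE_TOL:
                best = value
                improved = True
                break
            _apply_swap(b, a)
            for n in tree.postorder():
                n.length = saved[id(n)]
        if not improved:
            break
    best = engine.full_pass()
    return MLFit(tree=tree, loglik=best)


# ---------------------------------------------------------------------------
# Program-faithful pipeline with duplicate-sequence reduction


def _duplicate_classes(alignment: Alignment) -> tuple[list[str], dict[str, str]]:
    """Group identical rows: returns (representatives in row order,
    duplicate -> representative map)."""
    reps: list[str] = []
    rep_of: dict[str, str] = {}
    seen: dict[bytes, str] = {}
    for lab, row in zip(alignment.labels, alignment.matrix):
        key = row.tobytes()
        if key in seen:
            rep_of[lab] = seen[key]
        else:
            seen[key] = lab
            reps.append(lab)
    return reps, rep_of


def _reattach_duplicates(tree: Tree, alignment: Alignment, rep_of: dict[str, str]) -> Tree:
    """Insert each duplicate taxon (in alignment row order) adjacent to its
    retained representative, subdividing the representative's terminal
    branch; the last-inserted duplicate ends up closest to the
    representative."""
    t = tree.copy()
    leaf_by_label = {n.label: n for n in t.leaves()}
    for lab in alignment.labels:
        rep = rep_of.get(lab)
        if rep is None:
            continue
        rep_leaf = leaf_by_label[rep]
        parent = rep_leaf.parent
        idx = parent.children.index(rep_leaf)
        joint = Node(length=rep_leaf.length)
        rep_leaf.length = MIN_BRANCH_LENGTH
        dup_leaf = Node(lab, MIN_BRANCH_LENGTH)
        joint.add_child(rep_leaf)
        joint.add_child(dup_leaf)
        joint.parent = parent
        parent.children[idx] = joint
    return Tree(t.root, rooted=False)


def _chain_tree(labels: list[str]) -> Tree:
    """Caterpillar used when fewer than 3 distinct sequences remain."""
    root = Node()
    for lab in labels:
        root.add_child(Node(lab, MIN_BRANCH_LENGTH))
    return Tree(root, rooted=False)


def ml_tree(
    alignment: Alignment,
    model,
    rng: np.random.Generator | None = None,
    tie_rule: str = "random",
    tol: float = 1e-8,
) -> MLFit:
    """ML inference the way shell phylogenetics programs run it: duplicate
    sequences are reduced before the search and re-attached as cherries of
    their retained representative afterwards.

    This reduction is what resolves likelihood-flat data in favour of
    grouping taxa with (near-)identical sequences — the mechanism behind
    short-branch attraction in practice: the attraction tree is returned
    even though its likelihood exactly ties with the alternatives.  With
    four or more distinct sequences the reduced problem is solved by
    :func:`ml_quartet` (4 taxa) or :func:`ml_search` (more), then branch
    lengths of the full tree are re-optimized.  For quartets the fit
    reports the induced topology and internal branch length.
    """
    reps, rep_of = _duplicate_classes(alignment)
    is_quartet = alignment.n_taxa == 4
    if len(reps) == alignment.n_taxa:
        if is_quartet:
            return ml_quartet(alignment, model, tie_rule=tie_rule, rng=rng, tol=tol)
        return ml_search(alignment, model, rng=rng, tol=tol)
    reduced = alignment.take(reps)
    if len(reps) >= 4:
        if len(reps) == 4:
            base = ml_quartet(reduced, model, tie_rule=tie_rule, rng=rng, tol=tol).tree
        else:
            base = ml_search(reduced, model, rng=rng, tol=tol).tree
    else:
        base = _chain_tree(reps)
    full = _reattach_duplicates(base, alignment, rep_of)
    fit = optimize_branch_lengths(full, alignment, model, tol=tol, max_sweeps=20)
    if is_quartet:
        from sba.trees import quartet_topology

        fit.topology = quartet_topology(fit.tree, alignment.labels)
        internal = [
            n.length
            for n in fit.tree.postorder()
            if n.parent is not None and not n.is_leaf
        ]
        fit.internal_length = internal[0] if internal else 0.0
    return fit
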