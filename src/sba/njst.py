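"""NJst species-tree estimation from unrooted gene trees.

NJst summarizes a collection of gene trees by the average internode
distance between every species pair — the number of internal nodes on the
path connecting the two leaves in the unrooted gene tree, averaged over
the gene trees containing both — and applies neighbor joining to the
resulting matrix.  The distance is purely topological, which is what makes
the polytomy remedy effective: collapsing a spurious short internal branch
in an input gene tree removes a node from every path through it and weakens
the artifactual signal instead of feeding it to the species-tree step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import skbio
from skbio.tree import nj as _skbio_nj

from sba.trees import Tree, collapse_short_branches, parse_newick

__all__ = ["DistanceMatrix", "internode_distances", "neighbor_joining", "njst"]


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix with taxon labels."""

    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape must match label count")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if np.any(~np.isfinite(self.matrix)) or np.any(self.matrix < 0):
            raise ValueError("entries must be finite and non-negative")
        if np.any(np.diag(self.matrix) != 0):
            raise ValueError("diagonal must be zero")

    def to_tsv(self) -> str:
        lines = ["\t".join([""] + self.labels)]
        for lab, row in zip(self.labels, self.matrix):
            lines.append("\t".join([lab] + [repr(float(x)) for x in row]))
        return "\n".join(lines) + "\n"


def _internode_counts(tree: Tree) -> tuple[list[str], np.ndarray]:
    """Pairwise internal-node counts on leaf-to-leaf paths of one unrooted
    gene tree (edges on path minus one; a polytomy vertex counts once)."""
    t = tree.deroot() if len(tree.root.children) == 2 else tree
    nodes = list(t.postorder())
    index = {id(n): i for i, n in enumerate(nodes)}
    adj: list[list[int]] = [[] for _ in nodes]
    for n in nodes:
        if n.parent is not None:
            i, j = index[id(n)], index[id(n.parent)]
            adj[i].append(j)
            adj[j].append(i)
    leaves = [(index[id(n)], n.label) for n in nodes if n.is_leaf]
    labels = [lab for _, lab in leaves]
    dist = np.zeros((len(leaves), len(leaves)))
    for a, (start, _) in enumerate(leaves):
        # BFS counting edges
        hops = np.full(len(nodes), -1)
        hops[start] = 0
        queue = [start]
        while queue:
            nxt = []
            for u in queue:
                for v in adj[u]:
                    if hops[v] < 0:
                        hops[v] = hops[u] + 1
                        nxt.append(v)
            queue = nxt
        for b, (stop, _) in enumerate(leaves):
            if b != a:
                dist[a, b] = hops[stop] - 1
    return labels, dist


def internode_distances(gene_trees: Iterable[Tree]) -> DistanceMatrix:
    """Average internode distance between every species pair across the
    gene trees containing both (gene trees may miss species and may be
    polytomous)."""
    sums: dict[tuple[str, str], float] = {}
    counts: dict[tuple[str, str], int] = {}
    species: list[str] = []
    seen = set()
    n_trees = 0
    for tree in gene_trees:
        n_trees += 1
        labels, dist = _internode_counts(tree)
        for lab in labels:
            if lab not in seen:
                seen.add(lab)
                species.append(lab)
        for i, a in enumerate(labels):
            for j in range(i + 1, len(labels)):
                key = (a, labels[j]) if a < labels[j] else (labels[j], a)
                sums[key] = sums.get(key, 0.0) + dist[i, j]
                counts[key] = counts.get(key, 0) + 1
    if n_trees == 0:
        raise ValueError("need at least one gene tree")
    species = sorted(species)
    n = len(species)
    matrix = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            key = (species[i], species[j])
            if key not in counts:
                raise ValueError(f"species {key} never co-occur in any gene tree")
            matrix[i, j] = matrix[j, i] = sums[key] / counts[key]
    return DistanceMatrix(species, matrix)


def neighbor_joining(matrix: DistanceMatrix) -> Tree:
    """Classical neighbor joining (Q-criterion agglomeration); negative
    estimated branch lengths are clamped to 0.  Backed by scikit-bio."""
    if len(matrix.labels) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    sym = (matrix.matrix + matrix.matrix.T) / 2.0  # absorb last-digit drift
    dm = skbio.DistanceMatrix(sym, ids=matrix.labels)
    result = _skbio_nj(dm)
    for node in result.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    newick = str(result)
    return parse_newick(newick, rooted=False)


def njst(gene_trees: Iterable[Tree], collapse: float | None = None) -> Tree:
    """NJst species tree from gene trees: average internode distances then
    neighbor joining.

    With ``collapse`` set (e.g. 1e-5), internal gene-tree branches shorter
    than the threshold are contracted to polytomies first — the remedy for
    short-branch attraction in the input gene trees.
    """
    trees = list(gene_trees)
    if collapse is not None:
        trees = [collapse_short_branches(t, collapse) for t in trees]
    return neighbor_joining(internode_distances(trees))
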