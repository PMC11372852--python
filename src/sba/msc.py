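"""Multispecies-coalescent gene-tree simulation with per-branch theta.

Species trees carry divergence branch lengths tau and population-size
parameters theta, both in mutation units; the pairwise coalescence rate in
a population is 2/theta (the MP-EST/phybase convention), so k lineages
coalesce at total rate k(k-1)/theta.  One allele is sampled per species.
Species trees need not be ultrametric: coalescent times are simulated per
population and a tip branch simply contributes its printed tau to the
gene-tree terminal branch.

Closed forms for the probability that lineages fail to coalesce within an
ancestral population (exp(-2 tau / theta) for two lineages, exp(-6 tau /
theta) for three) quantify when a bifurcating species tree behaves like a
star: if the product p1 p2 is near 1, all four alleles meet in the root
population and the gene-tree topology distribution is uniform over the
three resolved quartets.
"""

from __future__ import annotations

import math
import re

import numpy as np

from sba.trees import Node, Tree, parse_newick, SP_STAR, SP_BIF, SP_TREE8

__all__ = [
    "SpeciesTree",
    "simulate_gene_tree",
    "no_coal_prob_2",
    "no_coal_prob_3",
    "root_coal_scenario_prob",
    "species_tree_star",
    "species_tree_bif",
    "species_tree_8taxon",
]

_THETA_RE = re.compile(r"\[&?\s*theta\s*=\s*([0-9eE.+-]+)\s*\]")


class SpeciesTree:
    """A rooted species tree with per-ancestral-population theta.

    ``thetas`` maps the clade (frozenset of descendant leaf labels) of each
    internal node — including the root — to the theta of the population on
    the branch above that node (for the root: the root population).
    """

    def __init__(self, tree: Tree, thetas: dict[frozenset, float]):
        self.tree = tree
        self.thetas = {frozenset(k): float(v) for k, v in thetas.items()}
        for node in tree.postorder():
            if node.is_leaf:
                continue
            clade = self._clade(node)
            if clade not in self.thetas:
                raise ValueError(f"missing theta for ancestral population {sorted(clade)}")
            if self.thetas[clade] <= 0:
                raise ValueError("theta must be > 0")

    @staticmethod
    def _clade(node: Node) -> frozenset:
        out = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n.label)
            else:
                stack.extend(n.children)
        return frozenset(out)

    def theta_of(self, node: Node) -> float:
        return self.thetas[self._clade(node)]

    @classmethod
    def from_newick(
        cls,
        text: str,
        thetas: dict | None = None,
        default_theta: float | None = None,
    ) -> "SpeciesTree":
        """Build from newick; theta per ancestral population is taken from
        ``[&theta=...]`` comments in the newick string, from the ``thetas``
        sidecar table (clade label sets, frozenset or tuple keys), or from
        ``default_theta``.
        """
        annotated = _THETA_RE.findall(text)
        stripped = _THETA_RE.sub("", text)
        tree = parse_newick(stripped, rooted=True)
        table: dict[frozenset, float] = {}
        if thetas:
            table.update({frozenset(k): float(v) for k, v in thetas.items()})
        if annotated:
            table.update(_thetas_from_comments(text, tree))
        if default_theta is not None:
            for node in tree.postorder():
                if not node.is_leaf:
                    table.setdefault(cls._clade(node), float(default_theta))
        return cls(tree, table)

    def to_newick(self) -> str:
        """Newick with theta bracketed comments on internal branches."""

        def fmt(node: Node) -> str:
            if node.is_leaf:
                return f"{node.label}:{node.length!r}"
            inner = ",".join(fmt(c) for c in node.children)
            theta = self.thetas[self._clade(node)]
            return f"({inner})[&theta={theta!r}]:{node.length!r}"

        root = self.tree.root
        inner = ",".join(fmt(c) for c in root.children)
        theta = self.thetas[self._clade(root)]
        return f"({inner})[&theta={theta!r}];"


def _thetas_from_comments(text: str, tree: Tree) -> dict[frozenset, float]:
    """Parse [&theta=...] comments positionally: each comment annotates the
    closing parenthesis it follows."""
    table: dict[frozenset, float] = {}
    # walk the newick text, matching ')' to internal nodes in postorder
    internal_nodes = [n for n in tree.postorder() if not n.is_leaf]
    close_positions = []
    depth_stack: list[int] = []
    order = []
    for i, ch in enumerate(text):
        if ch == "(":
            depth_stack.append(i)
        elif ch == ")":
            depth_stack.pop()
            order.append(i)
    if len(order) != len(internal_nodes):
        return table
    # postorder of ')' in text corresponds to postorder-by-closing of nodes,
    # which matches Tree.postorder restricted to internals for newick input
    for pos, node in zip(order, internal_nodes):
        m = _THETA_RE.match(text, pos + 1)
        if m:
            table[SpeciesTree._clade(node)] = float(m.group(1))
    return table


# ---------------------------------------------------------------------------
# Simulation


def _coalesce_in_population(
    lineages: list[tuple[Node, float]],
    theta: float,
    duration: float,
    rng: np.random.Generator,
) -> tuple[list[tuple[Node, float]], int]:
    """Run the coalescent among ``lineages`` for ``duration`` mutation
    units at pair rate 2/theta.  Each lineage is (gene-tree node, pending
    branch length); survivors leave with pending increased by the time
    spent.  Returns (surviving lineages, number of coalescences)."""
    lineages = list(lineages)
    elapsed = 0.0
    n_events = 0
    while len(lineages) > 1:
        n = len(lineages)
        rate = n * (n - 1) / theta  # n(n-1)/2 pairs x 2/theta
        wait = rng.exponential(1.0 / rate)
        if elapsed + wait > duration:
            break
        elapsed += wait
        lineages = [(node, pending + wait) for node, pending in lineages]
        i, j = rng.choice(n, size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        node_i, pend_i = lineages[i]
        node_j, pend_j = lineages[j]
        parent = Node()
        node_i.length = pend_i
        node_j.length = pend_j
        parent.add_child(node_i)
        parent.add_child(node_j)
        lineages = [lin for k, lin in enumerate(lineages) if k not in (i, j)]
        lineages.append((parent, 0.0))
        n_events += 1
    remaining = duration - elapsed
    return [(node, pending + remaining) for node, pending in lineages], n_events


def simulate_gene_tree(
    stree: SpeciesTree,
    rng: np.random.Generator,
    return_events: bool = False,
):
    """Simulate one gene tree under the MSC (one allele per species).

    Gene-tree branch lengths are in mutation units: accumulated species
    tree tau plus coalescent waiting times.  With ``return_events`` the
    per-population coalescence counts are also returned (keyed by the
    population's clade), which lets the closed-form no-coalescence
    probabilities be checked against the simulator directly.
    """
    pools: dict[int, list[tuple[Node, float]]] = {}
    events: dict[frozenset, int] = {}
    for node in stree.tree.postorder():
        if node.is_leaf:
            pools[id(node)] = [(Node(label=node.label), node.length)]
            continue
        pool: list[tuple[Node, float]] = []
        for child in node.children:
            pool.extend(pools[id(child)])
        theta = stree.theta_of(node)
        duration = math.inf if node.parent is None else node.length
        pools[id(node)], n_events = _coalesce_in_population(pool, theta, duration, rng)
        events[SpeciesTree._clade(node)] = n_events
    final = pools[id(stree.tree.root)]
    assert len(final) == 1
    root, _ = final[0]
    root.length = 0.0
    tree = Tree(root, rooted=True)
    return (tree, events) if return_events else tree


# ---------------------------------------------------------------------------
# Closed-form no-coalescence probabilities


def no_coal_prob_2(tau: float, theta: float) -> float:
    """P(two lineages do not coalesce within a population of duration tau):
    exp(-2 tau / theta)."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if theta <= 0:
        raise ValueError("theta must be > 0")
    return math.exp(-2.0 * tau / theta)


def no_coal_prob_3(tau: float, theta: float) -> float:
    """P(three lineages undergo no coalescence within duration tau): three
    pairs at rate 2/theta each, so exp(-6 tau / theta)."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if theta <= 0:
        raise ValueError("theta must be > 0")
    return math.exp(-6.0 * tau / theta)


def root_coal_scenario_prob(stree: SpeciesTree) -> float:
    """For an asymmetric 4-taxon species tree (((a,b):tau1, c):tau2, d),
    the probability that all four alleles coalesce only in the root
    population: p = p1 p2 with p1 = exp(-2 tau1/theta1), p2 =
    exp(-6 tau2/theta2)."""
    tree = stree.tree
    root = tree.root
    if len(tree.leaf_labels()) != 4:
        raise ValueError("need a 4-taxon species tree")
    internals = [c for c in root.children if not c.is_leaf]
    if len(root.children) != 2 or len(internals) != 1:
        raise ValueError("species tree is not the asymmetric (((a,b),c),d) shape")
    n3 = internals[0]
    inner = [c for c in n3.children if not c.is_leaf]
    if len(n3.children) != 2 or len(inner) != 1 or any(not l.is_leaf for l in inner[0].children):
        raise ValueError("species tree is not the asymmetric (((a,b),c),d) shape")
    n2 = inner[0]
    tau1, theta1 = n2.length, stree.theta_of(n2)
    tau2, theta2 = n3.length, stree.theta_of(n3)
    return no_coal_prob_2(tau1, theta1) * no_coal_prob_3(tau2, theta2)


# ---------------------------------------------------------------------------
# The three study species trees: root population theta 1e-4; other
# ancestral populations theta 0.01.


def species_tree_star(root_theta: float = 1e-4) -> SpeciesTree:
    """4-taxon star species tree with short tips to S1 and S3."""
    return SpeciesTree.from_newick(SP_STAR, default_theta=root_theta)


def species_tree_bif(root_theta: float = 1e-4, internal_theta: float = 0.01) -> SpeciesTree:
    """Asymmetric 4-taxon species tree with 1e-4 internal branches."""
    tree = parse_newick(SP_BIF, rooted=True)
    thetas = {}
    for node in tree.postorder():
        if node.is_leaf:
            continue
        clade = SpeciesTree._clade(node)
        thetas[clade] = root_theta if node.parent is None else internal_theta
    return SpeciesTree(tree, thetas)


def species_tree_8taxon(root_theta: float = 1e-4, internal_theta: float = 0.01) -> SpeciesTree:
    """8-taxon species tree with A and B on 1e-4 terminal branches."""
    tree = parse_newick(SP_TREE8, rooted=True)
    thetas = {}
    for node in tree.postorder():
        if node.is_leaf:
            continue
        clade = SpeciesTree._clade(node)
        thetas[clade] = root_theta if node.parent is None else internal_theta
    return SpeciesTree(tree, thetas)
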