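"""Tree data model, newick I/O, and topology predicates.

Trees are stored rooted (every node has a parent except the root) with
branch lengths in expected substitutions per site.  Unrooted semantics —
quartet topologies, bipartitions, monophyly — are obtained by treating the
edge set of the rooted storage as an unrooted graph, so all topology
predicates are invariant under re-rooting.  Polytomies (nodes with more
than two children) are permitted and are the output of
:func:`collapse_short_branches`, the polytomy remedy for short-branch
artifacts.
"""

from __future__ import annotations

import enum
from typing import Iterable, Iterator, Sequence

import dendropy

__all__ = [
    "Node",
    "Tree",
    "QuartetTopology",
    "NewickError",
    "parse_newick",
    "write_newick",
    "quartet_topology",
    "is_monophyletic",
    "collapse_short_branches",
    "STAR1",
    "STAR2",
    "BIF3",
    "BIF4",
    "TREE8",
    "SP_STAR",
    "SP_BIF",
    "SP_TREE8",
]


class NewickError(ValueError):
    """Raised when a newick string cannot be parsed."""


class Node:
    """A tree node: parent link (``None`` for the root), ordered children,
    optional leaf label, and the length of the branch to its parent."""

    __slots__ = ("parent", "children", "label", "length")

    def __init__(self, label: str | None = None, length: float = 0.0):
        self.parent: Node | None = None
        self.children: list[Node] = []
        self.label = label
        self.length = float(length)

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = f"leaf {self.label!r}" if self.is_leaf else f"internal ({len(self.children)} children)"
        return f"<Node {kind} length={self.length}>"


class Tree:
    """Rooted storage of a (possibly unrooted) phylogenetic tree.

    The ``rooted`` flag records whether the root is meaningful (species
    trees, coalescent gene trees) or merely a storage artifact (ML trees,
    which are unrooted).  Topology predicates never depend on it.
    """

    def __init__(self, root: Node, rooted: bool = True):
        self.root = root
        self.rooted = rooted
        self._validate()

    # -- construction / validation ------------------------------------
    def _validate(self) -> None:
        labels = [n.label for n in self.leaves()]
        if len(labels) != len(set(labels)):
            raise ValueError("leaf labels must be unique")
        for node in self.postorder():
            if not (node.length >= 0.0 and node.length == node.length and node.length != float("inf")):
                raise ValueError(f"branch length must be finite and >= 0, got {node.length!r}")
            if node.is_leaf and node.label is None:
                raise ValueError("every leaf must carry a label")

    # -- traversal ----------------------------------------------------
    def postorder(self) -> Iterator[Node]:
        stack: list[tuple[Node, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def copy(self) -> "Tree":
        def clone(node: Node) -> Node:
            new = Node(node.label, node.length)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return Tree(clone(self.root), rooted=self.rooted)

    # -- unrooted structure -------------------------------------------
    def bipartitions(self, include_trivial: bool = False) -> set[frozenset[str]]:
        """Bipartitions of the unrooted tree, each encoded as the side not
        containing the lexicographically smallest leaf label."""
        all_labels = frozenset(self.leaf_labels())
        ref = min(all_labels)
        sides: set[frozenset[str]] = set()
        below: dict[int, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.label])
            else:
                below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
            if node is self.root:
                continue
            side = below[id(node)]
            if ref in side:
                side = all_labels - side
            if len(side) == 0 or side == all_labels:
                continue
            trivial = len(side) == 1 or len(side) == len(all_labels) - 1
            if trivial and not include_trivial:
                continue
            sides.add(side)
        return sides

    def n_internal_edges(self) -> int:
        """Internal edges of the unrooted tree (root of degree 2 merges its
        two incident storage edges into one)."""
        count = 0
        for node in self.postorder():
            if node is self.root or node.is_leaf:
                continue
            count += 1
        if len(self.root.children) == 2 and not any(c.is_leaf for c in self.root.children):
            count -= 1  # the two root edges are one unrooted edge
        return count

    def deroot(self) -> "Tree":
        """Return a copy with any degree-2 root suppressed (basal
        multifurcation), the storage form of an unrooted tree."""
        t = self.copy()
        while len(t.root.children) == 2:
            internal = next((c for c in t.root.children if not c.is_leaf), None)
            if internal is None:
                break  # two-leaf tree: nothing to suppress
            other = next(c for c in t.root.children if c is not internal)
            other.length += internal.length
            t.root.children.remove(internal)
            for grandchild in internal.children:
                t.root.add_child(grandchild)
        t.rooted = False
        return Tree(t.root, rooted=False)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Tree {len(self.leaf_labels())} leaves rooted={self.rooted}>"


class QuartetTopology(enum.Enum):
    """Resolved quartet topology relative to an ordered leaf quartet
    (a, b, c, d): T1 = ab|cd, T2 = ac|bd, T3 = ad|bc, or the unresolved
    STAR."""

    T1 = "T1"
    T2 = "T2"
    T3 = "T3"
    STAR = "STAR"


# ---------------------------------------------------------------------------
# Newick I/O


def _from_dendropy(dnode: dendropy.Node) -> Node:
    label = None
    if dnode.taxon is not None:
        label = dnode.taxon.label
    elif dnode.is_leaf():
        label = dnode.label
    length = dnode.edge.length if dnode.edge.length is not None else 0.0
    node = Node(label, length)
    for child in dnode.child_nodes():
        node.add_child(_from_dendropy(child))
    return node


def parse_newick(text: str, rooted: bool = True) -> Tree:
    """Parse a newick string into a :class:`Tree`.

    Branch lengths default to 0 when absent; polytomies are preserved.
    Raises :class:`NewickError` (with the tokenizer's position information)
    on malformed input.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickError(f"malformed newick: {exc}") from exc
    root = _from_dendropy(dtree.seed_node)
    return Tree(root, rooted=rooted)


def _format_length(x: float) -> str:
    return repr(float(x))


def _newick_subtree(node: Node) -> str:
    if node.is_leaf:
        return f"{node.label}:{_format_length(node.length)}"
    inner = ",".join(_newick_subtree(c) for c in node.children)
    return f"({inner}):{_format_length(node.length)}"


def write_newick(tree: Tree) -> str:
    """Serialize to newick with full-precision branch lengths; round-trips
    through :func:`parse_newick` exactly."""
    root = tree.root
    if root.is_leaf:
        return f"({root.label}:{_format_length(root.length)});"
    inner = ",".join(_newick_subtree(c) for c in root.children)
    return f"({inner});"


# ---------------------------------------------------------------------------
# Topology predicates


def quartet_topology(tree: Tree, leaves: Sequence[str]) -> QuartetTopology:
    """Induced unrooted topology of an ordered leaf quartet.

    Returns ``T1`` when the tree has an edge separating ``{leaves[0],
    leaves[1]}`` from ``{leaves[2], leaves[3]}``; analogously for ``T2``
    (0,2|1,3) and ``T3`` (0,3|1,2); ``STAR`` when no edge resolves the
    quartet.
    """
    a, b, c, d = leaves
    present = set(tree.leaf_labels())
    for lab in (a, b, c, d):
        if lab not in present:
            raise ValueError(f"leaf {lab!r} not in tree")
    quartet = {a, b, c, d}
    pairings = {
        frozenset([a, b]): QuartetTopology.T1,
        frozenset([a, c]): QuartetTopology.T2,
        frozenset([a, d]): QuartetTopology.T3,
    }
    below: dict[int, set[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = {node.label} & quartet
        else:
            below[id(node)] = set().union(*(below[id(ch)] for ch in node.children))
        if node is tree.root:
            continue
        side = below[id(node)]
        if len(side) == 2:
            other = quartet - side
            key = frozenset(side) if a in side else frozenset(other)
            return pairings[key]
    return QuartetTopology.STAR


def is_monophyletic(tree: Tree, labels: Iterable[str]) -> bool:
    """Whether ``labels`` form one side of some edge of the unrooted tree
    (bipartition test; symmetric in the complement set)."""
    group = frozenset(labels)
    all_labels = frozenset(tree.leaf_labels())
    if not group or group == all_labels:
        raise ValueError("label set must be a proper non-empty subset of the leaves")
    if not group <= all_labels:
        raise ValueError(f"unknown labels: {sorted(group - all_labels)}")
    sides = tree.bipartitions(include_trivial=True)
    complement = all_labels - group
    return group in sides or complement in sides


def collapse_short_branches(tree: Tree, epsilon: float) -> Tree:
    """Contract every internal edge shorter than ``epsilon`` into a
    polytomy; leaf edges are never contracted.

    This is the remedy for short-branch attraction: an estimated internal
    branch below the resolution of the data (e.g. 1e-5) is demoted to a
    polytomy rather than being reported as a resolved — and typically
    biased — grouping.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    t = tree.copy()
    changed = True
    while changed:
        changed = False
        for node in list(t.postorder()):
            if node is t.root or node.is_leaf:
                continue
            if node.length < epsilon:
                parent = node.parent
                idx = parent.children.index(node)
                parent.children.pop(idx)
                for child in node.children:
                    child.parent = parent
                parent.children[idx:idx] = node.children
                changed = True
                break
    return Tree(t.root, rooted=tree.rooted)


# ---------------------------------------------------------------------------
# Canonical scenario trees.  The two 4-taxon star trees place the short
# terminal branches on S1 and S3; the bifurcating trees add a 1e-4 internal
# branch; the 8-taxon tree puts A and B on 1e-4 terminal branches inside
# two otherwise well-separated clades.

STAR1 = "(S1:0.0001,S2:0.01,S3:0.0001,S4:0.01);"
STAR2 = "(S1:0.1,S2:0.01,S3:0.1,S4:0.01);"
BIF3 = "((S1:0.0001,S2:0.01):0.0001,S3:0.0001,S4:0.01);"
BIF4 = "((S1:0.1,S2:0.01):0.0001,S3:0.1,S4:0.01);"
TREE8 = (
    "((A:0.0001,((S1:0.01,S2:0.01):0.01,S3:0.01):0.01):0.0001,"
    "B:0.0001,((S4:0.01,S5:0.01):0.01,S6:0.01):0.01);"
)

# Species-tree analogues (newick only; per-branch theta is attached in
# sba.msc).  The 8-taxon species tree lengthens the S3/S6 tips to 0.02.
SP_STAR = "(S1:0.0001,S2:0.01,S3:0.0001,S4:0.01);"
SP_BIF = "(((S1:0.0001,S2:0.01):0.0001,S3:0.0001):0.0001,S4:0.01);"
SP_TREE8 = (
    "(((A:0.0001,((S1:0.01,S2:0.01):0.01,S3:0.02):0.01):0.0001,B:0.0001):0.0001,"
    "((S4:0.01,S5:0.01):0.01,S6:0.02):0.01);"
)
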