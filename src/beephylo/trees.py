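"""Rooted-tree data model, Newick I/O, and tree combinatorics.

Trees are rooted and leaf-labeled; internal nodes may be multifurcating.
Branch lengths and support values are optional, and absence is distinct from
zero.  All topology comparisons in this package are insensitive to child
order.  The model is deliberately small: algorithmic modules (terraces,
instability scores, Mk reconstruction) walk ``Node`` objects directly.

Newick parsing is delegated to dendropy and converted into this model;
support values written as internal-node labels are auto-detected and
normalized to proportions in [0, 1] (values > 1 are assumed to be
percentages on [0, 100]).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Iterator, Sequence

import dendropy
import numpy as np

__all__ = [
    "Node",
    "Tree",
    "Triplet",
    "NewickParseError",
    "TreeValidationError",
    "parse_newick",
    "write_newick",
    "induced_subtree",
    "rooted_triplets",
    "random_rooted_binary",
    "nodal_distance",
    "count_binary_topologies",
    "enumerate_rooted_binary",
    "topologies_equal",
]


class NewickParseError(ValueError):
    """Malformed Newick input; message includes the offending position."""


class TreeValidationError(ValueError):
    """Structurally invalid tree (duplicate leaves, unary nodes, ...)."""


@dataclass
class Node:
    label: str | None = None
    length: float | None = None
    support: float | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Node"]:
        stack, out = [self], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))


class Tree:
    """A rooted, leaf-labeled tree with optional branch lengths/supports."""

    def __init__(self, root: Node, validate: bool = True):
        self.root = root
        if validate:
            self.validate()

    # -- structure ---------------------------------------------------------

    def validate(self) -> None:
        labels: list[str] = []
        for node in self.root.postorder():
            if node.is_leaf:
                if not node.label:
                    raise TreeValidationError("leaf with empty label")
                labels.append(node.label)
            elif len(node.children) < 2:
                raise TreeValidationError(
                    f"internal node with {len(node.children)} child(ren); "
                    "every internal node must have >= 2"
                )
            if node.length is not None and node.length < 0:
                raise TreeValidationError(f"negative branch length {node.length}")
        dupes = {x for x in labels if labels.count(x) > 1}
        if dupes:
            raise TreeValidationError(f"duplicate leaf labels: {sorted(dupes)}")

    def leaves(self) -> list[Node]:
        return [n for n in self.root.postorder() if n.is_leaf]

    def leaf_labels(self) -> frozenset[str]:
        return frozenset(n.label for n in self.leaves())

    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def preorder(self) -> Iterator[Node]:
        return self.root.preorder()

    def is_binary(self) -> bool:
        return all(
            len(n.children) in (0, 2) for n in self.root.postorder()
        )

    def copy(self) -> "Tree":
        def rec(n: Node) -> Node:
            return Node(n.label, n.length, n.support, [rec(c) for c in n.children])

        return Tree(rec(self.root), validate=False)

    def parent_map(self) -> dict[int, Node | None]:
        """id(node) -> parent Node (None for root)."""
        parents: dict[int, Node | None] = {id(self.root): None}
        for node in self.root.preorder():
            for child in node.children:
                parents[id(child)] = node
        return parents

    def clade_map(self) -> dict[int, frozenset[str]]:
        """id(node) -> frozenset of leaf labels below it."""
        clades: dict[int, frozenset[str]] = {}
        for node in self.root.postorder():
            if node.is_leaf:
                clades[id(node)] = frozenset([node.label])
            else:
                acc: set[str] = set()
                for c in node.children:
                    acc |= clades[id(c)]
                clades[id(node)] = frozenset(acc)
        return clades

    def find_leaf(self, label: str) -> Node:
        for leaf in self.leaves():
            if leaf.label == label:
                return leaf
        raise KeyError(f"taxon {label!r} not in tree")

    # -- convenience -------------------------------------------------------

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tree({write_newick(self)})"


@dataclass(frozen=True)
class Triplet:
    """Rooted triplet ab|c: taxa a and b are closer to each other than to c."""

    pair: frozenset[str]
    outgroup: str

    def __post_init__(self):
        if len(self.pair) != 2 or self.outgroup in self.pair:
            raise ValueError("triplet requires three pairwise-distinct taxa")

    def __str__(self) -> str:
        a, b = sorted(self.pair)
        return f"{a}{b}|{self.outgroup}"


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------


def _support_from_label(label: str | None) -> float | None:
    if label is None or label == "":
        return None
    try:
        return float(label)
    except ValueError:
        return None


def parse_newick(text: str) -> Tree:
    """Parse a Newick string into a :class:`Tree`.

    Internal-node labels that parse as numbers are interpreted as support
    values; if any exceeds 1 the whole set is treated as percentages and
    divided by 100.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        if "Duplicate taxon labels" in str(exc):
            raise TreeValidationError(f"duplicate leaf labels: {exc}") from exc
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    def rec(dnode) -> Node:
        children = [rec(c) for c in dnode.child_nodes()]
        if children:
            label = dnode.label
            support = _support_from_label(label)
            return Node(
                label=None if support is not None else label,
                length=dnode.edge.length,
                support=support,
                children=children,
            )
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        return Node(label=label, length=dnode.edge.length)

    root = rec(dtree.seed_node)
    tree = Tree(root)
    supports = [n.support for n in tree.postorder() if n.support is not None]
    if supports and max(supports) > 1.0:
        for n in tree.postorder():
            if n.support is not None:
                n.support = n.support / 100.0
    return tree


def _fmt_num(x: float) -> str:
    if x == int(x) and abs(x) < 1e15:
        return str(int(x)) if float(int(x)) == x else repr(x)
    return repr(x)


def write_newick(tree: Tree, include_support: bool = True) -> str:
    def rec(n: Node) -> str:
        if n.is_leaf:
            s = n.label
        else:
            s = "(" + ",".join(rec(c) for c in n.children) + ")"
            if include_support and n.support is not None:
                s += _fmt_num(n.support)
            elif n.label:
                s += n.label
        if n.length is not None:
            s += f":{_fmt_num(n.length)}"
        return s

    return rec(tree.root) + ";"


# ---------------------------------------------------------------------------
# Restriction, triplets, distances
# ---------------------------------------------------------------------------


def induced_subtree(tree: Tree, taxa: Iterable[str]) -> Tree:
    """Restrict ``tree`` to ``taxa``, suppressing degree-2 nodes.

    Branch lengths are summed across suppressed nodes when present; a chain
    in which every suppressed edge lacks a length yields an absent length.
    """
    want = frozenset(taxa)
    missing = want - tree.leaf_labels()
    if missing:
        raise KeyError(f"taxa not in tree: {sorted(missing)}")
    if len(want) < 2:
        raise ValueError("restriction requires at least 2 taxa")

    def add_len(a: float | None, b: float | None) -> float | None:
        if a is None and b is None:
            return None
        return (a or 0.0) + (b or 0.0)

    def rec(n: Node) -> Node | None:
        if n.is_leaf:
            if n.label in want:
                return Node(n.label, n.length, n.support)
            return None
        kept = [k for k in (rec(c) for c in n.children) if k is not None]
        if not kept:
            return None
        if len(kept) == 1:
            child = kept[0]
            child.length = add_len(n.length, child.length)
            return child
        return Node(n.label, n.length, n.support, kept)

    root = rec(tree.root)
    assert root is not None
    if not root.is_leaf:
        root.length = None if tree.root.length is None else root.length
    return Tree(root)


def rooted_triplets(tree: Tree) -> set[Triplet]:
    """All rooted triplets ab|c displayed by the tree.

    A 3-subset {a,b,c} displays ab|c iff the most recent common ancestor of
    a and b is a strict descendant of that of all three.  Unresolved
    3-subsets (all three hanging off one multifurcation) are omitted.
    """
    clades = tree.clade_map()
    universe = tree.leaf_labels()
    if len(universe) < 3:
        return set()
    out: set[Triplet] = set()
    for node in tree.postorder():
        if node.is_leaf:
            continue
        kids = node.children
        outside = universe - clades[id(node)]
        for ci, cj in combinations(kids, 2):
            for a in clades[id(ci)]:
                for b in clades[id(cj)]:
                    pair = frozenset((a, b))
                    for c in outside:
                        out.add(Triplet(pair, c))
    return out


def nodal_distance(tree: Tree, a: str, b: str) -> int:
    """Number of edges on the path between leaves a and b."""
    if a == b:
        tree.find_leaf(a)
        return 0
    parents = tree.parent_map()
    node_a, node_b = tree.find_leaf(a), tree.find_leaf(b)

    def ancestors(n: Node) -> list[Node]:
        path = [n]
        while parents[id(path[-1])] is not None:
            path.append(parents[id(path[-1])])
        return path

    pa, pb = ancestors(node_a), ancestors(node_b)
    ids_a = {id(n): i for i, n in enumerate(pa)}
    for j, n in enumerate(pb):
        if id(n) in ids_a:
            return ids_a[id(n)] + j
    raise AssertionError("disconnected tree")  # pragma: no cover


def nodal_distance_matrix(tree: Tree, order: Sequence[str]) -> np.ndarray:
    """Dense matrix of pairwise leaf path lengths (in edges).

    O(n^2) via leaf depths and per-node cross-child pairing; used by the
    taxon-instability score where per-pair calls would be too slow.
    """
    depth: dict[str, int] = {}
    stack: list[tuple[Node, int]] = [(tree.root, 0)]
    while stack:
        node, d = stack.pop()
        if node.is_leaf:
            depth[node.label] = d
        stack.extend((c, d + 1) for c in node.children)

    idx = {t: i for i, t in enumerate(order)}
    n = len(order)
    dvec = np.array([depth[t] for t in order])
    dist = dvec[:, None] + dvec[None, :]

    clades = tree.clade_map()
    node_depth: dict[int, int] = {id(tree.root): 0}
    for node in tree.preorder():
        for c in node.children:
            node_depth[id(c)] = node_depth[id(node)] + 1
    for node in tree.postorder():
        if node.is_leaf:
            continue
        d = node_depth[id(node)]
        for ci, cj in combinations(node.children, 2):
            ai = np.array([idx[t] for t in clades[id(ci)]])
            aj = np.array([idx[t] for t in clades[id(cj)]])
            dist[np.ix_(ai, aj)] -= 2 * d
            dist[np.ix_(aj, ai)] -= 2 * d
    np.fill_diagonal(dist, 0)
    return dist


# ---------------------------------------------------------------------------
# Random and exhaustive topology generation
# ---------------------------------------------------------------------------


def count_binary_topologies(n: int) -> int:
    """(2n-3)!! rooted binary leaf-labeled topologies, exact integer."""
    if n < 2:
        raise ValueError("need at least 2 taxa")
    out = 1
    for k in range(3, 2 * n - 2, 2):
        out *= k
    return out


def random_rooted_binary(
    taxa: Iterable[str], seed: int | np.random.Generator
) -> Tree:
    """Uniform random rooted binary topology on ``taxa``.

    Sequential construction: each new leaf subdivides an edge chosen
    uniformly at random (the root edge included), which yields the uniform
    distribution over the (2n-3)!! labeled topologies.
    """
    labels = sorted(set(taxa))
    if len(labels) < 2:
        raise ValueError("need at least 2 taxa")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = list(rng.permutation(len(labels)))
    root = Node(children=[Node(labels[order[0]]), Node(labels[order[1]])])
    # edges represented by their child node; the root edge by the root itself
    edges: list[Node] = [root, root.children[0], root.children[1]]
    parents: dict[int, Node | None] = {
        id(root): None,
        id(root.children[0]): root,
        id(root.children[1]): root,
    }
    for k in order[2:]:
        leaf = Node(labels[k])
        target = edges[int(rng.integers(len(edges)))]
        parent = parents[id(target)]
        joint = Node(children=[target, leaf])
        if parent is None:
            root = joint
        else:
            parent.children[parent.children.index(target)] = joint
            parents[id(joint)] = parent
        parents[id(target)] = joint
        parents[id(leaf)] = joint
        if parent is None:
            parents[id(joint)] = None
        edges.extend([joint, leaf])
    return Tree(root)


# -- lightweight nested-tuple topologies (exhaustive oracle machinery) ------
#
# For brute-force enumeration a tree is a leaf label (str) or a tuple of two
# subtrees.  This representation is independent of the Node/Tree classes so
# that enumeration-based oracles do not share code with what they check.

TupleTree = object  # str | tuple


def enumerate_rooted_binary(labels: Sequence[str]) -> list[TupleTree]:
    """All rooted binary topologies on ``labels`` as nested tuples."""
    labels = list(labels)
    if len(labels) < 2:
        raise ValueError("need at least 2 taxa")
    trees: list[TupleTree] = [(labels[0], labels[1])]
    for lab in labels[2:]:
        nxt: list[TupleTree] = []
        for t in trees:
            nxt.extend(_insert_leaf(t, lab))
        trees = nxt
    return trees


def _insert_leaf(t: TupleTree, lab: str):
    yield (t, lab)  # new root above everything
    if isinstance(t, tuple):
        left, right = t
        for sub in _insert_leaf(left, lab):
            yield (sub, right)
        for sub in _insert_leaf(right, lab):
            yield (left, sub)


def tuple_leaves(t: TupleTree) -> frozenset[str]:
    if isinstance(t, str):
        return frozenset([t])
    return tuple_leaves(t[0]) | tuple_leaves(t[1])


def tuple_restrict(t: TupleTree, taxa: frozenset) -> TupleTree | None:
    if isinstance(t, str):
        return t if t in taxa else None
    kept = [s for s in (tuple_restrict(c, taxa) for c in t) if s is not None]
    if not kept:
        return None
    if len(kept) == 1:
        return kept[0]
    return tuple(kept)


def tuple_canonical(t: TupleTree):
    if isinstance(t, str):
        return t
    kids = sorted((tuple_canonical(c) for c in t), key=lambda x: str(x))
    return tuple(kids)


def tree_to_tuple(tree: Tree) -> TupleTree:
    def rec(n: Node):
        if n.is_leaf:
            return n.label
        return tuple(rec(c) for c in n.children)

    return rec(tree.root)


def tuple_to_tree(t: TupleTree) -> Tree:
    def rec(x) -> Node:
        if isinstance(x, str):
            return Node(x)
        return Node(children=[rec(c) for c in x])

    return Tree(rec(t))


def topologies_equal(a: Tree, b: Tree) -> bool:
    """Order-insensitive topology equality (labels only)."""
    return tuple_canonical(tree_to_tuple(a)) == tuple_canonical(tree_to_tuple(b))
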