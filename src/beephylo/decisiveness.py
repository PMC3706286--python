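"""Taxon-coverage diagnostics: decisiveness, terraces, and the BUILD tree.

A supermatrix with missing taxon x gene blocks constrains tree inference
only through the induced per-partition subtrees.  Two different binary
trees that restrict identically on every partition's taxon set are
indistinguishable under partitioned analysis; the set of such trees is a
*terrace*.  A coverage pattern is *decisive* for a tree when that tree's
terrace contains only itself, and *partially decisive* to the extent that
random equiprobable trees are each pinned down uniquely.

Everything here works in the rooted-triplet formulation: a binary tree is
determined by its set of rooted triplets, so the terrace of T under
coverage Y_1..Y_k is exactly the set of binary trees on the full taxon set
displaying every triplet of every T|Y_i.  Counting those trees uses the
BUILD (Aho) graph recursion: for a taxon subset S, connected components of
the graph with an edge {a,b} for every triplet ab|c whose three taxa lie in
S must each fall wholly on one side of the root, and the count is the sum
over bipartitions of components of the product of subproblem counts.  (A
simpler recursion that multiplies by (2m-3)!! over m components undercounts
whenever recursing into a component union loses triplets; the bipartition
sum is exact and is validated against exhaustive enumeration in the test
suite.)  Counts are exact unbounded integers throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .trees import (
    Node,
    Tree,
    Triplet,
    count_binary_topologies,
    induced_subtree,
    random_rooted_binary,
    rooted_triplets,
    tree_to_tuple,
    tuple_canonical,
    tuple_restrict,
    enumerate_rooted_binary,
    tuple_to_tree,
)

__all__ = [
    "CoveragePattern",
    "TerraceResult",
    "IncompatibleTripletsError",
    "terrace_size",
    "build_tree",
    "is_decisive_for_tree",
    "partial_decisiveness",
    "enumerate_terrace",
    "coverage_from_csv",
]


class IncompatibleTripletsError(ValueError):
    """The supplied rooted triplets admit no common tree."""


@dataclass(frozen=True)
class CoveragePattern:
    """Partition taxon sets Y_1..Y_k over a full taxon universe."""

    partitions: tuple[frozenset[str], ...]
    universe: frozenset[str]

    def __post_init__(self):
        if len(self.partitions) < 1:
            raise ValueError("need at least one partition")
        for y in self.partitions:
            if not y <= self.universe:
                raise ValueError(f"partition {sorted(y)} not within universe")

    @classmethod
    def from_sets(
        cls, partitions: Iterable[Iterable[str]], universe: Iterable[str] | None = None
    ) -> "CoveragePattern":
        parts = tuple(frozenset(y) for y in partitions)
        if universe is None:
            uni: frozenset[str] = frozenset().union(*parts) if parts else frozenset()
        else:
            uni = frozenset(universe)
        return cls(parts, uni)

    def add_taxon(self, partition_index: int, taxon: str) -> "CoveragePattern":
        parts = list(self.partitions)
        parts[partition_index] = parts[partition_index] | {taxon}
        return CoveragePattern(tuple(parts), self.universe | {taxon})


@dataclass
class TerraceResult:
    size: int
    build: Tree
    decisive: bool

    def __post_init__(self):
        assert self.decisive == (self.size == 1)


# ---------------------------------------------------------------------------
# Triplet bookkeeping
# ---------------------------------------------------------------------------


def _coverage_triplets(tree: Tree, coverage: CoveragePattern) -> set[Triplet]:
    """Union of rooted triplets of tree|Y_i over all partitions with >=3 taxa."""
    trips: set[Triplet] = set()
    for y in coverage.partitions:
        if len(y) >= 3:
            trips |= rooted_triplets(induced_subtree(tree, y))
    return trips


def _pair_index(triplets: Iterable[Triplet]) -> dict[frozenset, set[str]]:
    """cherry pair -> set of outgroups over all triplets."""
    index: dict[frozenset, set[str]] = {}
    for t in triplets:
        index.setdefault(t.pair, set()).add(t.outgroup)
    return index


def _components(taxa: frozenset, pair_index: dict[frozenset, set[str]]) -> list[frozenset]:
    """Connected components of the BUILD graph on ``taxa``.

    Edge {a,b} present iff some triplet ab|c has all of a, b, c in ``taxa``.
    """
    parent: dict[str, str] = {t: t for t in taxa}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for pair, outs in pair_index.items():
        if pair <= taxa and not outs.isdisjoint(taxa):
            a, b = pair
            union(a, b)
    comps: dict[str, set[str]] = {}
    for t in taxa:
        comps.setdefault(find(t), set()).add(t)
    return [frozenset(c) for c in comps.values()]


def _has_internal_triplet(taxa: frozenset, pair_index) -> bool:
    for pair, outs in pair_index.items():
        if pair <= taxa and not outs.isdisjoint(taxa):
            return True
    return False


# ---------------------------------------------------------------------------
# BUILD tree (Aho supertree)
# ---------------------------------------------------------------------------


def _build_from_triplets(taxa: frozenset, pair_index) -> Node:
    if len(taxa) == 1:
        (t,) = taxa
        return Node(t)
    comps = _components(taxa, pair_index)
    if len(comps) == 1:
        raise IncompatibleTripletsError(
            _conflict_message(taxa, pair_index)
        )
    return Node(children=[_build_from_triplets(c, pair_index) for c in comps])


def _conflict_message(taxa: frozenset, pair_index) -> str:
    # Look for a directly contradictory pair on the same 3-subset for a
    # readable certificate; otherwise report the stuck taxon set.
    by_trio: dict[frozenset, list[tuple[frozenset, str]]] = {}
    for pair, outs in pair_index.items():
        if pair <= taxa:
            for c in outs & taxa:
                trio = pair | {c}
                by_trio.setdefault(trio, []).append((pair, c))
    for trio, entries in by_trio.items():
        pairs = {p for p, _ in entries}
        if len(pairs) > 1:
            (p1, c1), (p2, c2) = entries[0], entries[1]
            a1, b1 = sorted(p1)
            a2, b2 = sorted(p2)
            return (
                "incompatible rooted triplets: "
                f"{a1}{b1}|{c1} conflicts with {a2}{b2}|{c2}"
            )
    return (
        "incompatible rooted triplets: BUILD graph on "
        f"{sorted(taxa)} does not disconnect"
    )


def build_tree(subtrees: Sequence[Tree]) -> Tree:
    """BUILD (Aho) consensus of the union of the subtrees' rooted triplets.

    The result may be multifurcating; for the subtrees induced by a tree's
    coverage pattern it is the Adams consensus of the terrace.
    """
    if not subtrees:
        raise ValueError("need at least one subtree")
    taxa = frozenset().union(*(t.leaf_labels() for t in subtrees))
    trips: set[Triplet] = set()
    for t in subtrees:
        if len(t.leaf_labels()) >= 3:
            trips |= rooted_triplets(t)
    return build_tree_from_triplets(trips, taxa)


def build_tree_from_triplets(
    triplets: Iterable[Triplet], taxa: Iterable[str]
) -> Tree:
    universe = frozenset(taxa)
    root = _build_from_triplets(universe, _pair_index(triplets))
    return Tree(root)


# ---------------------------------------------------------------------------
# Terrace size (exact count)
# ---------------------------------------------------------------------------


def _count_trees(taxa: frozenset, pair_index, cache: dict) -> int:
    if len(taxa) <= 2:
        return 1
    hit = cache.get(taxa)
    if hit is not None:
        return hit
    if not _has_internal_triplet(taxa, pair_index):
        out = count_binary_topologies(len(taxa))
        cache[taxa] = out
        return out
    comps = _components(taxa, pair_index)
    m = len(comps)
    if m == 1:
        cache[taxa] = 0
        return 0
    total = 0
    # sum over unordered bipartitions of components; component 0 fixed left
    for mask in range(1 << (m - 1)):
        left = [comps[0]]
        right = []
        for j in range(1, m):
            (left if (mask >> (j - 1)) & 1 else right).append(comps[j])
        if not right:
            continue
        sl: frozenset = frozenset().union(*left)
        sr: frozenset = frozenset().union(*right)
        total += _count_trees(sl, pair_index, cache) * _count_trees(
            sr, pair_index, cache
        )
    cache[taxa] = total
    return total


def terrace_size(tree: Tree, coverage: CoveragePattern) -> TerraceResult:
    """Exact number of rooted binary trees with the same induced subtree as
    ``tree`` on every partition, plus the BUILD tree of those subtrees."""
    if tree.leaf_labels() != coverage.universe:
        raise ValueError(
            "tree leaf set differs from coverage universe: "
            f"{sorted(tree.leaf_labels() ^ coverage.universe)}"
        )
    if not tree.is_binary():
        raise ValueError("terrace_size requires a binary tree")
    trips = _coverage_triplets(tree, coverage)
    index = _pair_index(trips)
    universe = coverage.universe
    if len(universe) < 3:
        return TerraceResult(1, tree.copy(), True)
    size = _count_trees(universe, index, {})
    build = Tree(_build_from_triplets(universe, index))
    return TerraceResult(size, build, size == 1)


def enumerate_terrace(
    tree: Tree, coverage: CoveragePattern, max_count: int | None = None
) -> tuple[list[Tree], bool]:
    """Exhaustively list all terrace members (test oracle for terrace_size).

    Generates every rooted binary topology on the universe and keeps those
    whose restriction to each partition equals the input tree's.  Returns
    (members, truncated); ``truncated`` is True when ``max_count`` stopped
    the enumeration early.
    """
    universe = sorted(coverage.universe)
    ref = tree_to_tuple(tree)
    targets = []
    for y in coverage.partitions:
        if len(y) >= 3:
            targets.append((frozenset(y), tuple_canonical(tuple_restrict(ref, frozenset(y)))))
    members: list[Tree] = []
    for cand in enumerate_rooted_binary(universe):
        ok = all(
            tuple_canonical(tuple_restrict(cand, y)) == want for y, want in targets
        )
        if ok:
            members.append(tuple_to_tree(cand))
            if max_count is not None and len(members) >= max_count:
                return members, True
    return members, False


# ---------------------------------------------------------------------------
# Decisiveness
# ---------------------------------------------------------------------------


def _decisive_fast(tree: Tree, partitions: Sequence[frozenset]) -> bool:
    """Terrace size == 1, without counting.

    The counting recursion for a displayed tree visits exactly the clades of
    the tree, and the count is 1 iff at every internal node the BUILD graph
    on that node's leaf set has exactly the two child clades as its
    connected components.  Cross-child edges cannot occur (any outgroup
    witness would have to lie outside the clade), so the check reduces to:
    each child clade is connected.  A partition Y contributes, on clade
    leaf set S, a clique on each child-group of lca(Y ∩ S) — which is what
    gets unioned here, avoiding explicit triplet enumeration.
    """
    clades = tree.clade_map()
    for node in tree.postorder():
        if node.is_leaf:
            continue
        s = clades[id(node)]
        if len(s) == 2:
            continue
        # union-find over s
        parent = {t: t for t in s}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for y in partitions:
            z = y & s
            if len(z) < 2:
                continue
            # descend to lca(z) within this clade
            w = node
            while True:
                sub = None
                for c in w.children:
                    zc = z & clades[id(c)]
                    if zc == z:
                        sub = c
                        break
                if sub is None or sub.is_leaf:
                    break
                w = sub
            if len(z) < 3:
                continue  # no triplets from this partition inside s
            groups = [z & clades[id(c)] for c in w.children]
            for g in groups:
                g = list(g)
                for t in g[1:]:
                    ra, rb = find(g[0]), find(t)
                    if ra != rb:
                        parent[ra] = rb
        for child in node.children:
            cl = list(clades[id(child)])
            r0 = find(cl[0])
            if any(find(t) != r0 for t in cl[1:]):
                return False
    return True


def is_decisive_for_tree(tree: Tree, coverage: CoveragePattern) -> bool:
    """True iff the coverage pattern pins ``tree`` down uniquely
    (terrace size 1)."""
    if tree.leaf_labels() != coverage.universe:
        raise ValueError("tree leaf set differs from coverage universe")
    if not tree.is_binary():
        raise ValueError("decisiveness check requires a binary tree")
    return _decisive_fast(tree, coverage.partitions)


def partial_decisiveness(
    coverage: CoveragePattern,
    n_trees: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Fraction of uniform random rooted binary trees for which the coverage
    is decisive, with the binomial Monte-Carlo standard error."""
    if len(coverage.universe) < 4:
        raise ValueError("partial decisiveness needs a universe of >= 4 taxa")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hits = 0
    for _ in range(n_trees):
        t = random_rooted_binary(coverage.universe, rng)
        if _decisive_fast(t, coverage.partitions):
            hits += 1
    p = hits / n_trees
    se = float(np.sqrt(p * (1 - p) / n_trees))
    return p, se


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------


def coverage_from_csv(path) -> CoveragePattern:
    """Read a taxa x partitions 0/1 matrix (first column = taxon)."""
    import pandas as pd

    df = pd.read_csv(path, index_col=0)
    parts = [
        frozenset(df.index[df[col].astype(int) == 1]) for col in df.columns
    ]
    return CoveragePattern.from_sets(parts, universe=df.index)


def coverage_to_csv(coverage: CoveragePattern, path, names: Sequence[str] | None = None):
    import pandas as pd

    names = list(names) if names is not None else [
        f"p{i+1}" for i in range(len(coverage.partitions))
    ]
    taxa = sorted(coverage.universe)
    data = {
        name: [int(t in y) for t in taxa]
        for name, y in zip(names, coverage.partitions)
    }
    pd.DataFrame(data, index=pd.Index(taxa, name="taxon")).to_csv(path)
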