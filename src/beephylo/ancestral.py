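"""Ancestral geographic-range reconstruction over binary area characters.

Each of seven broad geographic areas (Africa, Eastern Palearctic, Western
Palearctic, North America, South America, Central America, Oceania) is
treated as an independent presence/absence character on the taxa of a
rooted binary tree.  Two reconstructions are offered per area:

* Fitch parsimony — bottom-up state sets with a top-down pass;  '?'
  (unknown, e.g. outgroups with a null distribution) is treated as {0, 1}.
* Two-state Mk maximum likelihood — a symmetric continuous-time Markov
  model with a single rate q and stationary frequencies (1/2, 1/2); the
  change probability over a branch of length t is (1 - e^{-2qt})/2.  The
  rate is fitted by maximizing the Felsenstein pruning likelihood, and
  per-node marginal presence probabilities are obtained by combining
  downward (subtree) and upward (rest-of-tree) partial likelihoods — the
  rerooting method.

Composite ranges at a node are ranked by the product of per-area marginals
(areas treated as independent, matching the per-area model), capped at
four areas per range.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .trees import Node, Tree

__all__ = [
    "AREAS",
    "MkModel",
    "NodeReconstruction",
    "fitch_ancestral",
    "mk_fit_and_reconstruct",
    "mk_loglik",
    "mk_fit_shared_rate",
    "composite_ranges",
    "summarize_clade_ranges",
    "read_range_csv",
    "MAX_RANGE_SIZE",
]

AREAS = (
    "Africa",
    "Eastern Palearctic",
    "Western Palearctic",
    "North America",
    "South America",
    "Central America",
    "Oceania",
)
MAX_RANGE_SIZE = 4


@dataclass(frozen=True)
class MkModel:
    """Symmetric two-state Markov model with rate q (changes per unit length)."""

    q: float

    def __post_init__(self):
        if not self.q > 0:
            raise ValueError("rate q must be > 0")

    def p_change(self, t: float) -> float:
        return (1.0 - math.exp(-2.0 * self.q * t)) / 2.0

    def transition_matrix(self, t: float) -> np.ndarray:
        pc = self.p_change(t)
        return np.array([[1 - pc, pc], [pc, 1 - pc]])


@dataclass
class NodeReconstruction:
    """Per-node reconstruction for one binary character.

    ``state_sets`` maps node id to the parsimony state set; ``marginals``
    maps node id to the ML probability of state 1 (presence).  ``order``
    lists node ids in postorder with leaf labels where applicable.
    """

    tree: Tree
    state_sets: dict[int, frozenset[int]] = field(default_factory=dict)
    marginals: dict[int, float] = field(default_factory=dict)
    parsimony_length: int | None = None
    model: MkModel | None = None
    at_bound: bool = False


# ---------------------------------------------------------------------------
# Fitch parsimony
# ---------------------------------------------------------------------------


def _leaf_states(character: Mapping[str, object], label: str) -> frozenset[int]:
    v = character.get(label, "?")
    if v in (0, 1):
        return frozenset([int(v)])
    if v in ("0", "1"):
        return frozenset([int(v)])
    if v in ("?", None):
        return frozenset([0, 1])
    raise ValueError(f"bad state {v!r} for taxon {label!r}")


def fitch_ancestral(
    tree: Tree, character: Mapping[str, object]
) -> NodeReconstruction:
    """Fitch bottom-up/top-down parsimony reconstruction of one character.

    Unknown ('?') leaves carry {0,1}.  The parsimony length counts
    bottom-up intersection failures.  The top-down pass resolves each
    node's set toward its parent when possible (accelerated-transformation
    flavored tie handling: a node keeps only states shared with its parent's
    final set whenever that intersection is non-empty).
    """
    if not tree.is_binary():
        raise ValueError("Fitch reconstruction requires a binary tree")
    scored = [
        lab for lab in tree.leaf_labels() if character.get(lab, "?") in (0, 1, "0", "1")
    ]
    if len(scored) < 2:
        raise ValueError("need at least 2 scored (non-'?') taxa")

    down: dict[int, frozenset[int]] = {}
    length = 0
    for node in tree.postorder():
        if node.is_leaf:
            down[id(node)] = _leaf_states(character, node.label)
        else:
            a, b = (down[id(c)] for c in node.children)
            inter = a & b
            if inter:
                down[id(node)] = inter
            else:
                down[id(node)] = a | b
                length += 1

    final: dict[int, frozenset[int]] = {id(tree.root): down[id(tree.root)]}
    for node in tree.preorder():
        if node is tree.root:
            pass
        for child in node.children:
            inter = down[id(child)] & final[id(node)]
            final[id(child)] = inter if inter else down[id(child)]

    return NodeReconstruction(tree, state_sets=final, parsimony_length=length)


# ---------------------------------------------------------------------------
# Mk likelihood
# ---------------------------------------------------------------------------


def _leaf_partial(character: Mapping[str, object], label: str) -> np.ndarray:
    states = _leaf_states(character, label)
    return np.array([1.0 if s in states else 0.0 for s in (0, 1)])


def _branch_lengths_or_unit(tree: Tree) -> dict[int, float]:
    lengths = {}
    missing = False
    for node in tree.postorder():
        if node is tree.root:
            continue
        if node.length is None or node.length <= 0:
            missing = True
            lengths[id(node)] = 1.0
        else:
            lengths[id(node)] = float(node.length)
    if missing:
        warnings.warn(
            "tree lacks (positive) branch lengths; falling back to unit lengths"
        )
    return lengths


def mk_loglik(
    tree: Tree, character: Mapping[str, object], q: float,
    _lengths: dict[int, float] | None = None,
) -> float:
    """Felsenstein-pruning log-likelihood of the character under Mk(q)."""
    model = MkModel(q)
    lengths = _lengths if _lengths is not None else _branch_lengths_or_unit(tree)
    partial: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            p = _leaf_partial(character, node.label)
        else:
            p = np.ones(2)
            for child in node.children:
                m = model.transition_matrix(lengths[id(child)])
                p = p * (m @ partial[id(child)])
        partial[id(node)] = p
    lik = 0.5 * partial[id(tree.root)].sum()
    if lik <= 0 or not np.isfinite(lik):
        raise ValueError("non-finite Mk likelihood")
    return float(np.log(lik))


def mk_fit_and_reconstruct(
    tree: Tree,
    character: Mapping[str, object],
    q_bounds: tuple[float, float] = (1e-6, 1e3),
) -> NodeReconstruction:
    """Fit the single Mk rate and compute per-node marginal presence
    probabilities by the rerooting (up/down message) method."""
    if not tree.is_binary():
        raise ValueError("Mk reconstruction requires a binary tree")
    scored = [
        lab for lab in tree.leaf_labels() if character.get(lab, "?") in (0, 1, "0", "1")
    ]
    if len(scored) < 2:
        raise ValueError("need at least 2 scored (non-'?') taxa")
    lengths = _branch_lengths_or_unit(tree)

    res = minimize_scalar(
        lambda lq: -mk_loglik(tree, character, math.exp(lq), _lengths=lengths),
        bounds=(math.log(q_bounds[0]), math.log(q_bounds[1])),
        method="bounded",
        options={"xatol": 1e-8},
    )
    q_hat = float(math.exp(res.x))
    at_bound = (
        q_hat <= q_bounds[0] * 1.01 or q_hat >= q_bounds[1] * 0.99
    )
    if at_bound:
        warnings.warn(f"fitted Mk rate at optimizer bound: q={q_hat:g}")
    model = MkModel(q_hat)

    # downward partials
    down: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            down[id(node)] = _leaf_partial(character, node.label)
        else:
            p = np.ones(2)
            for child in node.children:
                m = model.transition_matrix(lengths[id(child)])
                p = p * (m @ down[id(child)])
            down[id(node)] = p

    # upward messages: out[v] = likelihood of everything outside v's subtree,
    # as a function of v's state (root prior folded in)
    out: dict[int, np.ndarray] = {id(tree.root): np.array([0.5, 0.5])}
    for node in tree.preorder():
        for child in node.children:
            sib = np.ones(2)
            for other in node.children:
                if other is child:
                    continue
                m = model.transition_matrix(lengths[id(other)])
                sib = sib * (m @ down[id(other)])
            msg = out[id(node)] * sib
            m = model.transition_matrix(lengths[id(child)])
            out[id(child)] = m.T @ msg

    marginals: dict[int, float] = {}
    for node in tree.postorder():
        joint = down[id(node)] * out[id(node)]
        total = joint.sum()
        marginals[id(node)] = float(joint[1] / total)

    return NodeReconstruction(
        tree, marginals=marginals, model=model, at_bound=at_bound
    )


def mk_fit_shared_rate(
    tree: Tree,
    characters: Sequence[Mapping[str, object]],
    q_bounds: tuple[float, float] = (1e-6, 1e3),
) -> MkModel:
    """Fit one Mk rate shared across several independent binary characters
    (e.g. the seven area characters) by maximizing the summed pruning
    log-likelihood."""
    lengths = _branch_lengths_or_unit(tree)

    def nll(lq: float) -> float:
        q = math.exp(lq)
        return -sum(
            mk_loglik(tree, ch, q, _lengths=lengths) for ch in characters
        )

    res = minimize_scalar(
        nll,
        bounds=(math.log(q_bounds[0]), math.log(q_bounds[1])),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return MkModel(float(math.exp(res.x)))


# ---------------------------------------------------------------------------
# Clade-level composite-range summaries
# ---------------------------------------------------------------------------


def _clade_node(tree: Tree, taxa: frozenset[str], name: str) -> Node:
    clades = tree.clade_map()
    for node in tree.postorder():
        if clades[id(node)] == taxa:
            return node
    raise ValueError(f"clade {name!r} is not monophyletic in the tree")


def composite_ranges(
    marginals_by_area: Mapping[str, float],
    top: int = 3,
    min_score: float = 0.10,
    max_areas: int = MAX_RANGE_SIZE,
) -> list[tuple[tuple[str, ...], float]]:
    """Rank area subsets by the product of per-area marginals.

    Score of subset R = Π_{a in R} p_a · Π_{a not in R} (1 - p_a), over
    non-empty subsets of at most ``max_areas`` areas.  Subsets scoring below
    ``min_score`` are suppressed.  Ties: smaller ranges first, then
    alphabetically.
    """
    areas = list(marginals_by_area)
    scored = []
    for k in range(1, min(max_areas, len(areas)) + 1):
        for combo in combinations(areas, k):
            score = 1.0
            for a in areas:
                p = marginals_by_area[a]
                score *= p if a in combo else (1.0 - p)
            scored.append((combo, score))
    scored.sort(key=lambda x: (-x[1], len(x[0]), x[0]))
    return [(combo, s) for combo, s in scored[:top] if s >= min_score]


def summarize_clade_ranges(
    reconstructions: Mapping[str, NodeReconstruction],
    clades: Mapping[str, Iterable[str]],
    top: int = 3,
    min_score: float = 0.10,
) -> pd.DataFrame:
    """Top-ranked composite ancestral ranges at each named clade's root.

    ``reconstructions`` maps area name to that area's NodeReconstruction
    (all on the same tree, with ML marginals filled in).
    """
    first = next(iter(reconstructions.values()))
    tree = first.tree
    rows = []
    for name, taxa in clades.items():
        node = _clade_node(tree, frozenset(taxa), name)
        marg = {
            area: rec.marginals[id(node)] for area, rec in reconstructions.items()
        }
        ranked = composite_ranges(marg, top=top, min_score=min_score)
        for rank, (combo, score) in enumerate(ranked, start=1):
            rows.append(
                {
                    "clade": name,
                    "rank": rank,
                    "range": "+".join(combo),
                    "score": score,
                }
            )
    return pd.DataFrame(rows, columns=["clade", "rank", "range", "score"])


def read_range_csv(path, areas: Sequence[str] = AREAS) -> pd.DataFrame:
    """taxon x areas binary matrix; '?' rows (outgroups) allowed as NaN."""
    df = pd.read_csv(path, index_col=0)
    missing = [a for a in areas if a not in df.columns]
    if missing:
        raise ValueError(f"range matrix missing area columns: {missing}")
    return df[list(areas)]
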