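"""Rogue-taxon detection over a bootstrap tree pool, and AIC model ranking.

A rogue ("unstable") taxon wanders across bootstrap replicates, depressing
support values without carrying consistent signal.  The instability score
of taxon t over a pool of trees is

    I(t) = sum over unordered tree pairs (i, j), sum over other taxa x of
           |d_i(t, x) - d_j(t, x)| / (d_i(t, x) + d_j(t, x))^2

with d the nodal (edge-count) path distance.  The denominator down-weights
disagreement among distant pairs, so taxa that jump between nearby
placements score highest.  I(t) is zero iff t keeps identical nodal
distances to every other taxon across the whole pool.  The top
``fraction`` of taxa by score are pruned (count = ceil(fraction * N), ties
broken by label for determinism).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .trees import Tree, induced_subtree, nodal_distance_matrix

__all__ = [
    "TreeSet",
    "instability_scores",
    "prune_unstable",
    "n_to_remove",
    "aic_rank",
]


@dataclass
class TreeSet:
    trees: list[Tree]

    def __post_init__(self):
        if len(self.trees) < 2:
            raise ValueError("need at least 2 trees")
        sets = {t.leaf_labels() for t in self.trees}
        if len(sets) != 1:
            raise ValueError("trees must share a common leaf set")

    @property
    def taxa(self) -> frozenset[str]:
        return self.trees[0].leaf_labels()


def instability_scores(trees: TreeSet) -> pd.DataFrame:
    """Per-taxon instability, raw and rank-normalized (1 = most unstable)."""
    order = sorted(trees.taxa)
    n = len(order)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    mats = [
        nodal_distance_matrix(t, order).astype(float) for t in trees.trees
    ]
    scores = np.zeros(n)
    for i in range(len(mats)):
        for j in range(i + 1, len(mats)):
            di, dj = mats[i], mats[j]
            with np.errstate(divide="ignore", invalid="ignore"):
                contrib = np.abs(di - dj) / (di + dj) ** 2
            np.fill_diagonal(contrib, 0.0)
            scores += contrib.sum(axis=1)
    df = pd.DataFrame({"taxon": order, "instability": scores})
    df["rank_normalized"] = df["instability"].rank(
        ascending=False, method="min"
    ) / n
    return df.sort_values(
        ["instability", "taxon"], ascending=[False, True]
    ).reset_index(drop=True)


def n_to_remove(n_taxa: int, fraction: float) -> int:
    """ceil(fraction * N): the top-percentile removal count (ceiling, not
    rounding, so 1% of 1376 taxa is 14 and 1% of 376 is 4)."""
    return math.ceil(fraction * n_taxa)


def prune_unstable(
    trees: TreeSet, fraction: float = 0.01
) -> tuple[list[str], TreeSet]:
    """Remove the ceil(fraction*N) most unstable taxa from every tree."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    scores = instability_scores(trees)
    n = len(scores)
    k = n_to_remove(n, fraction)
    if n - k < 3:
        raise ValueError(f"pruning {k} of {n} taxa would leave fewer than 3")
    ranked = scores.sort_values(
        ["instability", "taxon"], ascending=[False, True]
    )
    removed = list(ranked["taxon"].iloc[:k])
    keep = trees.taxa - set(removed)
    pruned = TreeSet([induced_subtree(t, keep) for t in trees.trees])
    return removed, pruned


def aic_rank(schemes: Sequence[tuple[str, float, int]]) -> pd.DataFrame:
    """Rank partitioning schemes by AIC = 2k - 2 lnL (best first)."""
    rows = []
    for name, lnl, k in schemes:
        if not np.isfinite(lnl):
            raise ValueError(f"non-finite log-likelihood for {name}")
        if k < 1:
            raise ValueError(f"parameter count must be >= 1 for {name}")
        rows.append({"scheme": name, "lnL": lnl, "k": k, "AIC": 2 * k - 2 * lnl})
    df = pd.DataFrame(rows).sort_values(["AIC", "scheme"]).reset_index(drop=True)
    df["dAIC"] = df["AIC"] - df["AIC"].iloc[0]
    return df
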