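"""Synthetic data generators emulating a sparse multi-gene supermatrix study.

The generators produce every input the pipeline consumes — a ranked
taxonomy with a known true tree, a taxon x gene coverage pattern with a
controllable empty-cell fraction, per-gene alignments evolved on the true
tree, bootstrap-like tree pools with planted rogue taxa, Gaussian
site-log-likelihood surrogates for topology-test calibration, and binary
geographic ranges evolved under a two-state Markov process — so the whole
analysis runs end to end with no downloads and a known ground truth.

Determinism: every generator takes the master seed (or a Generator); the
dataset builder derives one child seed per sub-generator through
``numpy.random.SeedSequence.spawn`` so individual stages are reproducible
in isolation.

The default configuration mirrors the shape of large bee supermatrices:
20 nuclear gene partitions, a seven-family ingroup plus a small wasp-like
outgroup clade present in every partition, ~85% empty taxon x gene cells,
and seven binary geographic areas.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ancestral import AREAS, MkModel
from .decisiveness import CoveragePattern
from .supermatrix import (
    GeneAlignment,
    SequenceRecord,
    TaxonomyTable,
    GAP,
)
from .trees import Node, Tree, random_rooted_binary

__all__ = [
    "SimulationConfig",
    "BEE_LIKE",
    "simulate_taxonomy",
    "simulate_coverage",
    "simulate_alignments",
    "simulate_sitelh",
    "simulate_ranges",
    "simulate_bootstrap_pool",
    "simulate_dataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    n_families: int = 7
    tribes_per_family: int = 2
    genera_per_tribe: int = 2
    species_per_genus: int = 2
    n_outgroup: int = 4
    n_genes: int = 20
    target_empty_fraction: float = 0.85
    gene_length: int = 150
    branch_length_mean: float = 0.05
    substitution_rate: float = 1.0
    ragged_end_prob: float = 0.0
    mk_rate: float = 0.5
    seed: int = 0

    @property
    def n_ingroup(self) -> int:
        return (
            self.n_families
            * self.tribes_per_family
            * self.genera_per_tribe
            * self.species_per_genus
        )


#: Study-shaped preset: 20 genes, ~85% empty cells, seven areas, a
#: seven-family ingroup and a wasp-like outgroup clade in every partition.
BEE_LIKE = SimulationConfig(
    n_families=7,
    tribes_per_family=3,
    genera_per_tribe=2,
    species_per_genus=2,
    n_outgroup=4,
    n_genes=20,
    target_empty_fraction=0.85,
    gene_length=150,
    ragged_end_prob=0.3,
)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Taxonomy + true tree
# ---------------------------------------------------------------------------


def _random_clade_tree(
    groups: Mapping[str, Node], rng: np.random.Generator
) -> Node:
    """Random binary arrangement of pre-built subtrees (clade roots)."""
    names = sorted(groups)
    if len(names) == 1:
        return groups[names[0]]
    shape = random_rooted_binary(names, rng)

    def rec(n: Node) -> Node:
        if n.is_leaf:
            return groups[n.label]
        return Node(children=[rec(c) for c in n.children])

    return rec(shape.root)


def simulate_taxonomy(
    cfg: SimulationConfig, seed=None
) -> tuple[TaxonomyTable, Tree]:
    """Nested taxonomy plus a matching true tree with monophyletic ranks.

    Every rank (family, tribe, genus) forms a clade on the true tree; a
    designated outgroup clade is sister to the ingroup.  Branch lengths are
    i.i.d. exponential with mean ``cfg.branch_length_mean``.
    """
    rng = _rng(cfg.seed if seed is None else seed)
    rows = []
    family_nodes: dict[str, Node] = {}
    for f in range(1, cfg.n_families + 1):
        fam = f"fam{f}"
        tribe_nodes: dict[str, Node] = {}
        for t in range(1, cfg.tribes_per_family + 1):
            tribe = f"{fam}t{t}"
            genus_nodes: dict[str, Node] = {}
            for g in range(1, cfg.genera_per_tribe + 1):
                genus = f"{tribe}g{g}"
                species_nodes: dict[str, Node] = {}
                for s in range(1, cfg.species_per_genus + 1):
                    sp = f"{genus}s{s}"
                    rows.append(
                        {"species": sp, "genus": genus, "tribe": tribe,
                         "family": fam, "ingroup": 1}
                    )
                    species_nodes[sp] = Node(sp)
                genus_nodes[genus] = _random_clade_tree(species_nodes, rng)
            tribe_nodes[tribe] = _random_clade_tree(genus_nodes, rng)
        family_nodes[fam] = _random_clade_tree(tribe_nodes, rng)
    ingroup = _random_clade_tree(family_nodes, rng)

    if cfg.n_outgroup > 0:
        out_nodes: dict[str, Node] = {}
        for o in range(1, cfg.n_outgroup + 1):
            sp = f"out{o}"
            rows.append(
                {"species": sp, "genus": "outg", "tribe": "outt",
                 "family": "outf", "ingroup": 0}
            )
            out_nodes[sp] = Node(sp)
        outgroup = _random_clade_tree(out_nodes, rng)
        root = Node(children=[outgroup, ingroup])
    else:
        root = ingroup
    tree = Tree(root)
    for node in tree.postorder():
        if node is not tree.root:
            node.length = float(rng.exponential(cfg.branch_length_mean))
    return TaxonomyTable(pd.DataFrame(rows)), tree


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------


def simulate_coverage(
    cfg: SimulationConfig,
    taxa: Sequence[str],
    seed=None,
    anchor_taxon: str | None = None,
) -> CoveragePattern:
    """Bernoulli taxon x gene sampling targeting a global empty fraction.

    Gene-specific presence rates are spread around the target (some genes
    densely sampled, some sparse, as in real mined matrices).  The anchor
    taxon (default ``out1``) is present in every gene so a shared root
    taxon exists; every taxon's row is resampled until it has >= 2 genes.
    """
    rng = _rng(cfg.seed if seed is None else seed)
    taxa = sorted(taxa)
    k = cfg.n_genes
    e = cfg.target_empty_fraction
    if not 0 <= e < 1:
        raise ValueError("target empty fraction must be in [0, 1)")
    if e > 0 and (1 - e) * k < 2.0:
        raise ValueError(
            f"target empty fraction {e} infeasible with {k} genes and the "
            ">=2-genes-per-taxon constraint"
        )
    anchor = anchor_taxon or ("out1" if "out1" in taxa else taxa[0])

    if e == 0:
        return CoveragePattern.from_sets([set(taxa)] * k, universe=taxa)

    # heterogeneous per-gene rates: long-tailed spread so a few genes are
    # densely sampled and most are sparse, as in mined matrices.  Rows are
    # conditioned on >= 2 genes, which inflates realized presence, so the
    # rates are calibrated against the exact conditional (truncated
    # Poisson-binomial) expectation to hit the global target.
    spread = rng.lognormal(0.0, 0.9, size=k)
    base = spread / spread.mean()
    n_taxa = len(taxa)

    def expected_empty(scale: float) -> float:
        r = np.clip(scale * base, 0.005, 0.98)
        q = 1.0 - r
        prod_q = np.prod(q)
        # P(taxon row kept pattern): conditioned on >= 2 present
        p0 = prod_q
        p1 = np.sum(r / q) * prod_q
        p_ge2 = max(1.0 - p0 - p1, 1e-300)
        # E[X_g ; sum >= 2] = r_g * (1 - prod_{h != g} q_h)
        e_pres = np.sum(r * (1.0 - prod_q / q)) / p_ge2
        e_pres = min(e_pres, float(k))
        # anchor taxon always fully present
        total = (n_taxa - 1) * e_pres + k
        return 1.0 - total / (n_taxa * k)

    lo, hi = 1e-4, 0.98 / base.min()  # at hi every gene saturates at 0.98
    if expected_empty(hi) > e:
        raise ValueError(
            f"target empty fraction {e} unreachable with this gene profile"
        )
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if expected_empty(mid) > e:
            lo = mid
        else:
            hi = mid
    rates = np.clip(0.5 * (lo + hi) * base, 0.005, 0.98)

    presence = np.zeros((len(taxa), k), dtype=bool)
    for ti, taxon in enumerate(taxa):
        for _ in range(1000):
            row = rng.random(k) < rates
            if taxon == anchor:
                row[:] = True
            if row.sum() >= 2:
                presence[ti] = row
                break
        else:  # pragma: no cover - unreachable under the feasibility check
            raise RuntimeError("could not satisfy >=2 genes per taxon")
    parts = [
        frozenset(taxa[ti] for ti in np.flatnonzero(presence[:, gi]))
        for gi in range(k)
    ]
    return CoveragePattern.from_sets(parts, universe=taxa)


# ---------------------------------------------------------------------------
# Sequence evolution (single-rate symmetric nucleotide model)
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _evolve_sites(
    tree: Tree, n_sites: int, rate: float, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """i.i.d. sites under the 4-state symmetric (Jukes-Cantor-type) model."""
    seqs: dict[str, np.ndarray] = {}

    def p_change(t: float) -> float:
        return 0.75 * (1.0 - np.exp(-4.0 * rate * t / 3.0))

    root_states = rng.integers(0, 4, size=n_sites)
    stack = [(tree.root, root_states)]
    while stack:
        node, states = stack.pop()
        if node.is_leaf:
            seqs[node.label] = states
            continue
        for child in node.children:
            t = child.length if child.length is not None else 0.0
            pc = p_change(t)
            change = rng.random(n_sites) < pc
            shifted = (states + rng.integers(1, 4, size=n_sites)) % 4
            stack.append((child, np.where(change, shifted, states)))
    return seqs


def simulate_alignments(
    true_tree: Tree,
    coverage: CoveragePattern,
    cfg: SimulationConfig,
    seed=None,
) -> list[GeneAlignment]:
    """Per-gene alignments on the true tree, honoring the coverage pattern.

    Taxa absent from a gene's partition are omitted from that alignment.
    With ``cfg.ragged_end_prob > 0`` some sequences get leading/trailing
    gap runs so end-trimming has something to do.
    """
    rng = _rng(cfg.seed if seed is None else seed)
    out = []
    for gi, y in enumerate(coverage.partitions):
        states = _evolve_sites(
            true_tree, cfg.gene_length, cfg.substitution_rate, rng
        )
        seqs: dict[str, str] = {}
        for taxon in sorted(y):
            chars = _BASES[states[taxon]]
            if cfg.ragged_end_prob > 0 and rng.random() < cfg.ragged_end_prob:
                lead = int(rng.integers(1, max(2, cfg.gene_length // 5)))
                trail = int(rng.integers(1, max(2, cfg.gene_length // 5)))
                chars = chars.copy()
                chars[:lead] = GAP
                chars[cfg.gene_length - trail:] = GAP
            seqs[taxon] = "".join(chars)
        out.append(GeneAlignment(f"gene{gi + 1:02d}", seqs))
    return out


def records_from_alignments(
    alignments: Iterable[GeneAlignment],
) -> list[SequenceRecord]:
    """Wrap aligned sequences as one SequenceRecord per (species, gene)."""
    recs = []
    for aln in alignments:
        for i, (taxon, seq) in enumerate(sorted(aln.sequences.items())):
            recs.append(
                SequenceRecord(f"{aln.gene}_{i:04d}", taxon, aln.gene, seq)
            )
    return recs


# ---------------------------------------------------------------------------
# Site-log-likelihood surrogate
# ---------------------------------------------------------------------------


def simulate_sitelh(
    n_trees: int,
    n_sites: int,
    separation: Sequence[float] | float = 0.0,
    noise_sd: float = 0.1,
    seed=0,
    base_mean: float = -1.5,
    base_sd: float = 0.5,
):
    """Gaussian surrogate site log-likelihoods: ℓ_ij = base_j + offset_i + ε_ij.

    ``separation`` gives the per-tree per-site mean offset (scalar 0 for the
    exchangeable null used in test calibration).  Returns a
    SiteLikelihoodMatrix.
    """
    from .topotests import SiteLikelihoodMatrix

    if n_trees < 2:
        raise ValueError("need >= 2 trees")
    rng = _rng(seed)
    offsets = (
        np.full(n_trees, float(separation))
        if np.isscalar(separation)
        else np.asarray(separation, dtype=float)
    )
    if offsets.shape != (n_trees,):
        raise ValueError("separation must be scalar or length n_trees")
    base = rng.normal(base_mean, base_sd, size=n_sites)
    eps = rng.normal(0.0, noise_sd, size=(n_trees, n_sites))
    values = base[None, :] + offsets[:, None] + eps
    labels = [f"H{i + 1}" for i in range(n_trees)]
    return SiteLikelihoodMatrix(labels, values)


# ---------------------------------------------------------------------------
# Geographic ranges
# ---------------------------------------------------------------------------


def simulate_ranges(
    true_tree: Tree,
    q: float,
    seed=0,
    areas: Sequence[str] = AREAS,
    root_states: Sequence[int] | None = None,
    ingroup: Iterable[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Binary area characters evolved independently under Mk(q).

    Returns (taxon x area 0/1 DataFrame, recorded root states).  Ingroup
    taxa must occupy >= 1 area; an all-absent ingroup leaf has its row
    redrawn conditional on its parent's states (along its own terminal
    branch) until at least one area is present.
    """
    rng = _rng(seed)
    model = MkModel(q)
    taxa = sorted(true_tree.leaf_labels())
    ingroup_set = set(ingroup) if ingroup is not None else set(taxa)
    if root_states is None:
        roots = {a: int(rng.integers(0, 2)) for a in areas}
    else:
        roots = {a: int(s) for a, s in zip(areas, root_states)}

    parent_states: dict[str, dict[int, int]] = {}
    leaf_states: dict[str, dict[str, int]] = {t: {} for t in taxa}
    leaf_parent_state: dict[str, dict[str, int]] = {t: {} for t in taxa}
    leaf_branch: dict[str, float] = {}

    for area in areas:
        stack = [(true_tree.root, roots[area])]
        while stack:
            node, state = stack.pop()
            if node.is_leaf:
                leaf_states[node.label][area] = state
                continue
            for child in node.children:
                t = child.length if child.length is not None else 1.0
                if child.is_leaf:
                    leaf_parent_state[child.label][area] = state
                    leaf_branch[child.label] = t
                flip = rng.random() < model.p_change(t)
                stack.append((child, 1 - state if flip else state))

    for taxon in taxa:
        if taxon not in ingroup_set:
            continue
        for _ in range(10000):
            if any(leaf_states[taxon][a] == 1 for a in areas):
                break
            t = leaf_branch.get(taxon, 1.0)
            pc = model.p_change(t)
            for area in areas:
                ps = leaf_parent_state[taxon].get(area, roots[area])
                flip = rng.random() < pc
                leaf_states[taxon][area] = 1 - ps if flip else ps
        else:  # pragma: no cover
            raise RuntimeError(f"could not draw a non-empty range for {taxon}")

    df = pd.DataFrame(
        {a: [leaf_states[t][a] for t in taxa] for a in areas},
        index=pd.Index(taxa, name="taxon"),
    )
    return df, roots


# ---------------------------------------------------------------------------
# Bootstrap-like tree pools with planted rogues
# ---------------------------------------------------------------------------


def _detach_leaf(tree: Tree, label: str) -> Tree:
    from .trees import induced_subtree

    keep = tree.leaf_labels() - {label}
    return induced_subtree(tree, keep)


def _attach_leaf(tree: Tree, label: str, rng: np.random.Generator) -> Tree:
    t = tree.copy()
    parents = t.parent_map()
    edges = [n for n in t.root.postorder()]  # root = root edge
    target = edges[int(rng.integers(len(edges)))]
    parent = parents[id(target)]
    joint = Node(children=[target, Node(label)])
    if parent is None:
        return Tree(joint)
    parent.children[parent.children.index(target)] = joint
    return Tree(t.root)


def simulate_bootstrap_pool(
    true_tree: Tree,
    n_trees: int = 100,
    rogue_taxa: Sequence[str] = (),
    seed=0,
) -> list[Tree]:
    """Pool of topology replicates: the true tree with each planted rogue
    taxon re-attached to a uniformly random edge in every replicate."""
    rng = _rng(seed)
    pool = []
    for _ in range(n_trees):
        t = true_tree.copy()
        for rogue in rogue_taxa:
            t = _detach_leaf(t, rogue)
            t = _attach_leaf(t, rogue, rng)
        for node in t.postorder():  # topology pool; lengths irrelevant
            node.length = None
        pool.append(t)
    return pool


# ---------------------------------------------------------------------------
# Whole datasets
# ---------------------------------------------------------------------------


def simulate_dataset(cfg: SimulationConfig = BEE_LIKE) -> dict:
    """Generate every pipeline input under one master seed.

    Child seeds are spawned per stage, so e.g. the coverage pattern is
    reproducible without regenerating alignments.
    """
    ss = np.random.SeedSequence(cfg.seed)
    s_tax, s_cov, s_aln, s_rng = (np.random.default_rng(c) for c in ss.spawn(4))
    taxonomy, true_tree = simulate_taxonomy(cfg, seed=s_tax)
    taxa = taxonomy.species()
    coverage = simulate_coverage(cfg, taxa, seed=s_cov)
    alignments = simulate_alignments(true_tree, coverage, cfg, seed=s_aln)
    ranges, root_states = simulate_ranges(
        true_tree,
        cfg.mk_rate,
        seed=s_rng,
        ingroup=[t for t in taxa if taxonomy.is_ingroup(t)],
    )
    return {
        "config": cfg,
        "taxonomy": taxonomy,
        "true_tree": true_tree,
        "coverage": coverage,
        "alignments": alignments,
        "records": records_from_alignments(alignments),
        "ranges": ranges,
        "range_root_states": root_states,
    }
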