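"""End-to-end analysis over a synthetic dataset with known ground truth.

Stages mirror the supermatrix workflow: simulate inputs, assemble the
matrix, measure coverage diagnostics (missing data, partial decisiveness,
genus-level terrace), score and prune rogue taxa from a bootstrap-like
tree pool, run the topology tests on a site-likelihood matrix with planted
signal, and reconstruct ancestral ranges per area, scoring recovery of the
known root states.  Everything is driven by one master seed.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass

import numpy as np

from . import ancestral, decisiveness, rogues, simulate, supermatrix, topotests
from .trees import induced_subtree

__all__ = ["run_pipeline"]


def run_pipeline(
    cfg: simulate.SimulationConfig = simulate.BEE_LIKE,
    seed: int | None = None,
    n_decisiveness_trees: int = 200,
    n_bootstrap_trees: int = 50,
    n_test_reps: int = 1000,
    rogue_fraction: float = 0.01,
    genus_terrace: bool = True,
) -> dict:
    """Run the whole analysis; returns a flat summary dict of key numbers."""
    if seed is not None:
        cfg = simulate.replace(cfg, seed=seed)
    t0 = time.time()
    ss = np.random.SeedSequence(cfg.seed ^ 0x5EED)
    s_dec, s_pool, s_lh, s_q = ss.spawn(4)
    out: dict = {"seed": cfg.seed}

    # -- simulate + assemble ----------------------------------------------
    ds = simulate.simulate_dataset(cfg)
    sm, report = supermatrix.assemble(ds["alignments"], ds["taxonomy"])
    out["n_taxa"] = report["taxa"]
    out["n_genes"] = report["genes"]
    out["n_sites"] = report["sites"]
    out["missing_cell_fraction"] = report["missing_cell_fraction"]
    out["missing_character_fraction"] = report["missing_character_fraction"]

    # -- decisiveness ------------------------------------------------------
    cov = sm.coverage()
    p, se = decisiveness.partial_decisiveness(
        cov, n_trees=n_decisiveness_trees, seed=np.random.default_rng(s_dec)
    )
    out["partial_decisiveness"] = p
    out["partial_decisiveness_se"] = se

    true_tree = ds["true_tree"]
    sub = induced_subtree(true_tree, sm.taxa)
    out["true_tree_decisive"] = bool(
        decisiveness.is_decisive_for_tree(
            sub,
            decisiveness.CoveragePattern(cov.partitions, frozenset(sm.taxa)),
        )
    )

    # genus-level collapse: denser coverage, terrace often collapses to 1
    alns = {a.gene: a for a in ds["alignments"]}
    reps = supermatrix.collapse_to_genera(
        ds["records"], ds["taxonomy"], alns, n_replicates=3, seed=cfg.seed + 1
    )
    out["genus_missing_cell_fraction"] = float(
        np.mean([supermatrix.missing_fraction(r)[0] for r in reps])
    )
    if genus_terrace:
        gsm = reps[0]
        gtree = induced_subtree(
            _genus_tree(ds), gsm.taxa
        )
        ts = decisiveness.terrace_size(gtree, gsm.coverage())
        out["genus_terrace_size"] = ts.size
        out["genus_decisive"] = ts.decisive

    # -- rogue pruning -----------------------------------------------------
    rng_pool = np.random.default_rng(s_pool)
    taxa = sorted(sm.taxa)
    rogue_taxa = [taxa[int(rng_pool.integers(len(taxa)))]]
    pool = simulate.simulate_bootstrap_pool(
        induced_subtree(true_tree, sm.taxa),
        n_trees=n_bootstrap_trees,
        rogue_taxa=rogue_taxa,
        seed=rng_pool,
    )
    treeset = rogues.TreeSet(pool)
    removed, _ = rogues.prune_unstable(treeset, fraction=rogue_fraction)
    out["planted_rogue"] = rogue_taxa[0]
    out["removed_taxa"] = removed
    out["rogue_recovered"] = rogue_taxa[0] in removed

    # -- topology tests ----------------------------------------------------
    offsets = [0.02] + [0.0] * 4  # hypothesis 1 carries the signal
    m = simulate.simulate_sitelh(
        5, 2000, separation=offsets, noise_sd=0.1, seed=np.random.default_rng(s_lh)
    )
    rep = topotests.topology_test_report(m, n_reps=n_test_reps, seed=cfg.seed + 2)
    out["best_hypothesis"] = rep.iloc[0]["hypothesis"]
    out["best_bic_pp"] = float(rep.iloc[0]["BIC_pp"])
    out["n_rejected_wsh"] = int(rep["reject_WSH"].sum())

    # -- ancestral ranges --------------------------------------------------
    ranges = ds["ranges"]
    roots = ds["range_root_states"]
    ingroup = [t for t in ds["taxonomy"].species() if ds["taxonomy"].is_ingroup(t)]
    recon = {}
    correct = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for area in ancestral.AREAS:
            char = {t: int(ranges.at[t, area]) for t in ingroup}
            rec = ancestral.mk_fit_and_reconstruct(true_tree, char)
            recon[area] = rec
            marg = rec.marginals[id(true_tree.root)]
            correct += (marg >= 0.5) == (roots[area] == 1)
    out["range_root_recovered"] = correct
    out["range_areas"] = len(ancestral.AREAS)

    fam_clades = {
        fam: [
            t for t in ds["taxonomy"].species()
            if ds["taxonomy"].df.at[t, "family"] == fam
        ]
        for fam in sorted(ds["taxonomy"].df["family"].unique())
        if fam != "outf"
    }
    summary = ancestral.summarize_clade_ranges(recon, fam_clades)
    out["clade_range_rows"] = len(summary)
    out["runtime_s"] = time.time() - t0
    return out


def _genus_tree(ds) -> "object":
    """True tree collapsed to one exemplar leaf per genus, relabeled."""
    from .trees import Tree

    taxonomy = ds["taxonomy"]
    tree = ds["true_tree"]
    exemplar = {}
    for sp in sorted(tree.leaf_labels()):
        exemplar.setdefault(taxonomy.genus(sp), sp)
    sub = induced_subtree(tree, set(exemplar.values()))
    sp_to_genus = {sp: g for g, sp in exemplar.items()}
    for leaf in sub.leaves():
        leaf.label = sp_to_genus[leaf.label]
    return Tree(sub.root)
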