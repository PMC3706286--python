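"""Fitch parsimony and Mk maximum-likelihood ancestral reconstruction."""

import itertools
import math
import warnings

import numpy as np
import pytest

from beephylo.ancestral import (
    MkModel,
    composite_ranges,
    fitch_ancestral,
    mk_fit_and_reconstruct,
    mk_fit_shared_rate,
    mk_loglik,
    summarize_clade_ranges,
)
from beephylo.trees import Node, Tree, parse_newick, random_rooted_binary


# ---------------------------------------------------------------------------
# Brute-force oracles (independent of the pruning/Fitch implementations)
# ---------------------------------------------------------------------------


def brute_force_parsimony(tree, character):
    """Minimum changes over all internal labelings, by exhaustion."""
    internals = [n for n in tree.postorder() if not n.is_leaf]
    parents = tree.parent_map()
    leaves = tree.leaves()
    best = math.inf
    for labeling in itertools.product([0, 1], repeat=len(internals)):
        assign = {id(n): s for n, s in zip(internals, labeling)}
        for leaf in leaves:
            v = character.get(leaf.label, "?")
            if v in (0, 1):
                assign[id(leaf)] = v
        ok_costs = []
        # leaves with '?' take the cheaper state
        cost = 0
        for node in tree.postorder():
            if node is tree.root:
                continue
            pa = assign[id(parents[id(node)])]
            if id(node) in assign:
                cost += assign[id(node)] != pa
            # unknown leaf: free to match parent, adds 0
        best = min(best, cost)
    return best


def brute_force_mk_marginal(tree, character, q, node):
    """P(state of ``node`` = 1 | tips) by summing over all internal states."""
    model = MkModel(q)
    internals = [n for n in tree.postorder() if not n.is_leaf]
    parents = tree.parent_map()
    num = 0.0
    den = 0.0
    leaf_sets = {}
    for leaf in tree.leaves():
        v = character.get(leaf.label, "?")
        leaf_sets[id(leaf)] = [int(v)] if v in (0, 1) else [0, 1]
    leaf_ids = [id(l) for l in tree.leaves()]
    for labeling in itertools.product([0, 1], repeat=len(internals)):
        assign = {id(n): s for n, s in zip(internals, labeling)}
        for leaf_choice in itertools.product(
            *[leaf_sets[i] for i in leaf_ids]
        ):
            full = dict(assign)
            full.update(dict(zip(leaf_ids, leaf_choice)))
            prob = 0.5  # root prior
            for n in tree.postorder():
                if n is tree.root:
                    continue
                t = n.length if n.length is not None else 1.0
                pc = model.p_change(t)
                same = full[id(n)] == full[id(parents[id(n)])]
                prob *= (1 - pc) if same else pc
            den += prob
            if full[id(node)] == 1:
                num += prob
    return num / den


def _random_bltree(labels, rng):
    tree = random_rooted_binary(labels, rng)
    for n in tree.postorder():
        if n is not tree.root:
            n.length = float(rng.uniform(0.05, 1.0))
    return tree


# ---------------------------------------------------------------------------
# Fitch
# ---------------------------------------------------------------------------


class TestFitch:
    def test_textbook_two_cherries(self):
        tree = parse_newick("((A,B),(C,D));")
        rec = fitch_ancestral(tree, {"A": 0, "B": 0, "C": 1, "D": 1})
        assert rec.parsimony_length == 1
        assert rec.state_sets[id(tree.root)] == frozenset({0, 1})

    def test_constant_character(self):
        tree = parse_newick("((A,B),(C,D));")
        rec = fitch_ancestral(tree, {l: 0 for l in "ABCD"})
        assert rec.parsimony_length == 0
        assert all(s == frozenset({0}) for s in rec.state_sets.values())

    def test_unknown_leaves_are_free(self):
        tree = parse_newick("((A,B),(C,D));")
        rec = fitch_ancestral(tree, {"A": 0, "B": "?", "C": 1, "D": "?"})
        assert rec.parsimony_length == 1

    def test_all_unknown_rejected(self):
        tree = parse_newick("((A,B),(C,D));")
        with pytest.raises(ValueError):
            fitch_ancestral(tree, {l: "?" for l in "ABCD"})

    def test_length_matches_brute_force(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 7))
            labels = [f"t{i}" for i in range(n)]
            tree = random_rooted_binary(labels, rng)
            character = {
                l: (int(rng.integers(0, 2)) if rng.random() > 0.2 else "?")
                for l in labels
            }
            if sum(1 for v in character.values() if v != "?") < 2:
                continue
            rec = fitch_ancestral(tree, character)
            assert rec.parsimony_length == brute_force_parsimony(
                tree, character
            )


# ---------------------------------------------------------------------------
# Mk
# ---------------------------------------------------------------------------


class TestMk:
    def test_two_leaf_closed_form_curve(self):
        """L(q) = (1 - e^{-4qt})/4 for a 0/1 cherry with branch lengths t."""
        tree = parse_newick("(A:0.3,B:0.3);")
        for q in np.linspace(0.05, 5.0, 25):
            expected = math.log((1 - math.exp(-4 * q * 0.3)) / 4)
            assert abs(mk_loglik(tree, {"A": 0, "B": 1}, q) - expected) < 1e-10

    def test_saturation_limit_root_marginal_half(self):
        tree = parse_newick("(A:0.3,B:0.3);")
        # huge fixed rate: compute marginals via a one-sided fit window
        rec = mk_fit_and_reconstruct(
            tree, {"A": 0, "B": 1}, q_bounds=(50.0, 60.0)
        )
        assert rec.marginals[id(tree.root)] == pytest.approx(0.5, abs=1e-6)

    def test_zero_rate_limit_constant_character(self):
        tree = parse_newick("((A:0.2,B:0.2):0.2,(C:0.2,D:0.2):0.2);")
        with pytest.warns(UserWarning):
            rec = mk_fit_and_reconstruct(
                tree, {l: 1 for l in "ABCD"}, q_bounds=(1e-6, 1e-4)
            )
        assert rec.at_bound
        assert rec.marginals[id(tree.root)] == pytest.approx(1.0, abs=1e-3)

    def test_marginals_match_exhaustive_summation(self, rng):
        for _ in range(30):
            n = int(rng.integers(3, 7))
            labels = [f"t{i}" for i in range(n)]
            tree = _random_bltree(labels, rng)
            character = {
                l: (int(rng.integers(0, 2)) if rng.random() > 0.15 else "?")
                for l in labels
            }
            if sum(1 for v in character.values() if v != "?") < 2:
                continue
            rec = mk_fit_and_reconstruct(tree, character)
            q = rec.model.q
            for node in tree.postorder():
                want = brute_force_mk_marginal(tree, character, q, node)
                assert rec.marginals[id(node)] == pytest.approx(
                    want, abs=1e-8
                )

    def test_state_swap_gives_complementary_marginals(self, rng):
        labels = [f"t{i}" for i in range(6)]
        tree = _random_bltree(labels, rng)
        character = {l: int(rng.integers(0, 2)) for l in labels}
        flipped = {l: 1 - v for l, v in character.items()}
        a = mk_fit_and_reconstruct(tree, character)
        b = mk_fit_and_reconstruct(tree, flipped)
        for node in tree.postorder():
            assert a.marginals[id(node)] == pytest.approx(
                1 - b.marginals[id(node)], abs=1e-6
            )

    def test_shared_rate_recovery_is_plausible(self, rng):
        """Joint fit over several characters lands within a factor of ~3 on
        a mid-sized tree (the full factor-2/200-tip experiment runs in the
        acceptance suite)."""
        from beephylo.simulate import simulate_ranges

        labels = [f"t{i}" for i in range(60)]
        tree = random_rooted_binary(labels, rng)
        for n in tree.postorder():
            if n is not tree.root:
                n.length = float(rng.exponential(0.12))
        q_true = 1.0
        df, _ = simulate_ranges(tree, q_true, seed=5)
        chars = [
            {t: int(df.at[t, a]) for t in labels} for a in df.columns
        ]
        model = mk_fit_shared_rate(tree, chars)
        assert 1 / 3 < model.q / q_true < 3


# ---------------------------------------------------------------------------
# Composite ranges
# ---------------------------------------------------------------------------


class TestCompositeRanges:
    def test_certain_single_area(self):
        marg = {"Africa": 1.0, "Oceania": 0.0, "North America": 0.0}
        out = composite_ranges(marg)
        assert out[0] == (("Africa",), pytest.approx(1.0))

    def test_two_area_ranking_by_product(self):
        out = composite_ranges({"A": 0.6, "B": 0.5, "C": 0.0})
        assert [r for r, _ in out] == [("A",), ("A", "B"), ("B",)]
        assert [s for _, s in out] == pytest.approx([0.3, 0.3, 0.2])

    def test_low_scores_suppressed(self):
        out = composite_ranges({"A": 0.25, "B": 0.2, "C": 0.2})
        assert all(s >= 0.10 for _, s in out)

    def test_max_range_size_respected(self):
        marg = {a: 0.9 for a in "ABCDEF"}
        out = composite_ranges(marg, top=5, min_score=0.0)
        assert all(len(r) <= 4 for r, _ in out)

    def test_clade_summary_and_monophyly_error(self, rng):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            recs = {
                "Africa": mk_fit_and_reconstruct(
                    tree, {"A": 1, "B": 1, "C": 0, "D": 0}
                ),
                "Oceania": mk_fit_and_reconstruct(
                    tree, {"A": 0, "B": 0, "C": 1, "D": 1}
                ),
            }
        df = summarize_clade_ranges(recs, {"left": ["A", "B"]})
        assert (df["clade"] == "left").all()
        assert df.iloc[0]["range"] == "Africa"
        with pytest.raises(ValueError, match="bad"):
            summarize_clade_ranges(recs, {"bad": ["A", "C"]})
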