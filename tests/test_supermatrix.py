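"""Assembly rules: selection, filters, trimming, concatenation, collapsing."""

import warnings

import numpy as np
import pandas as pd
import pytest

from beephylo.supermatrix import (
    GAP,
    MISSING,
    GeneAlignment,
    SequenceRecord,
    Supermatrix,
    TaxonomyTable,
    assemble,
    collapse_to_genera,
    concatenate,
    drop_single_gene_taxa,
    filter_genes_by_tribe_coverage,
    missing_fraction,
    select_longest_per_species,
    trim_gene_ends,
)


@pytest.fixture
def taxonomy():
    rows = []
    for i, (sp, genus, tribe, fam, ing) in enumerate(
        [
            ("sp1", "g1", "trA", "famX", 1),
            ("sp2", "g1", "trA", "famX", 1),
            ("sp3", "g2", "trB", "famX", 1),
            ("sp4", "g3", "trC", "famY", 1),
            ("wasp1", "wg", "wt", "wf", 0),
        ]
    ):
        rows.append(
            {"species": sp, "genus": genus, "tribe": tribe, "family": fam,
             "ingroup": ing}
        )
    return TaxonomyTable(pd.DataFrame(rows))


class TestSelectLongest:
    def test_longest_wins(self):
        recs = [
            SequenceRecord("x1", "sp1", "rho", "A" * 300),
            SequenceRecord("x2", "sp1", "rho", "A" * 450),
        ]
        out = select_longest_per_species(recs, seed=0)
        assert [r.accession for r in out] == ["x2"]

    def test_gaps_do_not_count_toward_length(self):
        recs = [
            SequenceRecord("x1", "sp1", "rho", "A" * 100),
            SequenceRecord("x2", "sp1", "rho", "A" * 90 + "-" * 60),
        ]
        out = select_longest_per_species(recs, seed=0)
        assert out[0].accession == "x1"

    def test_tie_broken_deterministically(self):
        recs = [
            SequenceRecord("x1", "sp1", "rho", "A" * 400),
            SequenceRecord("x2", "sp1", "rho", "C" * 400),
        ]
        picks = {select_longest_per_species(recs, seed=5)[0].accession
                 for _ in range(5)}
        assert len(picks) == 1

    def test_single_record_identity_and_empty(self):
        rec = SequenceRecord("x1", "sp1", "rho", "ACGT")
        assert select_longest_per_species([rec], seed=0) == [rec]
        assert select_longest_per_species([], seed=0) == []


class TestGeneFilter:
    def test_three_tribes_retained(self, taxonomy):
        genes = {"rho": {"sp1", "sp3", "sp4"}}  # tribes A, B, C
        assert filter_genes_by_tribe_coverage(genes, taxonomy) == {"rho"}

    def test_two_tribes_dropped(self, taxonomy):
        genes = {"rho": {"sp1", "sp3"}}
        assert filter_genes_by_tribe_coverage(genes, taxonomy) == set()

    def test_species_not_tribes_insufficient(self, taxonomy):
        genes = {"rho": {"sp1", "sp2"}}  # two species, one tribe
        assert filter_genes_by_tribe_coverage(genes, taxonomy) == set()

    def test_outgroup_coverage_does_not_count(self, taxonomy):
        genes = {"rho": {"sp1", "sp3", "wasp1"}}  # 2 ingroup tribes + wasp
        assert filter_genes_by_tribe_coverage(genes, taxonomy) == set()

    def test_unknown_species_reported(self, taxonomy):
        with pytest.raises(KeyError, match="mystery"):
            filter_genes_by_tribe_coverage({"rho": {"mystery"}}, taxonomy)


class TestDropSingleGeneTaxa:
    def test_thresholds(self):
        cov = {"t1": {"ef1af2"}, "t2": {"ef1af2", "rho"}}
        assert drop_single_gene_taxa(cov) == {"t2"}

    def test_all_single_gene_warns_empty(self):
        with pytest.warns(UserWarning):
            assert drop_single_gene_taxa({"t1": {"g"}, "t2": {"g"}}) == set()


class TestTrim:
    @staticmethod
    def _alignment_with_coverage(cov):
        """Build an alignment whose per-column residue counts equal cov."""
        n_taxa = max(cov)
        seqs = {}
        for t in range(n_taxa):
            row = "".join("A" if cov[j] > t else "-" for j in range(len(cov)))
            seqs[f"t{t}"] = row
        return GeneAlignment("g", seqs)

    def test_sparse_ends_removed(self):
        aln = self._alignment_with_coverage([1, 2, 4, 5, 2, 1])
        out = trim_gene_ends(aln, min_taxa=3)
        assert out.length == 2
        assert out.sequences["t0"] == "AA"

    def test_interior_sparseness_kept(self):
        aln = self._alignment_with_coverage([3, 1, 3])
        assert trim_gene_ends(aln, min_taxa=3).length == 3

    def test_dense_alignment_unchanged(self):
        aln = self._alignment_with_coverage([4, 4, 4])
        assert trim_gene_ends(aln, min_taxa=3).sequences == aln.sequences

    def test_all_sparse_warns_empty(self):
        aln = self._alignment_with_coverage([1, 1])
        with pytest.warns(UserWarning):
            assert trim_gene_ends(aln, min_taxa=3).length == 0

    def test_retained_columns_contiguous(self, rng):
        for _ in range(30):
            cov = list(rng.integers(0, 5, size=12))
            if max(cov) == 0:
                continue
            aln = self._alignment_with_coverage(cov)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out = trim_gene_ends(aln, min_taxa=3)
            dense = [j for j, c in enumerate(cov) if c >= 3]
            expected = (dense[-1] - dense[0] + 1) if dense else 0
            assert out.length == expected


class TestConcatenate:
    def test_lengths_and_partitions(self):
        a = GeneAlignment("g1", {"t1": "A" * 10, "t2": "C" * 10})
        b = GeneAlignment("g2", {"t1": "G" * 20})
        sm = concatenate([a, b])
        assert sm.length == 30
        assert sm.partitions == [("g1", 0, 10), ("g2", 10, 30)]

    def test_absent_block_filled_with_missing(self):
        a = GeneAlignment("g1", {"t1": "A" * 10, "t2": "C" * 10})
        b = GeneAlignment("g2", {"t1": "G" * 20})
        sm = concatenate([a, b])
        assert sm.block("t2", "g2") == MISSING * 20

    def test_single_gene_identity(self):
        a = GeneAlignment("g1", {"t1": "ACGT", "t2": "TGCA"})
        sm = concatenate([a])
        assert sm.rows == a.sequences

    def test_duplicate_gene_names_rejected(self):
        a = GeneAlignment("g1", {"t1": "A"})
        with pytest.raises(ValueError):
            concatenate([a, a])

    def test_coverage_matches_blocks(self):
        a = GeneAlignment("g1", {"t1": "AAAA", "t2": "CCCC"})
        b = GeneAlignment("g2", {"t1": "GGGG", "t3": "TTTT"})
        sm = concatenate([a, b])
        cov = sm.coverage()
        assert cov.partitions[0] == frozenset({"t1", "t2"})
        assert cov.partitions[1] == frozenset({"t1", "t3"})


class TestMissingFraction:
    def test_half_empty(self):
        a = GeneAlignment("g1", {"t1": "AAAA", "t2": "CCCC"})
        b = GeneAlignment("g2", {"t1": "GGGG", "t3": "TTTT"})
        sm = concatenate([a, b], taxa={"t1", "t2", "t3", "t4"})
        cell, char = missing_fraction(sm)
        # t1 covers both genes, t2/t3 one each, t4 none: 4 of 8 cells empty
        assert cell == pytest.approx(4 / 8)
        assert char == pytest.approx(4 / 8)

    def test_full_coverage_zero(self):
        a = GeneAlignment("g1", {"t1": "AAAA", "t2": "CCCC"})
        assert missing_fraction(concatenate([a])) == (0.0, 0.0)

    def test_character_level_at_least_cell_level(self, rng):
        """Within-gene gaps never lower the cell-level statistic; the
        character-level '?' fraction equals the cell-level fraction when
        blocks are all-or-nothing."""
        genes = []
        taxa = [f"t{i}" for i in range(6)]
        for g in range(4):
            members = rng.choice(taxa, size=int(rng.integers(2, 6)),
                                 replace=False)
            genes.append(
                GeneAlignment(f"g{g}", {t: "ACGT" * 3 for t in members})
            )
        sm = concatenate(genes, taxa=taxa)
        cell, char = missing_fraction(sm)
        assert char == pytest.approx(cell)


class TestCollapseToGenera:
    def test_chimeric_genus_forced(self, taxonomy):
        # sp1 has only geneA, sp2 (same genus) only geneB
        alns = {
            "geneA": GeneAlignment("geneA", {"sp1": "AAAA"}),
            "geneB": GeneAlignment("geneB", {"sp2": "CCCC"}),
        }
        recs = [
            SequenceRecord("r1", "sp1", "geneA", "AAAA"),
            SequenceRecord("r2", "sp2", "geneB", "CCCC"),
        ]
        (sm,) = collapse_to_genera(recs, taxonomy, alns, n_replicates=1, seed=0)
        assert sm.taxa == {"g1"}
        assert sm.block("g1", "geneA") == "AAAA"
        assert sm.block("g1", "geneB") == "CCCC"

    def test_single_gene_genus_removed(self, taxonomy):
        alns = {"geneA": GeneAlignment("geneA", {"sp3": "AAAA"})}
        recs = [SequenceRecord("r1", "sp3", "geneA", "AAAA")]
        (sm,) = collapse_to_genera(recs, taxonomy, alns, n_replicates=1, seed=0)
        assert sm.taxa == set()

    def test_replicates_deterministic(self, taxonomy):
        alns = {
            "geneA": GeneAlignment("geneA", {"sp1": "AAAA", "sp2": "TTTT"}),
            "geneB": GeneAlignment("geneB", {"sp1": "CCCC", "sp2": "GGGG"}),
        }
        recs = [
            SequenceRecord("r1", "sp1", "geneA", "AAAA"),
            SequenceRecord("r2", "sp2", "geneA", "TTTT"),
            SequenceRecord("r3", "sp1", "geneB", "CCCC"),
            SequenceRecord("r4", "sp2", "geneB", "GGGG"),
        ]
        reps1 = collapse_to_genera(recs, taxonomy, alns, n_replicates=10, seed=4)
        reps2 = collapse_to_genera(recs, taxonomy, alns, n_replicates=10, seed=4)
        assert [r.rows for r in reps1] == [r.rows for r in reps2]


class TestAssemblePipeline:
    def test_stage_report_and_idempotent_restages(self, taxonomy):
        genes = [
            GeneAlignment(
                "rho",
                {"sp1": "ACGTACGT", "sp3": "ACGTACGA", "sp4": "ACGAACGT"},
            ),
            GeneAlignment(
                "wg",
                {"sp1": "TTTTGGGG", "sp3": "TTTAGGGG", "sp4": "TTTTGGGC"},
            ),
        ]
        sm, report = assemble(genes, taxonomy, trim_min_taxa=3)
        assert report["taxa"] == 3 and report["genes"] == 2
        assert sm.length == 16
        # re-running trimming on its own output is a no-op
        for gene, start, end in sm.partitions:
            aln = GeneAlignment(
                gene, {t: sm.rows[t][start:end] for t in sm.rows}
            )
            assert trim_gene_ends(aln, 3).sequences == aln.sequences
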