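"""Supermatrix assembly from heterogeneous per-gene sequence sets.

The assembly rules mirror common database-mining practice for large
multi-gene matrices: keep the longest sequence per (species, gene), retain
only genes sampled across enough ingroup tribes, drop taxa represented by a
single gene (so every partition overlaps another through shared taxa), trim
sparse alignment ends, and concatenate with explicit partition coordinates.
Genus-level "chimeric" replicates draw one sequence per gene per genus at
random, which shrinks the empty-cell fraction at the cost of combining
sequences from different congeneric species in one row.

Characters: ``?`` marks a missing taxon x gene block, ``-`` an alignment
gap.  Both count as absent for end-trimming coverage, but only wholly
``?``-filled blocks count as empty cells for the matrix-level missing-data
statistic.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .decisiveness import CoveragePattern

__all__ = [
    "SequenceRecord",
    "TaxonomyTable",
    "GeneAlignment",
    "Supermatrix",
    "select_longest_per_species",
    "filter_genes_by_tribe_coverage",
    "drop_single_gene_taxa",
    "trim_gene_ends",
    "concatenate",
    "missing_fraction",
    "collapse_to_genera",
    "assemble",
    "read_gene_fasta",
    "read_taxonomy",
    "MISSING",
    "GAP",
]

MISSING = "?"
GAP = "-"


@dataclass(frozen=True)
class SequenceRecord:
    accession: str
    species: str
    gene: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty sequence")
        if not self.gene:
            raise ValueError("empty gene name")

    @property
    def ungapped_length(self) -> int:
        return sum(1 for c in self.sequence if c not in (GAP, MISSING))


class TaxonomyTable:
    """species -> (genus, tribe, family, ingroup flag)."""

    def __init__(self, df: pd.DataFrame):
        required = {"species", "genus", "tribe", "family", "ingroup"}
        if not required <= set(df.columns):
            raise ValueError(f"taxonomy table needs columns {sorted(required)}")
        if df["species"].duplicated().any():
            dupes = df.loc[df["species"].duplicated(), "species"].tolist()
            raise ValueError(f"duplicate species in taxonomy: {dupes}")
        for col in ("species", "genus", "tribe", "family"):
            if df[col].astype(str).str.len().eq(0).any() or df[col].isna().any():
                raise ValueError(f"empty values in taxonomy column {col!r}")
        self.df = df.set_index("species", drop=False)

    def __contains__(self, species: str) -> bool:
        return species in self.df.index

    def tribe(self, species: str) -> str:
        return self._get(species, "tribe")

    def genus(self, species: str) -> str:
        return self._get(species, "genus")

    def is_ingroup(self, species: str) -> bool:
        return bool(self._get(species, "ingroup"))

    def _get(self, species: str, col: str):
        try:
            return self.df.at[species, col]
        except KeyError:
            raise KeyError(f"species {species!r} missing from taxonomy") from None

    def species(self) -> list[str]:
        return list(self.df.index)

    @classmethod
    def read_tsv(cls, path) -> "TaxonomyTable":
        return cls(pd.read_csv(path, sep="\t"))

    def write_tsv(self, path) -> None:
        self.df.reset_index(drop=True).to_csv(path, sep="\t", index=False)


@dataclass
class GeneAlignment:
    gene: str
    sequences: dict[str, str]

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"unequal sequence lengths in gene {self.gene}: {lengths}")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(self.sequences)


@dataclass
class Supermatrix:
    rows: dict[str, str]
    partitions: list[tuple[str, int, int]]  # (gene, start, end) half-open

    def __post_init__(self):
        total = self.length
        pos = 0
        for gene, start, end in self.partitions:
            if start != pos or end <= start:
                raise ValueError("partition intervals must tile [0, length)")
            pos = end
        if self.partitions and pos != total:
            raise ValueError("partitions do not cover the matrix")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(self.rows)

    def block(self, taxon: str, gene: str) -> str:
        for g, start, end in self.partitions:
            if g == gene:
                return self.rows[taxon][start:end]
        raise KeyError(gene)

    def gene_taxa(self, gene: str) -> frozenset[str]:
        for g, start, end in self.partitions:
            if g == gene:
                return frozenset(
                    t for t, row in self.rows.items()
                    if any(c != MISSING for c in row[start:end])
                )
        raise KeyError(gene)

    def coverage(self) -> CoveragePattern:
        return CoveragePattern.from_sets(
            [self.gene_taxa(g) for g, _, _ in self.partitions],
            universe=self.taxa,
        )

    # -- serialization ----------------------------------------------------

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for taxon in sorted(self.rows):
                fh.write(f">{taxon}\n{self.rows[taxon]}\n")

    def write_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.rows)} {self.length}\n")
            for taxon in sorted(self.rows):
                fh.write(f"{taxon}  {self.rows[taxon]}\n")

    def write_partitions(self, path) -> None:
        """RAxML-style partition file, 1-based inclusive coordinates."""
        with open(path, "w") as fh:
            for gene, start, end in self.partitions:
                fh.write(f"DNA, {gene} = {start + 1}-{end}\n")

    def write_coverage_csv(self, path) -> None:
        taxa = sorted(self.rows)
        data = {
            gene: [int(t in self.gene_taxa(gene)) for t in taxa]
            for gene, _, _ in self.partitions
        }
        pd.DataFrame(data, index=pd.Index(taxa, name="taxon")).to_csv(path)


# ---------------------------------------------------------------------------
# Assembly operations
# ---------------------------------------------------------------------------


def select_longest_per_species(
    records: Sequence[SequenceRecord], seed: int | np.random.Generator = 0
) -> list[SequenceRecord]:
    """One record per (species, gene): longest by ungapped length, ties
    broken uniformly at random (deterministic given seed)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    groups: dict[tuple[str, str], list[SequenceRecord]] = {}
    for rec in records:
        groups.setdefault((rec.species, rec.gene), []).append(rec)
    out: list[SequenceRecord] = []
    for key in sorted(groups):
        cands = groups[key]
        best = max(r.ungapped_length for r in cands)
        ties = sorted(
            (r for r in cands if r.ungapped_length == best), key=lambda r: r.accession
        )
        out.append(ties[int(rng.integers(len(ties)))])
    return out


def filter_genes_by_tribe_coverage(
    genes: Mapping[str, Iterable[str]],
    taxonomy: TaxonomyTable,
    min_tribes: int = 3,
) -> set[str]:
    """Genes whose *ingroup* species span at least ``min_tribes`` tribes."""
    kept: set[str] = set()
    for gene, species in genes.items():
        tribes = set()
        for sp in species:
            if sp not in taxonomy:
                raise KeyError(f"species {sp!r} missing from taxonomy")
            if taxonomy.is_ingroup(sp):
                tribes.add(taxonomy.tribe(sp))
        if len(tribes) >= min_tribes:
            kept.add(gene)
    return kept


def drop_single_gene_taxa(coverage: Mapping[str, Iterable[str]]) -> set[str]:
    """Taxa sampled for >= 2 genes.

    Removing a taxon never changes another taxon's gene count, so a single
    pass reaches the fixed point; this is asserted.
    """
    counts = {t: len(set(genes)) for t, genes in coverage.items()}
    kept = {t for t, c in counts.items() if c >= 2}
    if not kept:
        warnings.warn("all taxa are single-gene; empty matrix")
    # fixed-point guard: counts are unaffected by removal
    assert all(counts[t] >= 2 for t in kept)
    return kept


def _column_coverage(aln: GeneAlignment) -> np.ndarray:
    if not aln.sequences:
        return np.zeros(0, dtype=int)
    arr = np.array([list(s) for s in aln.sequences.values()])
    return ((arr != GAP) & (arr != MISSING)).sum(axis=0)


def trim_gene_ends(aln: GeneAlignment, min_taxa: int = 3) -> GeneAlignment:
    """Strip leading/trailing columns with < ``min_taxa`` residues.

    Interior columns are never removed, however sparse: the retained
    columns always form one contiguous interval.
    """
    cov = _column_coverage(aln)
    dense = np.flatnonzero(cov >= min_taxa)
    if dense.size == 0:
        warnings.warn(f"gene {aln.gene}: no column reaches {min_taxa} taxa; empty")
        return GeneAlignment(aln.gene, {t: "" for t in aln.sequences})
    lo, hi = int(dense[0]), int(dense[-1]) + 1
    return GeneAlignment(
        aln.gene, {t: s[lo:hi] for t, s in aln.sequences.items()}
    )


def concatenate(
    alignments: Sequence[GeneAlignment], taxa: Iterable[str] | None = None
) -> Supermatrix:
    """Concatenate gene alignments; absent taxon x gene blocks are filled
    with the missing character ``?``."""
    names = [a.gene for a in alignments]
    if len(set(names)) != len(names):
        raise ValueError("duplicate gene names")
    if taxa is None:
        all_taxa: set[str] = set()
        for a in alignments:
            all_taxa |= a.taxa
    else:
        all_taxa = set(taxa)
    rows = {t: [] for t in all_taxa}
    partitions: list[tuple[str, int, int]] = []
    pos = 0
    for a in alignments:
        for t in all_taxa:
            rows[t].append(a.sequences.get(t, MISSING * a.length))
        partitions.append((a.gene, pos, pos + a.length))
        pos += a.length
    return Supermatrix({t: "".join(parts) for t, parts in rows.items()}, partitions)


def missing_fraction(sm: Supermatrix) -> tuple[float, float]:
    """(cell_level, character_level) missing-data fractions.

    cell_level: fraction of taxon x gene blocks that are entirely missing
    (the "empty cells" statistic).  character_level: fraction of matrix
    characters that are ``?``.
    """
    n_taxa = len(sm.rows)
    n_genes = len(sm.partitions)
    if n_taxa == 0 or n_genes == 0 or sm.length == 0:
        return 0.0, 0.0
    empty_cells = 0
    missing_chars = 0
    for row in sm.rows.values():
        missing_chars += row.count(MISSING)
    for gene, start, end in sm.partitions:
        for row in sm.rows.values():
            block = row[start:end]
            if all(c == MISSING for c in block):
                empty_cells += 1
    return empty_cells / (n_taxa * n_genes), missing_chars / (n_taxa * sm.length)


def collapse_to_genera(
    records: Sequence[SequenceRecord],
    taxonomy: TaxonomyTable,
    alignments: Mapping[str, GeneAlignment],
    n_replicates: int = 10,
    seed: int | np.random.Generator = 0,
) -> list[Supermatrix]:
    """Genus-level chimeric replicates.

    Per replicate, one uniformly chosen sequence per (genus, gene); genera
    with fewer than two genes are dropped.  ``alignments`` supplies the
    aligned sequences keyed by gene then species (records carry which
    (species, gene) combinations exist after deduplication).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    by_genus_gene: dict[tuple[str, str], list[str]] = {}
    for rec in records:
        genus = taxonomy.genus(rec.species)
        by_genus_gene.setdefault((genus, rec.gene), []).append(rec.species)
    out: list[Supermatrix] = []
    genes = sorted({g for _, g in by_genus_gene})
    for _ in range(n_replicates):
        chosen: dict[str, dict[str, str]] = {}  # gene -> genus -> sequence
        genus_genes: dict[str, set[str]] = {}
        for (genus, gene), species_list in sorted(by_genus_gene.items()):
            sp = sorted(species_list)[int(rng.integers(len(species_list)))]
            aln = alignments[gene]
            if sp not in aln.sequences:
                continue
            chosen.setdefault(gene, {})[genus] = aln.sequences[sp]
            genus_genes.setdefault(genus, set()).add(gene)
        keep = {g for g, gs in genus_genes.items() if len(gs) >= 2}
        gene_alns = [
            GeneAlignment(
                gene,
                {g: s for g, s in chosen.get(gene, {}).items() if g in keep},
            )
            for gene in genes
        ]
        out.append(concatenate([a for a in gene_alns if a.sequences], taxa=keep))
    return out


# ---------------------------------------------------------------------------
# File I/O and the staged pipeline
# ---------------------------------------------------------------------------


def read_gene_fasta(path, gene: str | None = None) -> GeneAlignment:
    path = Path(path)
    name = gene or path.stem
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    return GeneAlignment(name, seqs)


def read_taxonomy(path) -> TaxonomyTable:
    return TaxonomyTable.read_tsv(path)


def assemble(
    alignments: Sequence[GeneAlignment],
    taxonomy: TaxonomyTable,
    min_tribes: int = 3,
    min_genes: int = 2,
    trim_min_taxa: int = 3,
) -> tuple[Supermatrix, dict]:
    """Staged assembly: gene filter -> drop single-gene taxa -> trim ->
    concatenate.  Returns the supermatrix and a JSON-able run report."""
    report: dict = {"stages": []}
    gene_species = {a.gene: set(a.sequences) for a in alignments}
    report["stages"].append(
        {"stage": "input", "genes": len(alignments),
         "taxa": len(set().union(*gene_species.values())) if gene_species else 0}
    )
    kept_genes = filter_genes_by_tribe_coverage(gene_species, taxonomy, min_tribes)
    alns = [a for a in alignments if a.gene in kept_genes]
    report["stages"].append({"stage": "gene_filter", "genes": len(alns)})

    taxon_genes: dict[str, set[str]] = {}
    for a in alns:
        for t in a.taxa:
            taxon_genes.setdefault(t, set()).add(a.gene)
    if min_genes >= 2:
        kept_taxa = drop_single_gene_taxa(taxon_genes)
    else:
        kept_taxa = set(taxon_genes)
    alns = [
        GeneAlignment(a.gene, {t: s for t, s in a.sequences.items() if t in kept_taxa})
        for a in alns
    ]
    alns = [a for a in alns if a.sequences]
    report["stages"].append({"stage": "taxon_filter", "taxa": len(kept_taxa)})

    pre_len = sum(a.length for a in alns)
    alns = [trim_gene_ends(a, trim_min_taxa) for a in alns]
    alns = [a for a in alns if a.length > 0]
    post_len = sum(a.length for a in alns)
    report["stages"].append(
        {"stage": "trim", "sites_before": pre_len, "sites_after": post_len}
    )

    sm = concatenate(alns, taxa=kept_taxa)
    cell, char = missing_fraction(sm)
    report["missing_cell_fraction"] = cell
    report["missing_character_fraction"] = char
    report["taxa"] = len(sm.rows)
    report["genes"] = len(sm.partitions)
    report["sites"] = sm.length

    # every partition should share >= 1 taxon with some other partition
    cov = [sm.gene_taxa(g) for g, _, _ in sm.partitions]
    for i, yi in enumerate(cov):
        if len(cov) > 1 and not any(
            yi & yj for j, yj in enumerate(cov) if j != i
        ):
            warnings.warn(
                f"partition {sm.partitions[i][0]} shares no taxon with any other"
            )
    return sm, report
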