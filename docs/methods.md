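# Methods

This note records the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
experiments do and do not establish.

## Tree model

Trees are rooted, leaf-labeled, possibly multifurcating; child order is
never semantic.  Branch-length absence is distinct from zero.  Unrooted
Newick inputs must be rooted (the supermatrix workflow always carries
outgroup taxa, and the synthetic generator guarantees an anchor taxon
present in every partition), because the decisiveness/terrace machinery is
implemented in its rooted-triplet form.  Support values arriving as
internal-node labels are auto-detected; values above 1 are read as
percentages and normalized to [0, 1].

Uniform random rooted binary topologies are generated by sequential leaf
attachment to a uniformly chosen edge (root edge included): each topology
on k+1 leaves arises from exactly one (topology, edge) pair on k leaves,
so the process is uniform over the (2n−3)!! topologies.  Uniformity is
verified by a chi-square test against the 15 four-leaf topologies.

## Terraces, decisiveness, BUILD

A binary rooted tree is equivalent to its set of rooted triplets, and for
a binary T, another binary tree S satisfies S|Y = T|Y exactly when S
displays every triplet of T|Y.  The terrace of T under coverage Y₁..Y_k is
therefore the set of binary trees on the full taxon set displaying
R = ∪ᵢ triplets(T|Yᵢ).

**Counting.**  For a taxon subset S, let G(S) be the graph on S with an
edge {a,b} for every triplet ab|c with a, b, c ∈ S.  Any displaying tree's
root must keep each connected component of G(S) on one side, and
conversely any bipartition of components can be a root split, so

    N(S) = Σ over unordered bipartitions {A, B} of the components
           N(∪A) · N(∪B),        N(S) = 1 for |S| ≤ 2.

The recursion must re-derive components inside each part (triplets lose
their outgroup witness when the witness falls on the other side) — a
simpler scheme that multiplies (2m−3)!! over m components and recurses
into each component undercounts precisely in that situation.  Two
shortcuts keep the exact recursion fast: memoization on the taxon subset,
and the closed form (2|S|−3)!! when no triplet lies wholly inside S.
Counts are exact unbounded integers; nothing passes through floating
point.  The recursion is validated against exhaustive enumeration (all
topologies generated, restrictions compared) on hundreds of random
instances up to 7 taxa.

**Decisiveness.**  Decisive-for-T is *defined* as terrace size 1.  The
implementation uses an equivalent per-clade check derived from the
recursion: the count is 1 iff at every internal node of T the BUILD graph
of that node's leaf set has exactly the two child clades as components
(cross-child edges are impossible — the outgroup witness would have to
leave the clade).  Each partition contributes, on clade set S, a clique on
each child-group of lca(Yᵢ ∩ S), so connectivity is evaluated without
materializing triplets.  The shortcut is randomized-tested against the
normative terrace-size definition before anything relies on it.  Partial
tree-wise decisiveness is the decisive fraction over uniform random trees
(default 1000), with the binomial Monte-Carlo standard error; paired seeds
make coverage-growth comparisons exactly monotone per tree.

**BUILD.**  The Aho construction on the triplet set, recursing on
components with a polytomy per level, with an explicit incompatibility
error naming a directly contradictory triplet pair when one exists.  Note
that the BUILD tree is *not* in general refined by every terrace member: a
polytomy over components still displays cherry-versus-outside triplets
that individual members can contradict (e.g. coverage {{a,b,c}} with
T = (((a,b),c),d): BUILD = ((a,b),c,d) displays ab|d, yet (((a,d),b),c) is
on the terrace).  The guaranteed property — BUILD displays every
coverage-induced triplet — is what the tests assert.

## Supermatrix assembly

Pipeline order is fixed: select longest per (species, gene) → gene filter
by ingroup tribe span (≥ 3) → drop single-gene taxa → end-trim → 
concatenate.  Choices:

* Ties for longest (by ungapped length) break uniformly at random under
  the run seed.
* The tribe filter counts tribes of *ingroup* records only.
* Single-gene-taxon removal is one pass; removing a taxon cannot change
  another taxon's gene count, and an assertion guards that fixed point.
* `?` is the missing character, `-` an alignment gap.  Both count as
  "no residue" for trimming coverage; only all-`?` blocks count as empty
  cells.  The missing fraction is reported both cell-level (empty blocks /
  taxon × gene cells) and character-level (`?` characters / matrix size),
  since published summaries rarely say which accounting they used.
* Trimming removes only leading/trailing columns with fewer than three
  residues; retained columns always form one contiguous interval.
* Genus-level replicates sample uniformly among a genus's available
  sequences per gene (not longest-first), so genus rows may be chimeric;
  genera with fewer than two genes are dropped.

## Taxon instability and AIC

The instability of taxon t over a tree pool is
I(t) = Σ_{i<j} Σ_{x≠t} |dᵢ(t,x) − dⱼ(t,x)| / (dᵢ(t,x) + dⱼ(t,x))²,
with d the nodal (edge-count) distance.  The squared denominator
down-weights distance disagreements far from t, so taxa hopping between
nearby positions dominate.  This weighted form is frozen as the package's
definition; it is validated behaviorally (planted rogues rank first in
synthetic pools).  Pruning removes the ceil(fraction × N) top scorers,
ties broken by label — ceiling, not rounding, is what reproduces 14 of
1376 and 4 of 376 at the 1% level.  AIC = 2k − 2lnL with ΔAIC against the
best scheme.

## Topology tests

Inputs are tree × site log-likelihood matrices (PUZZLE/CONSEL `.sitelh`
dialect or labeled CSV).  One site-index multiset per RELL replicate is
shared by all trees (multinomial counts, chunked so memory stays flat at
10⁴ replicates × 10⁴ sites).

* **WSH**: observed statistic per tree i is max over j of
  (L_j − L_i)/σ̂ᵢⱼ with σ̂²ᵢⱼ = n/(n−1) Σ_s (δ_s − δ̄)² over centered
  per-site differences (the variance of the *total* difference); the null
  uses per-tree-centered RELL totals with the same standardization.
  Identical rows (zero variance) are skipped as comparators and tie at
  p = 1.  The unweighted SH variant is available via `weighted=False`.
* **AU**: bootstrap proportions BP(r) at scales r = 0.5..1.4 (step 0.1,
  CONSEL's convention; resample size round(r·n)), replicates tied for the
  top split equally.  Φ⁻¹(1−BP) is fitted as d√r + c/√r by weighted least
  squares with binomial weights n_rep φ(z)²/(BP(1−BP)); p = 1 − Φ(d−c).
  Trees with fewer than two scales off the boundary get the boundary
  p (0 or 1) with a `degenerate` flag rather than an error — a decisively
  losing tree routinely has BP = 0 at nine scales and one stray replicate
  at the tenth.
* **BIC posterior**: ppᵢ ∝ exp(−BICᵢ/2), BICᵢ = kᵢ ln n − 2Lᵢ, computed
  with a max-shift; equal k reduces to normalized likelihood weights.
* **Bonferroni**: reject at p < α/m; adjusted p = min(1, p·m).

**Calibration and a known limitation.**  On a *smooth-boundary* null (two
tied trees, the rest strongly inferior) the AU test is calibrated: ~0.05
rejection at α = 0.05 with approximately uniform p.  At an *exact
multi-way tie* (five trees with identical means) the tested point is a
cone vertex of the region "tree i is best"; the d√r + c/√r model is
derived for smooth boundaries, and at such vertices the AU test rejects at
roughly twice the nominal level (measured ≈ 0.10–0.12 at α = 0.05,
insensitive to replicate count and site count).  This is a property of the
AU construction, not of this implementation; the weighted SH test remains
conservative (≤ 0.07) in the same configuration.  Both rates are
recomputed by `scripts/acceptance.py`.

## Ancestral ranges

Each area is an independent binary character (presence/absence), matching
the per-area treatment of range data in comparative packages.  Fitch:
bottom-up state sets with `?` = {0,1}, length = number of empty
intersections; the top-down pass intersects each node's set with its
parent's final set when non-empty (accelerated-transformation-flavored tie
handling).  Mk: symmetric two-state model with stationary (½, ½) and
change probability (1−e^{−2qt})/2; the rate is fitted on log-q by bounded
scalar minimization of the pruning likelihood (bounds 10⁻⁶–10³,
boundary hits flagged); marginals combine downward and upward partial
likelihoods (rerooting).  Missing branch lengths fall back to unit lengths
with a loud warning.  Outgroups with unknown ("null") distributions enter
as `?` leaves contributing (1, 1).

Composite ranges are scored as the product of per-area marginals over
subsets of at most four areas (independence is a reporting convention,
consistent with the per-area model; four matches the usual cap on areas
per taxon), top three retained, scores below 0.10 suppressed, ties broken
smaller-range-first then alphabetically.  Fitch lengths and Mk marginals
are verified against brute-force enumeration over all internal state
assignments on trees of up to six leaves; a shared-rate fit across the
seven characters recovers a known rate within a factor of two on 200-tip
trees in ≥ 90% of replicates.

## Synthetic data

The generators target the *shapes* that matter to the pipeline, not
sequence realism:

* Taxonomy/true tree: balanced ranks (families → tribes → genera →
  species), every rank monophyletic by construction, an outgroup clade
  sister to the ingroup, exponential branch lengths (default mean 0.05).
  The study-shaped default is 7 families × 3 tribes × 2 genera × 2
  species + 4 outgroups (88 taxa), 20 genes, 150 sites per gene.
* Coverage: Bernoulli per (taxon, gene) with long-tailed (lognormal,
  σ = 0.9) per-gene rates — mined matrices have a few densely sampled
  genes and many sparse ones, and those dense genes are what carry
  decisiveness.  Rows are redrawn until each taxon has ≥ 2 genes; because
  that conditioning inflates presence, rates are calibrated against the
  exact truncated Poisson-binomial expectation so the realized global
  empty fraction matches the target (85% by default) in expectation.  The
  anchor outgroup taxon appears in every gene.
* Sequences: single-rate symmetric (Jukes–Cantor-type) model.  The
  pipeline never computes tree likelihoods from sequences, so model
  realism beyond coverage shape buys nothing; optional ragged gap ends
  exercise the trimming rule.
* Site log-likelihoods: ℓᵢⱼ = baseⱼ + offsetᵢ + εᵢⱼ with Gaussian noise —
  the standard surrogate for calibrating resampling tests; zero offsets
  give the exchangeable null.
* Ranges: seven characters evolved under Mk(q) from recorded root states;
  all-absent ingroup leaves are redrawn along their own terminal branch
  (ingroup taxa must occupy at least one area).
* Bootstrap pools: the true tree with planted rogue taxa re-attached to a
  uniform random edge per replicate — variability concentrated on the
  rogues, which is the signature the instability score detects.

One master seed drives everything; child seeds are spawned per stage
(`numpy.random.SeedSequence`), so stages are individually reproducible.

What passing these experiments shows: the algorithms agree with their
definitions (enumeration, brute-force state sums), the statistics behave
as their theory predicts on data satisfying the model assumptions, and
the pipeline is deterministic.  What they do not show: robustness to
alignment error, paralogy, taxonomic misidentification, rate
heterogeneity across sites or lineages, or non-independence between area
characters — real mined data violate all of these.

## Problem sizes

Default experiment sizes (chosen as the package's own validation budget):
terrace oracle on 200 random instances up to 7 taxa; null calibration on
1000 matrices of 100 sites × 5 trees with 1000 RELL replicates per scale
(the library default for analyses remains 10,000); Fitch oracle on 500
instances; Mk rate recovery on 100 replicates of 200-tip trees; end-to-end
runs at 88 taxa × 20 genes.  All complete in a few minutes on one CPU.
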