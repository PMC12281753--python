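# Methods

This note documents the models and procedures `nodsource` implements, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions that matter for exact
reproducibility.

## Study design and data model

The package targets a nested compartment design: four fertilization
treatments (P0, BC, BCplus, TSP) × three field blocks; per plot one bulk-soil
and one rhizosphere sample, and three replicate extractions each for roots
and nodules. Count tables are non-negative integer ASV × sample matrices;
metadata keys every sample to (compartment, treatment, block, replicate) with
at most three replicates per root/nodule plot. Taxonomy stores a seven-rank
lineage per ASV with an explicit `"unassigned"` sentinel — never an empty
string — so family-level aggregation is deterministic.

## Preprocessing

**Organelle removal.** ASVs whose lineage contains "chloroplast" or
"mitochondri" (case-insensitive, any rank) are dropped; removal is
read-conserving (input totals = output + removed) and logged per sample.
ASVs without taxonomy are retained and listed.

**Replicate-presence filter.** Within each root/nodule plot group, an ASV's
counts are zeroed unless it has count > 0 in at least `min_reps` (default 2)
of the group's replicates. Zeroing is per plot — an ASV can survive in one
plot and not another — and globally all-zero rows are then dropped. The
filter is idempotent and monotone in `min_reps`. Presence is evaluated on
organelle-filtered **raw** counts, before normalization: presence on
normalized values would depend on the scaling, and the filter's purpose is
robustness of detection, not abundance. A flag allows presence to be taken
on normalized values instead for sensitivity analyses.

**CSS normalization.** For sample *j*, the scaling factor is
`s_j = Σ { c_ij : c_ij ≤ q_j(l) }` where `q_j(l)` is the quantile (linear
interpolation) of the sample's *positive* counts at level `l` (default 0.5),
and normalized values are `c_ij / s_j × N` with output scale `N = 1000`.
Counts equal to the quantile are **included** in the cumulative sum; stated
explicitly because conventions differ. The quantile level is fixed rather
than searched adaptively — the adaptive search adds a data-dependent
degree of freedom that is hard to reproduce exactly, and the fixed median
variant is the common default. Zeros map to zeros, within-sample rank order
is preserved, and `s_j` is scale-equivariant (multiplying a sample by a
constant leaves its normalized vector unchanged); these are tested against a
brute-force sort/cumsum oracle at 1e-9.

## Community structure

**Bray–Curtis** uses `d_ij = Σ|x−y| / Σ(x+y)` (scipy); an all-zero sample
pair is assigned distance 0 with a warning rather than NaN.

**NMDS** minimizes Kruskal stress-1 with monotone (isotonic) regression on
the dissimilarities via SMACOF (scikit-learn), taking the best of *n*
random restarts (default 20) plus one warm start from classical metric
scaling; the reported stress is recomputed independently with isotonic
regression so it is always stress-1 regardless of the optimizer's internal
normalization. Distances that are exactly Euclidean re-embed at stress ~0
because the metric warm start is already optimal.

**PERMANOVA** follows the distance-based partitioning of Anderson /
McArdle & Anderson: with the Gower-centred matrix `G = −½ J D² J`,
`SS_total = tr(G) = (1/n) Σ_{i<j} d_ij²`, and each term's SS is the increment
in `tr(H G)` as the term's dummy columns join the design — sequential
(Type-I) SS in the order terms are listed, the `adonis` convention, with
interactions written `a:b`. Pseudo-F uses the residual trace. p-values come
from free permutation of sample labels with the `(b+1)/(m+1)` estimator
(seeded), or exhaustive enumeration of all n! relabellings for n ≤ 9.
Tie-handling: permuted F values within 1e-12 of the observed F count as
exceeding, which is slightly conservative. Correctness anchors: a 4-sample
two-group configuration with within/between distances 0.1/1 gives
SS_total = 1.005, F = 199, R² = 0.99005, exhaustive p = 1/3; the one-way
pseudo-F matches scikit-bio's implementation to 1e-10; the null rejection
rate at α = 0.05 is calibrated within [0.03, 0.07].

**Venn partitions** assign every ASV present in ≥ 1 group to the exact
subset of groups containing it (group presence pools the group's samples, so
a plot's replicates count once); cells are checked to be disjoint and
covering on every call, and read shares are fractions of the selected
compartment's total reads.

## Source attribution

Source sets are built per block from that plot's samples only — no
cross-block borrowing — as unions of presence over the plot's samples of
each compartment, consuming the replicate-filtered table. Nodule ASVs are
pooled across the plot's three extractions (union after the ≥2-of-3 filter)
before classification. Classification is exact set membership over the 2³
lattice; the full lattice is reported **including BulkSoil+Roots**, a
logically possible cell that source-contribution displays often omit;
`collapse_bulk_roots=True` folds it into BulkSoil+Rhizosphere+Roots for
strict display parity. "Unknown" is purely set-logic (detected in no source
compartment); the package makes no biological claim about seeds. Default
weighting is by ASV count ("percentage of nodular ASVs"); read weighting is
a labelled secondary output. Treatment-level values are arithmetic means
over the treatment's blocks; a block with an empty nodule roster is excluded
with a warning.

## Statistical layer

**Recruitment model.** Percentages (or counts) are analysed as
`ln(x + δ) ~ category × treatment` with a random intercept per block,
δ = 1 by default because exact zeros are expected (e.g. a treatment drawing
nothing from the rhizosphere alone). Factors use sum-to-zero coding, so the
per-term Wald F tests are marginal (Type-III-style) tests and pairwise
category contrasts reduce to differences of category main effects
(treatment-averaged marginal means); pairwise p-values are Holm-adjusted.
Denominator degrees of freedom use the containment rule
`n − rank(X) − (n_blocks − 1)`; on balanced designs this reproduces the
exact fixed-block F test, verified in simulation (type-I error within
[0.03, 0.07] at α = 0.05 over 500 null datasets). A singular or
non-convergent random-intercept fit is downgraded to a fixed-block OLS model
with a logged warning.

**ANOVA + Tukey.** Phenotype and richness comparisons use fixed-effects
ANOVA (Type II, one- or two-way with interaction); Tukey(-Kramer) HSD uses
the full model's residual mean square and the studentized-range
distribution, and agrees with statsmodels' implementation to 1e-6. Compact
letter displays use insert-and-absorb: start from one column holding all
groups, split every column containing a significantly different pair, absorb
subset columns, and assign letters in decreasing-mean order starting at "A".
Consistency (significant pairs share no letter, non-significant pairs share
at least one) is asserted on every call.

## Synthetic data generator

Per plot, membership follows a stepwise path: a taxon occupies bulk soil
with probability `p_bulk` (0.75), the rhizosphere with `p_rhizo` (0.6) if in
bulk or `eps_rhizo` (0.08) otherwise, and roots with `p_root` (0.35) if in
the rhizosphere or `eps_root` (0.3) otherwise. The epsilon rates admit
colonists that skip a step so every lattice class is realizable; taxa in
none of the three form the plot's seed pool. The nodule roster (80 ASVs by
default) draws category counts from a multinomial over `pi`; each category
samples from its exact-membership class, drafting from the seed pool (and
setting the drafted taxon's membership to exactly that category) when the
class is smaller than the draw, so truth labels always equal realized
memberships and `pi` is honoured exactly in expectation. The generator
errors only when the seed pool itself cannot cover demand. The default
`pi` (Unknown 0.42, Roots 0.25, BulkSoil+Rhizosphere+Roots 0.21,
Rhizosphere+Roots 0.08, Rhizosphere 0.04) mirrors the qualitative pattern of
replicated field observations of pea nodules: unknown/seed-borne sources
dominate, roots are the main known source, bulk soil alone contributes
essentially nothing.

Counts are Dirichlet-multinomial: sample relative abundances are Dirichlet
draws centred on the roster's log-normal regional abundances (σ = 1) with
mean per-taxon concentration `dirichlet_alpha = 2` — overdispersed enough
that replicate dropout is common in the rare tail and the ≥2-of-3 filter has
real work to do, while abundant taxa remain reliably detected at the default
depth of 50 000 reads/sample. Depth and concentration jointly control the
detection error that propagates into attribution: single-sample compartments
(bulk, rhizosphere) miss a few percent of their rare members, which is the
dominant source of recovery error (~1–3 percentage points per category at
defaults).

What the generator does **not** emulate: taxonomy mis-assignment, chimeras,
index hopping, contaminant lineages beyond simple organelle spike-ins,
compositional correlations between taxa (Dirichlet covariance only),
treatment effects on community composition, and true seed-compartment
communities (Unknown taxa are simply nodule-only). Passing recovery tests
therefore demonstrate correctness of the set-logic pipeline under realistic
detection noise, not robustness to upstream bioinformatic error.

## Numerical and reproducibility conventions

All randomness flows through explicit integer seeds (`numpy` Generators;
child seeds via `SeedSequence`). The one-shot pipeline writes every table
with a provenance header (version, seed, config hash over analysis settings,
paths excluded) and is byte-identical across runs with the same
configuration and seed. Problem sizes used by the test suite and the
acceptance script (e.g. 300–800 taxa, depths 3 000–50 000, 20 recovery
seeds, 500 calibration replicates) were chosen to give stable Monte-Carlo
estimates at interactive runtimes.

## Known limitations

* Presence/absence source logic cannot distinguish low-abundance true
  sources from detection failure; the Unknown category absorbs both.
* PERMANOVA uses free permutation; restricted (within-block) permutation
  schemes are not implemented.
* The mixed model supports a single random intercept (block); crossed or
  nested random effects are out of scope.
* The CSS implementation uses a fixed quantile level; the adaptive
  quantile search of metagenomeSeq is deliberately not reimplemented.
* BIOM support covers the JSON (1.0) dialect only, not HDF5 (2.x).
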