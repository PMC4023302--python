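# Methods

## Model and procedure

The package tests, for a fixed gene set of *p* genes measured in two
phenotype groups (n₁ and n₂ samples, each ≥ 3), the null hypothesis that
the set's coexpression structure is the same in both groups.

**Weight factors.**  Within one group, let *R* be the matrix of absolute
pairwise correlations with the diagonal removed.  We ask for a weight
vector *w* > 0 in which every gene's weight equals the weighted sum of its
absolute correlations with all other members, up to one common scale
factor.  In matrix form this is *c·w = R·w*: an eigenproblem.  *R* is
non-negative and symmetric; when it is irreducible (the graph of its
nonzero entries is connected) the Perron–Frobenius theorem gives a unique
largest eigenvalue with multiplicity one and a strictly positive
eigenvector *v\**, so the solution exists and is unique with scale
*c = λ\* − 1*, where *λ\** is the largest eigenvalue of the unit-diagonal
matrix *R + I* (adding the identity shifts eigenvalues by one and leaves
eigenvectors untouched).  The implementation therefore solves the dense
symmetric eigenproblem for *R + I* and reports *λ\** (always ≥ 1) together
with the positive unit-L2 eigenvector.  Weights are scaled as
*w = v\* · ‖v\*‖₁*, which normalizes them "around one": for an
equicorrelated set the eigenvector is uniform and every weight is exactly
1, independent of *p* and of the common correlation.  The sign of the
eigenvector returned by LAPACK is arbitrary, so absolute values are taken
(the Perron vector is positive up to a global sign).

**Test statistics.**  The primary statistic is the L1 distance
Σᵢ |wᵢ⁽¹⁾ − wᵢ⁽²⁾| between the scaled weight vectors of the two groups.
The comparator statistic is the size-adjusted Euclidean distance
√((1/K) Σₖ (ρₖ⁽¹⁾ − ρₖ⁽²⁾)²) over the K = p(p−1)/2 unordered pairs of
**signed** correlations.  The weight statistic deliberately uses absolute
correlations (a gene anti-correlated with the block is still structurally
tied to it); the pairwise comparator uses signed correlations, matching the
aggregation it represents.  Both views are carried explicitly in
`CorrelationStructure` so each statistic reads the correct one.

**Permutation calibration.**  P-values come from B random relabelings of
the pooled n₁+n₂ samples into groups of the original sizes, recomputing
correlations — and, for the weight statistic, eigenvectors — from scratch
for each relabeling.  The add-one-corrected p-value
(1 + #{null ≥ observed}) / (1 + B) never reaches zero and has granularity
1/(B+1).  Default B = 1000.  A permutation that leaves some gene with zero
variance inside a group is redrawn, up to 10·B attempts in total; this
keeps the statistic defined for near-constant genes without distorting the
null for ordinary data (for continuous expression values redraws
essentially never trigger).

## Minimum spanning tree backbones

The complete coexpression graph places an edge of length 1 − |rᵢⱼ| between
every pair of set members.  The first minimum spanning tree T₁ is computed
by Kruskal's algorithm with edges ordered by (distance, smaller gene index,
larger gene index), so tied distances — common in simulated data — resolve
deterministically.  The second structure is the minimum spanning tree of
the graph with T₁'s edges removed; when that reduced graph is disconnected
(e.g. a star-shaped T₁ on four nodes leaves the centre isolated) the
minimum spanning *forest* is used instead, which keeps the construction
total and preserves the minimum-degree-2 property of the union.  Degree and
betweenness centralities are computed on the unweighted union topology;
betweenness uses the standard normalized shortest-path-fraction definition.
The gene with the largest weight factor is the hub gene; ties (within
relative 1e-12) go to the earliest gene in set order and are flagged with a
warning.  "Central position of high-weight genes" is a qualitative
tendency, exported as node annotations, never asserted as an invariant.

## Simulation designs

Datasets are drawn from p-dimensional normals N(0, Σ₁) and N(0, Σ₂) via
Cholesky factors, with n per group (default 20, i.e. N = 40 total).  Two
alternatives are built in:

- **Single-block design** (`scenario="one"`): Σ₁ = I; in Σ₂ the first
  round(γ·p) genes are pairwise correlated at r.  γ ∈ (0, 1] is the
  detection call (fraction of truly coexpressed genes), r ∈ [0, 1) the
  correlation strength.  At γ = 1 both groups share the uniform leading
  eigenvector, so the design is invisible to the weight statistic by
  symmetry — the canonical separation between the two tests.
- **Block-shift design** (`scenario="two"`): both matrices tile the
  diagonal with blocks of size round(β·p) (which must divide p exactly);
  within each block round(γ·β·p) genes are correlated at r — the first
  ones in Σ₁, the last ones in Σ₂ — so the coexpressed *membership*
  shifts while the average correlation stays equal.  The two memberships
  share max(0, 2·round(γβp) − round(βp)) genes per block; at
  (p, β, γ) = (20, 0.25, 0.6) that is 3 coexpressed genes per block and 4
  shared genes overall.  Off-block entries default to 0, with a
  `background` parameter for the small-positive variant.

Rounding of γp, βp and γβp is half-away-from-zero.  Note that at a rounding
boundary the disjointness rule "γ ≤ 0.5 ⇒ no shared genes" can be broken
(β·p = 5, γ = 0.5 rounds 2.5 up to 3); it holds whenever γβp is an integer.

`estimate_rejection_rate` reports the fraction of independent replicate
datasets with p ≤ α and its binomial standard error.  Replicate streams are
spawned from the master seed with `numpy.random.SeedSequence.spawn`, on top
of the counter-based Philox generator, so every estimate is reproducible
from a single integer seed across platforms.  Default B inside power
studies is 500; the null-calibration runs in the acceptance script use
B = 1000 with 1000 replicates at p = 20 and 300 replicates at p = 100
(problem sizes chosen to keep a full reproduction run in the ten-minute
range on one core).

## Screening workflow

Probe-level matrices are collapsed to genes by dropping unmapped probes and
keeping, per gene, the probe with the largest absolute Welch (unequal
variance) t-statistic between the phenotypes; probes constant in both
groups are skipped with a warning.  Gene sets are intersected with the
measured universe *before* the 15–500 size filter, so a large nominal set
whose measured overlap lands inside the bounds is kept at its overlap.
Each surviving set is tested with both statistics on independent
sub-streams spawned from the master seed; the whole screen is
bit-reproducible.  Sets are categorized (`gsnca_only`, `gsca_only`,
`both`, `neither`) from the raw p-values at the configured α;
Benjamini–Hochberg q-values across the collection are reported alongside,
since multiplicity handling is a policy choice best left visible to the
analyst.  Two per-set effect summaries separate the regimes the two tests
respond to: the absolute difference in mean signed correlation, and the
mean per-gene absolute weight difference (the L1 statistic divided by p).
Hub-membership enrichment uses the inclusive hypergeometric upper tail
P(X ≥ k), validated against exact binomial-coefficient enumeration.

## Numerical choices

- Correlations: Pearson by default (standard for log-scale expression
  data), Spearman selectable; matrices are symmetrized and clipped to
  [−1, 1] before use.
- The permutation engine vectorizes over relabelings.  For Pearson, each
  group's correlation matrices derive from per-subset sums and
  sums-of-products obtained by multiplying 0/1 membership vectors against
  the (globally centred) data — two large GEMMs per batch — and the second
  group's sums are the pooled totals minus the first group's.  Global
  centring leaves within-subset covariances unchanged while avoiding
  catastrophic cancellation; the batched matrices agree with
  `numpy.corrcoef` to ~1e-15.  Spearman ranks depend on the subset, so
  that path ranks each subset directly.
- Leading eigenvectors in the null loop use the batched LAPACK `syevd`
  gufunc for p < 50 and a per-matrix subset solver (`syevx`, top eigenpair
  only) above; the observed statistic always goes through the scalar
  `gene_weights` path.  A two-gene set is rejected for the weight test:
  the zero-diagonal 2×2 matrix has a constant leading eigenvector, making
  the statistic identically zero.
- Weight solutions are validated against an independent power-iteration
  oracle (relative tolerance 1e-9 over random instances, p = 3…10) and
  against full eigendecompositions for Perron positivity and eigenvalue
  dominance; minimum spanning trees against exhaustive enumeration of all
  spanning trees for p ≤ 6.

## What the simulations do and do not show

The generator produces exactly block-structured, mean-zero Gaussian data
with homogeneous within-block correlation.  Real expression data have
heavier tails, mean/variance relationships, batch structure and smoothly
varying correlation strength; none of these are emulated.  Passing
calibration and power checks therefore demonstrate correctness of the
statistics and their permutation calibration under the stated designs, not
performance guarantees on any particular microarray or RNA-seq dataset.
Under the γ = 1 degenerate design the rejection rate stays at or below the
nominal level but can run conservative (measured ~0.01–0.04 at α = 0.05
depending on r): permuting labels across two groups with *unequal*
covariances inflates the null spread of the statistic, a known property of
permutation tests under heterogeneity — the design is undetectable, which
is the scientifically relevant claim, but the test is not exact there.

## Known limitations

- The weight eigenproblem requires an irreducible absolute-correlation
  matrix; a gene uncorrelated with every other member (exact zeros, which
  occur with rank-deficient or heavily discretized data) raises an error
  naming the offending genes rather than silently regularizing.
- Permutation p-values have granularity 1/(B+1); screens at small B cannot
  distinguish small p-values, which propagates into the BH q-values.
- The probe-collapsing rule (max |Welch t|) targets two-group designs
  only; no identifier translation is performed — probe→gene maps are
  accepted as input tables.
- Betweenness is computed on the unweighted MST2 topology; edge lengths
  influence which edges enter the backbone but not the centrality
  arithmetic.
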