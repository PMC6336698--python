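# Methods

This note records the statistical model behind `parconc`, the choices
made where the design was genuinely open, and what the synthetic test
conditions do and do not establish about real atlas data.

## Model and assumptions

A *parcellation* is an exhaustive, non-overlapping division of a masked
3D volume into integer-labeled areas (0 = background) on a voxel grid
with a NIfTI affine.  The analysis assumes every atlas lives on one
shared grid: shapes must match exactly and affines within 1e-4 mm.  No
resampling is offered — resampling label volumes silently changes every
overlap count, so mismatched grids are hard errors and registration is
treated as a preprocessing step outside the package.  Coordinate lookup
uses the inverse affine with nearest-neighbor rounding (half-up ties);
labels are never interpolated.

## Concordance statistics

*Conditional probability.*  P(a|b) = n_ab / |b| with |b| the **full**
size of area b, including voxels the other atlas leaves unlabeled.
Columns of a P-matrix therefore sum to ≤ 1, with equality exactly at
full coverage.

*Directional Wallace.*  W_A→B is the probability that two voxels
co-located in one area of group A are co-located in one area of group B.
It is computed through the contingency identity
Σ n_kl(n_kl−1) / Σ m_k(m_k−1) over unordered pairs, with m_k the full
area sizes of the conditioning group.  Two conventions needed fixing
because the probability wording alone does not determine them:

- **Coverage:** a voxel pair whose members are not jointly inside a
  single area of the other group counts as "not together", including
  pairs with a member the other atlas does not label at all.  The
  denominator uses full sizes.  This follows the probability definition
  literally; the alternative (restricting to the jointly covered domain)
  would make concordance of partially overlapping atlases look better
  than their maps justify.
- **Raw vs analytically adjusted:** the package computes raw directional
  probabilities and calibrates chance empirically with the null model;
  an analytic chance-corrected variant (rescaling each direction against
  its expectation under independent alignment of the marginals) is
  available via `adjusted=True` but is not the default.

The identity is verified in the tests against an independent brute-force
enumeration of all unordered voxel pairs on volumes up to ~350 voxels
(tolerance 1e-12).

*Summaries.*  W_max = max of the two directions, W_asym = absolute
difference; 0 ≤ W_asym ≤ W_max ≤ 1 is enforced.  Interpretation: high
W_max/low W_asym = one-to-one concordance; high/high = subset
(subdivision) configuration; low W_max = no concordance.

*Cluster aggregation.*  A cluster's single number over >2 atlases is the
arithmetic mean of its per-atlas-pair W_max (and W_asym) values.  The
choice of reduction is genuinely open (mean, median, and size-weighted
variants are all defensible); per-pair rows are always emitted so any
alternative is recomputable from the output table.  Degenerate pairs
(all-singleton conditioning groups) raise an explicit undefined-index
error rather than contributing silent zeros; clusters present in fewer
than two atlases are skipped with a warning.

## Random-parcellation null

Random partitions are grown by seeded random label filling: N distinct
seed voxels drawn uniformly without replacement, then breadth-first
frontier growth where a uniformly random pending claim wins each step.
All regions are 6-connected and nonempty.  "Label filling" could also be
read as unconstrained random label assignment; the connected
region-growing reading is adopted because unconstrained assignments have
no spatial autocorrelation and would make the null trivially easy to
beat.  The same generator produces the synthetic base parcellations, so
null and synthetic atlases come from one distribution.

For one atlas-pair comparison, two **independent pools** (one per side,
`n_parcellations_per_atlas` each; reference 50, desk scale 10) are
grown and `n_pairs` pairs (reference 1,000, desk 100) are sampled
uniformly without replacement from the cross product; separate pools
mean no pair can reuse one parcellation on both sides, for any N.
Cutoffs are empirical percentiles with linear interpolation between
order statistics (stated because percentile conventions differ); a value
exactly at the cutoff counts as chance-level.

Calibration behavior worth knowing: at desk scale the cutoff is an
essentially unbiased quantile estimate, but with only 10 parcellations
per side the 100 pair samples are strongly dependent, so any *single*
null realization's cutoff is noisy and its one-realization false-positive
rate scatters widely (sd ≈ 4 percentage points).  The package therefore
exposes `calibration_false_positive_rate`, which redraws the entire
procedure (null + observed pair) per repetition; averaged over 500
independent repetitions the rate sits somewhat above the nominal 5%
(measured 5–9% across seeds — the residual upward bias is the
Jensen-inequality cost of the noisy desk-scale cutoff and shrinks with
larger pools).  Note also that size-mismatched random pairs (e.g.
6 vs 12 areas) are *systematically asymmetric*, so a genuine subdivision
relationship can have W_asym below the matched null's 95th percentile
even when its W_max is far above chance — the asymmetry flag is
conservative for mismatched region counts.

## Synthetic families

`make_family` emulates the structure the analysis assumes about real
multi-author atlas sets:

- **mask** — full box or inscribed ellipsoid (default 16³ ellipsoid,
  ≈ 2,100 voxels): a connected convex stand-in for a subcortical volume,
  not an anatomically realistic shape;
- **base** — random growth with `n_base_areas` = 6 by default, giving
  areas of a few hundred voxels, comparable in relative scale to major
  nuclear groups;
- **splitters** — every base area split into `split_factor` = 2
  connected children by k-seed growth inside the parent; nesting is
  exact, so child→parent Wallace is exactly 1 (the subset-configuration
  signature: W_max = 1, W_asym > 0);
- **lumpers** — groups of ~`merge_factor` = 2 adjacent areas fused by
  capacity-limited growth on the area-adjacency graph (stranded areas
  join the smallest adjacent group), yielding ⌈n/factor⌉ connected
  areas;
- **boundary noise** — per iteration, every voxel with a differently
  labeled 6-neighbor is reassigned to a uniformly chosen neighboring
  label with probability p (default 0.05, 2 iterations, applied
  synchronously).  This models inter-observer boundary jitter as a
  local, isotropic process; it is a stand-in, not a model fitted to
  observer data, and the truth record labels it as such.  Noise is
  applied to the derived (split/merge) atlases only, keeping the base as
  the clean reference; an area erased by noise raises a degeneracy error
  rather than silently shrinking the label set.
- **cluster map** — clusters correspond to base areas; every derived
  area is assigned its base ancestor's cluster.  A merged area has no
  unique ancestor, so it takes the cluster of its largest constituent
  (majority ancestor) — a deliberately noisy assignment mirroring how
  real composite areas get filed under one region.

What passing tests on these families show: the statistics respond
correctly to known nesting, known coarsening, and graded noise, and the
pipeline's inferences (subset signatures, null exceedance, MDS family
separation) recover planted structure.  What they do not show: behavior
under registration error fields, anatomically curved boundaries,
systematic inter-atlas volume differences, or partial-coverage atlases —
real data properties the generator does not emulate.

## Seriation, MDS, voxel maps

*Block seriation.*  Objective: mean over nonzero entries of
|i/(rows−1) − j/(cols−1)| (normalized so non-square blocks are
comparable).  Each block is reordered by the first left/right singular
vector pair of the double-centered block, signs chosen jointly so the
left vector correlates positively with row index.  Exact permutation
blocks (e.g. an anti-diagonal) make that SVD degenerate — all singular
values coincide — so a neighbor-smoothed variant (tridiagonal smoothing
of rows and columns before centering) is also evaluated; among
{identity, plain SVD, smoothed SVD} the lowest objective wins, identity
on ties, so the objective provably never increases.

*MDS.*  The inter-atlas distance d = √((1−W_max)² + W_asym²) treats
concordance shortfall and asymmetry as orthogonal dissimilarity axes;
any monotone combination would be defensible, and this one is the
simplest that makes identical atlases coincide and "more overlapping,
less asymmetric" strictly closer on both axes.  Embedding is classical
(Torgerson) MDS — double-centered squared distances, two leading
eigenpairs, negative eigenvalues clipped — deterministic up to
rotation/reflection, so tests compare inter-point distances and family
silhouettes, never raw coordinates.

*Voxel maps.*  Per unordered atlas pair and voxel labeled by both, the
local statistic of the containing areas a, b is max(P(a|b), P(b|a))
(concordance) and |P(a|b) − P(b|a)| (asymmetry); maps are means over
contributing pairs with an explicit coverage volume.  The per-voxel
statistic is genuinely underdetermined by the map semantics alone; a
single-area directional-Wallace variant is available via
`statistic="wallace"`.  Local asymmetry never exceeds local concordance,
and that survives averaging.

## Problem sizes and numerical conventions

Test and demo scales: 16³ ellipsoid family (≈ 2,100 voxels, 5 atlases),
12³ ellipsoid null masks (≈ 900 voxels), desk null budget 10
parcellations/side × 100 pairs, 500-repetition calibration runs, oracle
cross-checks on volumes ≤ 7³.  These sizes were chosen so every
distributional claim is still measured with real Monte-Carlo width while
the whole suite runs in well under a minute per stage; the reference
(paper-scale) null budget remains available through `NullConfig` and CLI
flags.  All randomness flows from one integer seed per operation
(`numpy.random.SeedSequence` spawning per stage; the growth frontier
uses Python's `random.Random` internally for cheap per-step draws), and
fixed seeds give bit-identical volumes and byte-identical pipeline
outputs.  Floating-point tolerances: Wallace identity vs enumeration
1e-12; affine/grid agreement 1e-4 mm; seriation objective comparisons
1e-12.

## Known limitations

- Wallace indices are voxel-count statistics: they ignore boundary
  geometry, so two atlases disagreeing only in thin boundary shells can
  still score high W_max.
- The empirical null conditions only on region *count*, not on region
  size distributions; atlases with very unequal area sizes are compared
  to nulls with more homogeneous sizes.
- The asymmetry significance flag is conservative for pairs with
  mismatched region counts (see null section).
- Cluster aggregation by unweighted pair mean treats a cluster's every
  atlas pair equally regardless of member-area volume.
- The S-index family of overlap measures is not implemented.
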