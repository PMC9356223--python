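# Methods

This note documents the models, estimators and numerical conventions behind
`ionoflux`, the choices made where the design was genuinely open, and what
the synthetic-data tests do and do not demonstrate about real data.

## Study design assumed by the package

A destructive-harvest water-deficit (WD) experiment: plants grown to a
pre-treatment harvest t₀, then split into a well-watered control arm (80% of
field capacity) and WD arms dried to 40% or 25% of field capacity, harvested
after a short (t1_40, t1_25) or extended (t2_40, t2_25) deficit. Each
harvest takes 5 independent replicates. Tissues are roots, old/young leaf
blades (OLB/YLB) and, for rapeseed, old/young petioles (OP/YP); "old" and
"young" split tissues developed before vs after t₀. Concentrations are in
ppm of dry weight (µg/g), dry weights in g, quantities and net uptake in
µg/plant. No unit inference is performed.

## Net uptake from subtractive replicate combinations

Element quantity per tissue is Q = E × DW; plant totals sum Q over the 3- or
5-tissue layout, and a plant missing a tissue is an error, never imputed.
Net uptake between t₀ and t′ is estimated over the full Cartesian product of
replicate plant totals: with n₁ totals at t′ and n₂ at t₀ there are n₁ × n₂
subtractive combinations (25 for the complete design). The t₀ harvest
precedes the treatment split and is shared by both arms.

Two conventions deserve emphasis:

* **The reported SE is sd/√(n₁n₂) over the combination values.** The
  combinations share replicates and are statistically dependent, so this SE
  understates the true sampling uncertainty. It is kept because it is the
  field's reporting convention for this estimator; inference should not rely
  on it.
* **Significance of a WD/control net-uptake ratio** is, by default, a Welch
  t-test on the two combination samples (`nu_test="welch"`), which inherits
  the same anti-conservatism — with 25 dependent values per arm it can flag
  ratios a few percent away from 1. The defensible alternative is
  `nu_test="perm"`: a replicate-level permutation test that pools the t′
  plant totals of the two arms and enumerates all C(10,5) = 252 re-splits
  exactly (Monte-Carlo beyond 100 000 splits), respecting the dependence.
  The choice is configurable because the original reporting convention does
  not name a test; on noiseless data both are undefined and the model
  reports NaN.

The mean of the combination values equals the difference of the two harvest
means exactly, and NU is linear in any common concentration scaling; both
are enforced by property tests.

Group comparisons of phenotype variables use one-way ANOVA with Tukey's HSD
(Tukey–Kramer standard errors for unbalanced groups, studentized-range
reference with k groups and N−k degrees of freedom). For k = 2 the adjusted
p-value is computed through the exact identity Q = √2·|t|, i.e. the F-test
p-value, which avoids a slow numerical integration in tight loops. When
every group has zero internal variance the result is flagged degenerate with
NaN p-values rather than p = 0. Relative-to-control tables are masked at
p < α with an explicit NaN marker; cells are never dropped.

## Phenotyping conventions

* **ExG** is computed on mean channel intensities over the plant mask,
  (2Ḡ − (R̄+B̄))/(R̄+Ḡ+B̄) ∈ [−1, 2]. The printed form of this index is
  ambiguous about the grouping of terms; the standard channel-sum-normalized
  definition is implemented. A per-pixel variant (mean of pixelwise ExG) is
  available behind `per_pixel=True`. Averaging is over the mask only, not
  the full background-deleted frame. Arrays with a maximum above 1 are
  treated as 0–255 and rescaled; ExG itself is invariant to uniform channel
  scaling.
* **Convex hull**: Andrew's monotone chain over foreground *pixel centers*,
  area by the shoelace formula. Under this convention four pixels at the
  corners of a 10 × 10-pixel square span (10−1)² = 81 px². The hull can
  undercount a filled region's pixel count by up to perimeter/2 + 1 (the
  lattice-point bound), which is the documented discretization slack in the
  invariant hull ≥ projected − slack. Fewer than 3 non-collinear pixels is
  degenerate: area 0 with a warning.
* **Projected area** is the foreground pixel count × pixel_scale².
* **WUE = A/E** is computed per replicate and averaged, not as a ratio of
  means (the two differ by a small Jensen gap on real data).

## Differential expression

The stage follows the standard TMM + NB GLM + LRT + BH skeleton for
two-group contrasts, implemented in-package:

* **Filtering**: keep genes with CPM ≥ 1 in ≥ 2 samples (both configurable).
  The fraction removed is data-dependent and reported, not targeted.
* **TMM**: reference = library whose upper quartile of scaled counts is
  closest to the mean upper quartile; per-gene log-ratios M and abundances A
  against the reference over genes positive in both libraries; two-sided
  trims of 30% on M and 5% on A (rank-based); weighted mean of the kept M
  with inverse delta-method variances as precision weights; factor = 2^mean,
  renormalized to geometric mean 1. Identical compositions short-circuit to
  factor 1. Factors agree with the Bioconductor reference implementation to
  10⁻⁶ on random matrices (cross-checked in the test suite via Rscript).
* **Dispersion**: a single NB dispersion φ (Var = µ + φµ²) maximizing the
  Cox–Reid adjusted profile likelihood over genes — group means are re-fit
  at every candidate φ and the adjustment −½·log I per fitted mean corrects
  the downward bias of the plain profile likelihood (without it the
  estimator undershoots by roughly (n−p)/n and the stage loses FDR control).
  The 1-D search runs on log φ over [10⁻⁶, 5]; optima at the boundary
  collapse to the Poisson limit φ = 0. Groups with a single replicate are
  rejected. An optional fixed φ can be supplied instead.
* **Per-gene GLM**: log µ = b(group) + log(library size × TMM factor).
  The group-wise MLE solves a 1-D concave score equation per gene by
  vectorized Newton iteration (clipped steps, 10⁻¹² tolerance); the LRT
  statistic 2(ℓ_full − ℓ_null) is referred to χ²(1) with no small-sample
  correction. log₂FC = Δb/ln 2; a group with all-zero counts is shrunk with
  a half count for fold-change *reporting* only, and genes zero everywhere
  get p = 1, log₂FC = 0, flagged.
* **Multiplicity**: BH step-up per contrast across all filtered genes
  (delegated to statsmodels' `multipletests`), never pooled across
  contrasts. A gene is a DEG iff adjusted p ≤ α, irrespective of fold
  change; direction is the sign of log₂FC.

Calibration on synthetic NB data (the acceptance suite): null raw-p
rejection at 0.05 sits inside the binomial 99% CI on 2000 genes, and the
observed FDR with 10% planted DE genes averages ≈ 0.045 over 20 runs,
consistent with BH's E[FDP] ≤ α(1−π₁).

## Gene–element patterns

The annotation merges two sources — KIG orthologs (element assignments taken
from the curated list) and GO "ion transport" genes with an unambiguous
element — deduplicated on (gene, element) with KIG precedence; rows without
an element assignment are dropped with a logged count. Live GO/ortholog
queries are out of scope: the module consumes exported tables. A gene tagged
for several elements (e.g. MSA1-style "S and Se") counts once per element.

The up/down/mixed language of per-element expression patterns is
operationalized by a dominance threshold: with summed up-counts U and
down-counts D across contrasts, an element is "up" if U/(U+D) ≥ 0.75, "down"
if D/(U+D) ≥ 0.75, "mixed" otherwise, "none" at U+D = 0. The 0.75 default is
a declared choice validated only by planted-pattern recovery; no claim is
made that it reproduces any published per-element assignment. A DEG flag
with log₂FC = 0 is rejected as inconsistent input.

UpSet exclusive intersections are computed by membership bitmasks (≤ 16
sets): for each realized subset, the count of items belonging to exactly
that subset; counts sum to the union size by construction and the output is
ordered by descending count.

## PCA

Eigendecomposition via full SVD of the centered (default) and unit-variance
scaled (default) matrix; constant columns under scaling and missing values
are errors naming the column, not silent drops or imputations. Scaling
defaults to on because elemental concentrations span five orders of
magnitude in ppm; expression PCA operates on log₂(CPM + 1) with the
pseudo-count documented here. Signs follow a deterministic convention
(largest-magnitude loading positive). Cumulative explained variance is the
running sum of the variance fractions.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *structure* of the experiment: 5 replicates ×
{control, WD} × 4 WD harvests plus shared t₀; 20 elements with realistic
ppm magnitudes per tissue; near-exponential control growth (≈1.8× five days
after t₀ to ≈10× after three weeks, consistent with published control
biomass trajectories at these stages); NB-distributed counts with
log-uniform library sizes (so TMM is exercised non-trivially) and balanced
up/down planted fold changes; annotation tables with controllable element
counts and KIG fractions; and simple geometric plant images with
analytically known areas.

The planted ground truth for the ionome is the relative net uptake: the WD
multiplier m acts on the plant-total net uptake,
Q_WD(t′) = Q(t₀) + m·(Q_ctrl(t′) − Q(t₀)), with the implied concentration
scaling spread uniformly over tissues, so the zero-noise pipeline returns m
exactly. Noise is multiplicative lognormal with unit mean and configurable
CV (default 5%) on concentrations and dry weights — chosen for positivity
and constant CV; the true error law of ICP-MS measurements is not published,
so this is a declared assumption, not a derived one. All generators are pure
functions of (config, seed); one integer seed is split deterministically per
generator.

What passing tests therefore show: the estimators are correct and calibrated
under the stated noise model at the stated design size. What they do not
show: robustness to tissue-correlated measurement error, element crosstalk,
unequal replicate loss, library-preparation artifacts, or annotation
incompleteness — all properties of real data the generators deliberately do
not model (nor do they model soil water dynamics, hormone signalling or
uptake kinetics).

A note on attainability: the ±0.05 absolute recovery band for relative net
uptake refers to the planted-multiplier cell at a late harvest. For an
element with multiplier 1 at the *earliest* harvest the band is not
statistically attainable at 5% CV with 5 replicates — there the net uptake
is a small difference of large noisy totals and the ratio's standard error
alone exceeds half the band for any realistic growth factor.

## Problem sizes and numerical tolerances

Test and acceptance simulations use 2000-gene matrices with 5 samples per
group (dispersion recovery uses 3 per group to stress small-n behaviour),
500 ionome simulations for recovery rates, 2000 null simulations for ANOVA
calibration, and 20 000-permutation oracles — sizes chosen so the entire
suite completes in about a minute on one core while keeping Monte-Carlo
bands (99% binomial CIs) tight enough to be informative. Oracle equivalences
(TMM reimplementation, shoelace areas, Poisson-limit GLM) are asserted at
10⁻⁶–10⁻⁸; identities forced by construction (zero-noise recovery, BH hand
values, combination counts) are asserted exactly or at 10⁻¹².

## Known limitations

* The common-dispersion NB model has no tagwise/empirical-Bayes moderation;
  genes with outlying dispersion are tested at the shared φ.
* The Welch default for net-uptake significance is anti-conservative (see
  above); use `nu_test="perm"` when inference matters.
* The hull/area conventions are pixel-center based; areas of very small
  masks differ from corner-based conventions by O(perimeter) pixels.
* TSV/MatrixMarket/PNG are the only formats; no HDF5/AnnData containers.
* Image segmentation is out of scope: masks are inputs.
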