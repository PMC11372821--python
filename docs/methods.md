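# Methods

This note documents the models and estimators implemented in
`tridacna_sdm`, the choices made where the design was genuinely open,
and what the synthetic experiments do and do not demonstrate.

## Grid and areas

All layers live on a regular WGS84 geographic grid at 5 arc-minutes
(≈ 9.2 km at the equator), registered by cell edges with row 0 at the
northern edge. Cells are half-open: a point on an interior edge belongs
to the higher-index (east/south) cell, with quotients snapped at 1e-9 so
points constructed to sit exactly on an edge behave as intended.

Cell areas use the spherical band formula
A = R² · Δλ · (sin φ_top − sin φ_bottom) with R = 6371 km and cell-edge
latitudes — no projection. Over the 26°-wide tropical study band, cell
area varies by ~2%, enough to matter for km² bookkeeping but not for
anything else; summing cells reproduces the analytic band area exactly
(telescoping identity). Whether published km² figures were planar or
geodesic is not knowable from the tables alone; the spherical convention
is this package's and is used consistently on both sides of every ratio,
so percent-protection and range-change figures are insensitive to it.

Rasters are single-band ESRI ASCII grids with a JSON sidecar holding the
layer name and units; values round-trip bit-exactly (written with repr
precision). Vector data (population boundary, MPA polygons) are GeoJSON
handled through shapely.

## Synthetic data generator

The generator emulates the structure the analysis assumes, not real
oceanography:

* **Fields.** Each of the nine predictors (current velocity, salinity,
  temperature mean, temperature range, depth, distance to shore,
  dissolved oxygen, light at bottom, phytoplankton) is Gaussian white
  noise smoothed with a kernel of `autocorr_cells` cells (default 6,
  lag-1 neighbour correlation ≈ 0.95) and mapped affinely to a plausible
  range (e.g. temperature 20–31 °C, salinity 31–35.5 PSS). Temperature
  additionally carries an equator-peaked latitudinal gradient so warm
  water is where it should be. The land/sea mask is the sign of a
  synthetic depth field thresholded at a target sea fraction (default
  0.8); distance to shore is the true distance transform from the
  synthetic coastline.
* **Niches.** A population's niche is a product of independent Gaussian
  terms, one per constrained variable, with a known optimum and
  tolerance — smooth, unimodal, and analytically known, which is what a
  recovery experiment needs. The two populations (EIOS west, WPI east of
  a meridional boundary) differ in temperature and salinity optima.
  Default optima (27.4/27.0 °C) sit below the ambient temperature mode:
  the populations live near their upper thermal limit, so each scenario's
  warming strictly shrinks the truly suitable area, and the four presets
  (2050s/2100s × RCP 2.6/8.5, temperature offsets 0.6–2.8 °C with small
  salinity freshening) lose area monotonically toward 2100s RCP 8.5.
* **Sampling.** Presences are drawn from sea cells with probability
  proportional to true suitability, jittered within their cell.
  Pseudo-absences are drawn uniformly from sea cells that contain no
  presence and fall outside the presences' per-variable environmental
  envelope (with a `cells_only` fallback when too few such cells exist).
* **MPAs.** Axis-aligned rectangles centred on random sea cells,
  accumulated greedily with deficit-adaptive sizes until the realized
  (area-weighted) sea coverage reaches the target (default 16%);
  placement is independent of suitability, so the null expectation is
  percent-protected ≈ coverage.

What passing tests on this generator do **not** show: realistic spatial
sampling bias, detection error, true oceanographic covariance between
predictors, or dispersal limits. The pipeline assumes unlimited
dispersal when projecting, so future suitable area is potential, not
expected, range.

## Collinearity screening and PCA

Screening is two-stage and iterative: while any pair has |Pearson r| ≥
0.7, drop the member of the worst pair with the larger mean absolute
correlation; then while any VIF = 1/(1 − R²) ≥ 10 (each predictor
regressed on all others, via statsmodels), drop the largest. The
post-conditions are re-checked exhaustively in tests. The elimination
order is this package's choice; thresholds are the conventional ones.

PCA standardizes variables (population sd) before eigen-decomposition
because the predictors' units are incommensurable; components are signed
so the largest-magnitude loading is positive. The niche analysis keeps
k = 4 components and runs on the pooled presences of both populations so
the two niches live in one space. PCA on all sea cells instead of
presences is available via `pca_fit` on any environment frame.

## Hypervolumes and the beta decomposition

A population's niche region is {x : f̂(x) ≥ τ} where f̂ is a Gaussian
product-kernel density over its PCA scores and τ is the density value
such that 95% of the training points lie inside (the `quantile`
parameter). Volume is estimated by uniform Monte-Carlo sampling over the
training bounding box expanded by 3 bandwidths; accepted draws double as
the stochastic points (default cap 20 000) used for plotting.

Bandwidths default to **2 × the per-dimension Silverman rule**
(h_j = σ_j (4/(d+2))^{1/(d+4)} n^{−1/(d+4)}). The factor matters: at
plain Silverman scale in d = 4 with a few hundred records, the kernel
density at the 95% boundary carries > 100% relative error (n·h⁴ ≈ 19
effective neighbours), and because most of a 4-D region's volume lies
near its boundary, two samples from the *same* distribution then read
β_total ≈ 0.4. Doubling the bandwidth stabilises the boundary
(replicate samples read β ≲ 0.15 at n = 500) while niches separated by
more than four tolerance units still read β > 0.7. Two hypervolumes
that are to be compared are built with **common bandwidths** (the mean of
the two samples' estimates) so the comparison measures where the niches
lie, not differences in smoothing.

The pairwise comparison estimates V₁, V₂ and V_shared on the *same*
uniform draws over the union bounding box (common random numbers), which
makes V_shared ≤ min(V₁, V₂) exact and removes between-box Monte-Carlo
noise from the ratios. With unique volumes u_i = V_i − V_shared:

    β_total = (u₁ + u₂) / V_union
    β_shift = 2 · min(u₁, u₂) / V_union
    β_rich  = |u₁ − u₂| / V_union

β_total = β_shift + β_rich holds algebraically and is asserted on every
comparison. Volumes are unit-dependent (PCA-space units⁴) and only the
decomposition and its ordering are comparable across analyses. The
known residual limitation: even with these choices, replicate-sample
β_total has a noise floor of roughly 0.1 at n = 500 in d = 4 — the
sampling variability of a 500-point cloud's location and spread is
irreducible by any region estimator that honours the data.

## Learners, evaluation and ensembling

The ten algorithms are realized with fixed, logged hyperparameters:
GLM (logistic regression on a quadratic feature expansion), GAM
(logistic regression on per-variable cubic spline bases — a GAM with
fixed smoothing), MARS (logistic regression on hinge features at
quantile knots), CTA (depth-6 decision tree), RF (200 trees), GBM (100
boosting stages), ANN (one hidden layer of 8 units on standardized
inputs), FDA (LDA on the quadratic expansion), MAXENT (L2-regularized
logistic regression, C = 0.1, on a standardized quadratic expansion),
and SRE, implemented bespoke: suitability 1 iff every variable lies
within the presences' [q, 1−q] percentile envelope (q = 0.025). No
hyperparameter tuning is performed anywhere.

Evaluation: AUC is the rank-based (Mann-Whitney) statistic with tie
correction; TSS(τ) = sensitivity + specificity − 1 is maximized over all
sorted unique predictions and their midpoints, which covers every
achievable confusion table (verified against a dense τ-scan).
Cross-validation draws a fresh stratified 5-fold partition per replicate
(10 replicates → 50 runs per learner); a learner failing on a fold has
that run logged and excluded. Gates are strict: mean TSS > 0.7 **and**
mean AUC > 0.8. The ensemble refits survivors on the full table and
averages with equal weights by default; `tss_proportional` weighting is
available because the two conventions (weighted vs. equal) are both
defensible readings of common practice, and the choice is logged.

Permutation importance is 1 − Pearson r between original and
variable-permuted predictions, averaged over 10 shuffles, clipped to
[0, 1]. Response curves sweep one variable over its observed range with
the others at their medians (evaluation-strip).

## Projection and change maps

The maxTSS threshold τ is derived once per model from its full-data
training predictions and reused for every scenario; ≥ τ counts as
presence (fixed tie rule). Change categories: (1,0) loss, (1,1) stable,
(0,1) gain, (0,0) unsuitable; loss + stable equals current suitable
area and stable + gain the future one, asserted per scenario. Range
change is 100 × (A_future − A_current)/A_current with cell-area-weighted
km². Population-level models are projected on the full grid but
reported within their side of the boundary.

A documented artifact of envelope pseudo-absences: because no training
absence can be warmer than the warmest presence (the warm tail of the
envelope usually touches the warmest available cells), tree-based
learners extrapolate a high-suitability plateau beyond the observed
temperature range, and the *fitted* ensemble can project habitat gains
under warming even when the generating truth loses area monotonically.
The truth-level monotonicity is what the tests assert; the fitted-map
discrepancy is reported as-is and is the expected behaviour of
presence/background ensembles extrapolated outside their training
range. The `cells_only` pseudo-absence strategy removes the artifact
(absences then exist at all temperatures) at the cost of heavily
overlapping classes, which no learner separates well enough to pass the
TSS/AUC gates — the two strategies trade calibration for
discrimination, and the envelope default matches how this kind of
analysis is usually able to report high TSS.

On the response-curve recovery experiment: with envelope absences the
fitted suitability saturates near 1 across a ±1.5 °C plateau around the
true optimum, so the curve's argmax is only loosely pinned; the
end-to-end recovery assertion is meaningful at the one-tolerance-unit
scale, and the measured peak lands within one curve grid step of the
optimum at the default conditions and seed used by the acceptance test.

## Gap analysis

MPA polygons are rasterized by cell centres (a cell is protected iff its
centre lies in, or on the boundary of, any polygon) — partial-cell
precision would be spurious at 5-arc-minute resolution. Percent
protection is 100 × protected/predicted area, both cell-area-weighted,
and is invariant to uniform area rescaling by construction. The
projected loss class is partitioned exactly into Priority Conservation
Areas (outside MPAs) and Conservation Areas Pending Optimization
(inside); the partition identity with the change map's loss category is
asserted on every run. The "range" denominator is the species-level
binary map at the maxTSS threshold.

## Orchestration and reproducibility

One `RunConfig` drives every stage; the single seed fans out to
per-stage seeds by hashing the stage name (stable under stage
re-ordering, all below 2³¹). Each run writes a manifest (config, stage
seeds, package version) sufficient to re-run identically, a log with one
line per stage decision (drops, exclusions, tie-breaks), and CSV/ASCII
outputs; re-running a config reproduces the CSV outputs byte-identically.

## Problem sizes

Default experiments use a 25° × 17° window (≈ 49 000 sea cells), 400
presences, and the full 5 × 10 cross-validation; the parameter-recovery
experiment uses 1000 presences and the niche-bracketing experiments 500
records per population. These sizes were chosen so each experiment's
Monte-Carlo and sampling noise is comfortably below the effects being
measured, while a complete run stays in the minutes range on one CPU.
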