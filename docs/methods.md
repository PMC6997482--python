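# Methods

## Problem setting

`popsdm` models the climatic suitability of a species whose range is split
into geographically disjoint, potentially locally adapted populations. The
analysis contrasts three data suites — each population separately ("West",
"East") and all presences pooled ("Whole") — under current and future
climates, and asks whether the population-wise approach reveals structure
the pooled model misses. All stages run on presence-only records plus a
stack of gridded bioclimatic variables (Bio01–Bio19 semantics, ESRI ASCII
grids, square cells in decimal degrees).

## The maximum-entropy model

The suitability model is the Gibbs distribution over landscape cells whose
feature expectations match the presence sample — the classic
presence/background maximum-entropy construction. We minimize

J(λ) = −(1/m) Σ_presences λ·f(x) + log Σ_background exp(λ·f(x))
       + Σ_j RM·β⁰_j·(σ_j/√m)·|λ_j|

* **Features.** Linear, quadratic, unordered-pair product, forward hinge
  max(0, x−k)/(max−k), reverse hinge max(0, k−x)/(k−min), and threshold
  1[x > k]. Hinge/threshold knots sit at n_knots (default 20) equally
  spaced interior quantiles of the background distribution per variable.
  All features are min–max scaled to [0, 1] on the training background;
  features of constant variables are dropped (their coefficients would be
  unidentifiable) and zero-variance features keep exactly zero weight.
* **Regularization.** β⁰ is the per-class default interpolated on the
  presence count m: linear/quadratic/product 1.0 at m ≤ 10, 0.2 at m = 30,
  0.05 at m ≥ 100 (piecewise linear); hinge 0.5; threshold 2.0 at m = 0
  decreasing to 1.0 at m ≥ 100. σ_j is the presence-sample SD of feature j.
  RM = 0 is run at a 1e−6 numerical floor so the objective stays coercive;
  the model records `rm_floored` when that happens.
* **Optimizer.** Monotone proximal-gradient descent: Barzilai–Borwein step
  seeding, halving backtracking against the quadratic upper bound, and the
  soft-threshold proximal map for the L1 term. Convergence when the
  objective improves by less than `tol` (default 1e−7) or `max_iter`
  (default 500) is reached; the convergence flag and iteration count are
  stored on the model. The objective is monotonically non-increasing by
  construction, and the fitted raw output sums to 1 over the training
  background (tested at 1e−6). Tight-accuracy comparisons (e.g. against a
  BFGS likelihood oracle) use larger `max_iter` and smaller `tol`.
* **Outputs.** raw = exp(λ·f)/Z; with H the entropy of the fitted raw
  distribution, logistic = raw·e^H/(1+raw·e^H) and cloglog =
  1−exp(−raw·e^H). cloglog is the default map output; all three transforms
  are strictly monotone in each other, so rankings and AUC are identical.
  Projection clamps variables to their training ranges by default.

## Evaluation and tuning

* **AUC** is the Mann–Whitney pairwise statistic (ties half) of presence
  vs background scores.
* **AICc** = 2K − 2lnL + 2K(K+1)/(m−K−1) with K the number of nonzero
  coefficients and lnL the presence log-likelihood of the raw output
  renormalized over the landscape (background ∪ presences; whole-raster
  normalization would also be defensible but is costlier and changes
  nothing about the ranking on our landscapes). Settings with m ≤ K+1 are
  ineligible (+∞).
* **Setting selection** scores every (RM, FC) on shared random 50/50
  presence splits (mean test AUC), keeps the top 10% (ceiling, ≥ 1), and
  picks the lowest AICc among them; ties break by smaller K, then smaller
  RM, then FC order. If every kept setting is AICc-ineligible the maximum
  mean test AUC wins, with a warning.
* **Importance.** Permutation importance permutes one variable jointly
  across presence and background rows and reports mean training-AUC drops
  normalized to percentages; jackknife importance refits each variable
  alone and omitted on shared splits. Response curves vary one variable
  over its training range with the others fixed at presence means; the
  reported threshold range is where the curve exceeds the cutoff
  (default 0.2).

## Ensembles and range maps

Each suite's selected setting is refit on 10 random 50/50 presence splits;
replicates under test AUC 0.85 are dropped (error if none survive, warning
below 3). Each survivor is binarized at its maximum
sensitivity-plus-specificity threshold computed on its own *test*
presences against the shared background — test rather than training scores
to limit optimism; a config switch restores training-side thresholds. Ties
resolve to the smallest candidate (the more inclusive map), and a cell
exactly at the threshold counts suitable. The consensus map marks a cell
suitable when strictly more than 60% of surviving maps agree (with 10 maps
that means ≥ 7). Areas use the spherical quadrilateral formula
A = R²·Δλ·(sin φ_top − sin φ_bottom), R = 6371.0088 km; centroids are
cell-area-weighted means over suitable cells. Change maps assign each cell
one of eight categories from its (current, mid, late) binary triple. The
two population maps combine by cellwise union — "suitable for either
population" — with intersection available by flag.

## Population grouping

PCA runs on the correlation matrix (standardized variables) and reports
loadings as variable–component correlations, each component signed so its
largest-magnitude loading is positive. Hierarchical clustering uses
Euclidean distance on the standardized VIF-retained variables; candidate
linkages (single, complete, average, weighted, Ward) are ranked by the
agglomerative coefficient AC = mean_i (1 − d_first(i)/d_final) and the
winner's tree is cut into k groups. Population distinctness is validated
by a two-class pooled-covariance linear discriminant fit on a random 50%
of sites (redrawn if a class is missing, rather than stratified, to keep
the split genuinely random) and scored on the held-out half, repeated
(default 1000×); proportional priors by default, equal priors available.
A singular pooled covariance is ridge-regularized at 1e−8·trace. VIF is
computed on the background sample, not the presences, and elimination is
greedy: drop the largest VIF, recompute, repeat until all are below 10.

## Synthetic data

The generator supplies study conditions with known ground truth:

* **Climate layers** are white noise smoothed by a Gaussian kernel
  (default 5 cells) for spatial autocorrelation, standardized, then
  Cholesky-mixed to a target correlation matrix — smoothing before mixing
  preserves the target. The default correlation is a two-factor model
  (temperature and precipitation): mean-temperature and total-precipitation
  layers carry loadings ≈ 0.95 and are nearly interchangeable, as in real
  bioclim stacks, while seasonality, diurnal-range, and extreme-month
  layers load weakly (0.35–0.6). A VIF screen therefore eliminates most of
  the redundant blocks and keeps the distinctive variables, mirroring how
  real analyses end up with a handful of survivors. Layers are affinely
  mapped to plausible ranges per variable (e.g. Bio01 12 ± 5 °C,
  Bio12 900 ± 300 mm).
* **Populations.** Default window 97–112°E × 22–36°N (0.05° cells at full
  scale). A western population (44 presences, lon 98–105) and an eastern
  one (23 presences, lon 105–112) carry Gaussian niches in
  (Bio04, Bio14) space: μ_West = (4.5 °C, 6 mm) with SDs (0.8, 2),
  μ_East = (8.5 °C, 26 mm) with SDs (0.8, 3). The ~5-SD separation in
  Bio04 makes the populations climatically distinct (discriminant
  misjudgment ≈ 1%) and the niche widths make fitted models strongly
  selective (test AUCs ≈ 0.93–0.98), matching what field studies of
  montane endemics report. Presences are drawn without replacement, one
  per cell, with probability proportional to the niche suitability — the
  exponential-race scheme — so the one-record-per-cell convention holds by
  construction, and true suitability surfaces are retrievable for
  parameter-recovery tests.
* **Future scenarios** are per-layer affine shifts (a·x + b); the test and
  acceptance scenarios warm Bio01 by +1.5/+2.8 °C and dry Bio14 by
  10/20%, a mid/late-century high-emission caricature.

What the generator does *not* emulate: topographically driven climate
(elevation gradients, rain shadows), sampling bias in presences,
observation error, dispersal limits, and non-Gaussian niche shapes.
Passing tests therefore demonstrate that the algorithms implement their
contracts and recover known ground truth under clean conditions — not that
any particular real species analysis is correct.

## Numerical and design choices

* Thinning bins records on a sinusoidal equal-area projection
  (x = R·λ·cos φ, y = R·φ) anchored at (0, 0); the first record per bin in
  input order wins. The bin origin is exposed because thinning counts are
  origin-sensitive at the margin.
* Cell ownership is half-open, [x_left, x_right) × [y_bottom, y_top), with
  row 0 the northernmost row; the xllcenter ASCII dialect is converted to
  corner convention on read.
* Earth is a sphere of radius 6371.0088 km throughout (haversine distances
  and cell areas); ellipsoidal refinement is out of scope.
* Niche overlap is computed on continuous (cloglog) ensemble-mean
  surfaces normalized over the shared study region for the West–East pair,
  and on the binary consensus maps for the Combination–Whole pair (the
  combination map is defined by a binary union, so a continuous analog
  would be artificial). Cells nodata in either surface are excluded before
  normalization. The I statistic is computed in the Hellinger form with
  the Bhattacharyya identity as an internal consistency check (they agree
  to 1e−12).
* Seed ladder: every random stage derives its seed as a 31-bit hash of
  (master seed, stage name, suite tag), so stages are independent and the
  whole pipeline is bit-reproducible under one master seed.
* Degenerate inputs: empty occurrence sets thin to empty; an all-zero
  suitability surface, an empty background mask, or the loss of every
  bootstrap replicate to the AUC filter raise errors naming the stage.

## Problem sizes

The test suite and the acceptance script run the landscape at 56 × 60
cells (0.25°) with 800–2000 background points, RM grids of 2–3 values,
L/LQ feature combinations, 3–5 evaluation splits, and 6–10 bootstrap
replicates; the pipeline's defaults remain the full study configuration
(10,000 background points, RM 0–4 × {L, LQ, H, LQH, LQHP, LQHPT}, 10
splits, 10 replicates). The scaled settings exercise every code path of
the full configuration on the same invariants.

## Known limitations

* The threshold feature class makes the objective piecewise-constant in
  knot placement; with few presences AICc often disqualifies it (K grows
  quickly), which matches its reputation as a high-variance class.
* The agglomerative-coefficient implementation matches R's
  `cluster::agnes` exactly for single/complete/average/Ward linkage;
  WPGMA ("weighted") merge heights differ from agnes's flexible-strategy
  heights in the third decimal on some data.
* Permutation importance clips negative AUC drops at zero before
  normalizing; a variable whose permutation *improves* AUC (sampling
  noise) reports 0%.
* The pipeline validates exactly two populations with the discriminant
  (k > 2 clustering is supported, but the misjudgment validation is
  two-class).
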