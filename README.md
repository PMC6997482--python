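# popsdm

Population-aware presence/background species distribution modeling.

Species with geographically disjoint populations often harbor local
adaptation: each population tolerates a narrower climatic envelope than the
species as a whole. Pooling all occurrences into one species distribution
model (SDM) can therefore blur or miss suitable habitat. `popsdm`
implements the population-based alternative end to end: it delineates
climatically distinct populations from occurrence records, fits a separate
maximum-entropy suitability model per population (and for the pooled data),
projects all of them under future climate scenarios, and quantifies how the
resulting ranges shift, shrink, and diverge.

The package is aimed at biogeographers and conservation planners who work
with presence-only records and gridded bioclimatic layers (Bio01–Bio19
semantics, ESRI ASCII grids), and at methodologists who want a fully
scriptable, dependency-light MaxEnt-style pipeline they can test on
synthetic data with known ground truth.

## The model

The core is a from-scratch presence/background maximum-entropy model. Given
presence cells x₁…x_m and a background sample B, the fitted suitability is
the Gibbs distribution over cells

    q_λ(x) = exp(λ·f(x)) / Z(λ),   Z(λ) = Σ_{x∈B} exp(λ·f(x)),

where f(x) are feature transforms of the climate variables — linear,
quadratic, product, forward/reverse hinge, and threshold classes (the
classic L/Q/P/H/T families), min–max scaled to [0, 1] on the background.
λ minimizes the convex L1-regularized objective

    J(λ) = −(1/m) Σᵢ λ·f(xᵢ) + log Z(λ) + Σⱼ RM·βⱼ⁰·(σⱼ/√m)·|λⱼ|,

with RM the regularization multiplier, βⱼ⁰ the per-feature-class default
weight (interpolated on m), and σⱼ the presence-sample SD of feature j.
Optimization is monotone proximal-gradient descent with Barzilai–Borwein
step seeding. Outputs come as raw, logistic, or cloglog transforms.

Around that core the pipeline provides: 20-km spatial thinning, a 500-km
great-circle study buffer, VIF-based collinearity elimination (threshold
10), correlation-matrix PCA with variable–component correlation loadings,
hierarchical clustering with linkage chosen by agglomerative coefficient,
repeated-split linear-discriminant validation of population distinctness,
(RM, FC) tuning by top-10% test AUC then minimum AICc, 10-replicate
bootstrap ensembles filtered at test AUC 0.85, maximum
sensitivity-plus-specificity binarization, strict >60% majority-vote
consensus maps, spherical area/centroid range summaries, eight-category
temporal change maps, population-map union, and niche overlap via
Schoener's D and the Hellinger-based I statistic.

## Worked example

Everything runs on synthetic data with known ground truth — no downloads:

```python
import popsdm as p

spec = p.SyntheticSpec(nrows=56, ncols=60, cellsize=0.25, seed=5)
stack = p.generate_climate_stack(spec)          # 19 correlated bioclim layers
occ = p.generate_populations(stack, spec)       # 44 western + 23 eastern presences

future = {"2050s_RCP8.5": p.generate_future_stack(
    stack, {"Bio01": {"offset": 1.5}, "Bio14": {"factor": 0.9}})}

cfg = p.PipelineConfig(background_n=800, rm_grid=(0.5, 1.0),
                       fc_combos=("L", "LQ"), eval_splits=3,
                       bootstrap_reps=6, lda_reps=100, n_knots=8, seed=5)
report = p.run_pipeline(occ, stack, future, cfg)
s = report.summary()
print(round(100 * s["lda"]["mean_misjudgment"], 2))        # 1.18
print(s["suites"]["West"]["rm"], s["suites"]["West"]["fc"])  # 0.5 LQ
print(round(s["suites"]["West"]["mean_test_auc"], 3))        # 0.968
```

The discriminant misjudges only ~1.2% of held-out sites (1.18% here), confirming the two
synthetic populations occupy distinct climates; tuning selects a linear +
quadratic feature set at RM 0.5 (a Gaussian niche is exactly
log-quadratic); and the western ensemble's mean test AUC of 0.97 says its
replicates rank presences far above background. `report.summary()` also
carries suitable areas and centroids per scenario, per-variable permutation
importances and response-curve thresholds, eight-category change counts,
and the D/I overlap series between populations and between the combined and
pooled maps.

A thin CLI wraps the same functions for shell use:

```bash
popsdm simulate --out demo --seed 3
popsdm filter --occ demo/occurrences.csv --cell-km 20 --out demo/thinned.csv
popsdm region --occ demo/thinned.csv --radius-km 500 \
    --template demo/stack/Bio01.asc --out demo/mask.asc
popsdm run --occ demo/thinned.csv --stack demo/stack --out demo/report
```

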