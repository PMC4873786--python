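# Methods

## Scope and data model

Everything spatial lives on a single north-up geographic grid
(`GridSpec`): square cells of `cell_size` degrees, cell (0, 0) at the
north-west corner, half-open cells `[edge, edge + size)` so point-in-cell
assignment is a floor. The grid is treated as WGS84-style lon/lat;
distances use the haversine formula on a sphere of radius 6371 km. For
buffer radii of 50–100 km the sphere-vs-ellipsoid error is below 0.5%,
which is negligible against the ~10 km cell size. Cell size is expressed
in degrees; a 0.125° cell is used as the nominal "10 km" cell (13.9 km
north–south, ~9 km east–west at the mid-latitudes of the reference grid),
an approximation the pipeline makes no attempt to correct for.

Raster I/O supports ESRI ASCII grids (nodata sentinel −9999, values
written as shortest round-tripping decimals so write-then-read is
bit-exact) and minimal single-band GeoTIFF through tifffile
(ModelPixelScale / ModelTiepoint / GDAL nodata tags). Bilinear resampling
interpolates cell-centre values; where some of the four neighbouring
centres are masked the weights are renormalised over the valid ones (this
keeps coastlines from eroding), and the outer half-cell rim extrapolates
linearly so planar fields are reproduced exactly.

## Response data

Thinning keeps the *set of occupied cells* and represents each by its
geometric centre, discarding record coordinates — so duplicate and
clustered records collapse automatically, and thinning is idempotent.

Pseudo-absences are rejection-sampled: draw a uniform random unmasked
cell, jitter uniformly within it, accept iff the great-circle distance to
the nearest presence centroid lies in (50, 100] km — strictly outside the
inner buffer, at most the outer limit. Rejection sampling is unbiased over
the eligible annulus; a configurable attempt cap (default 10,000 per
point) turns an empty annulus into a diagnostic `InfeasibleGeometryError`
rather than a hang. Points are continuous coordinates (cell + jitter),
not cell centroids. Each replicate dataset draws from an independent
seeded stream, so datasets are reproducible individually and jointly.

Equal-prevalence weighting assigns presence rows weight 1 and absence
rows weight n₁/n₀; the class totals then agree exactly. The weights are
used both in fitting (where the backend supports them) and in AUC
evaluation; an unweighted AUC is available via the `weights=None`
argument.

## Predictor selection

VIF of a variable is 1/(1 − R²) from an OLS regression (with intercept,
via statsmodels) of that variable on all remaining candidates; R² = 1
within 1e−12 maps to +inf. Stepwise pruning removes the current maximum
until all VIFs drop below the threshold (default 10, the classical rule
of thumb; configurable, or a pinned variable list can bypass selection
entirely). Ties break toward the earliest column, deterministically.
Selection runs once, on the pooled rows of the *first* absence dataset
with weights ignored, and the retained set is fixed for all datasets and
methods — a single refined suite for the whole run.

## The nine methods

All methods implement one contract: fit on a feature table with binary
label and case weights, predict probabilities in [0, 1], reproducible
under a seed. Defaults are pinned explicitly (`METHOD_DEFAULTS`) rather
than inherited silently from backends:

| method | backend | pinned defaults |
|---|---|---|
| ANN | sklearn MLP (scaled) | 1 hidden layer of 5, weight decay 0.01, 500 iters |
| CTA | sklearn decision tree | min leaf 5, cost-complexity α = 0.001 |
| FDA | own MARS basis + optimal scoring | 15 basis terms, 10 knots/var |
| GAM | spline basis + logistic regression | cubic B-splines, 5 knots, ridge C = 1 |
| GBM | sklearn gradient boosting | 100 trees, depth 3, learning rate 0.1 |
| GLM | logistic regression | linear + quadratic terms, unpenalised |
| MARS | own MARS basis + logistic head | 15 terms, 10 knots, C = 1e4 |
| RF | sklearn random forest | 500 trees |
| SRE | own envelope | q = 0.025 |

The MARS basis is built in-package: forward greedy selection of reflected
hinge pairs max(0, ±(x − t)) at interior-quantile knots, weighted
least squares via normal equations, then backward pruning by GCV with
penalty 2. The learner is additive (degree-1 hinges), the parsimonious
setting appropriate for smooth unimodal niche responses. FDA uses the
two-class optimal-scoring reduction — weighted least squares of the 0/1
label on the same basis, predictions clipped to [0, 1]. SRE bounds each
variable by the presence-only empirical q and 1−q quantiles
(linear-interpolation definition) and predicts 1 inside the closed box,
0 outside; it is the only presence-only and the only binary-output
member. ANN is the one method whose backend accepts no case weights, so
it fits unweighted; all other methods honour the equal-prevalence
weights. MLP runs can hit the iteration cap on hard tables; the fit is
kept as long as predictions are finite, mirroring the
"flagged-but-usable" convention.

## Evaluation and ensemble

Each (method, absence dataset) is scored by `n_repeats` random 70/30
splits; a split is re-drawn (warned, capped at 100) if either part is
single-class. Splits are *shared across methods within a dataset* so
method comparisons are paired; split seeds, model seeds and shuffle seeds
all derive from the master seed by hashing (BLAKE2), avoiding correlated
streams. The final per-(method, dataset) model is refit on all rows and
carries the mean AUC of its repeats.

AUC uses the Mann–Whitney formulation (probability a random positive
outscores a random negative, ties 0.5), computed by sklearn's
`roc_auc_score` with case weights — each (+,−) pair contributes w⁺·w⁻ —
and verified in the tests against an explicit all-pairs oracle.

Member selection drops any method whose overall mean AUC is below a
floor (default 0.8); an explicit drop list overrides, mirroring the
judgment call of excluding a systematically weaker envelope model.
Ensemble weights are proportional to mean AUC, wᵢ = AUCᵢ/ΣAUCⱼ. This is
the simplest weighting that is strictly increasing in AUC; rank-decay
alternatives exist in the literature but proportional normalisation is
the package's choice. The EMmw prediction averages within a method over
its per-dataset final models first, then combines methods by weight —
the collapse rule from ten absence datasets to one member per method is
otherwise underdetermined, and within-method averaging is the stated
choice. The ensemble's own cross-validated AUC reuses the members'
held-out predictions on the identical splits, giving per-(dataset,
repeat) EMmw records; the Welch unequal-variance t-test then compares
ensemble records against the retained individual records. (A published
comparison against a single ensemble value is not a reproducible test;
the per-repeat pairing here is the package's resolution, and the
returned t, df, p come from scipy with the Welch–Satterthwaite df.)

Randomization importance permutes one predictor column, re-predicts, and
scores 1 − r (Pearson). The default averages 3 seeded shuffles — a single
shuffle is the minimal version, but averaging reduces Monte-Carlo noise
at trivial cost. If the permuted predictions are constant while the
originals are not, r carries no signal and is taken as 0. Ensemble
importance applies the ensemble weights to per-method mean scores, sums
by variable, divides by the number of members (a pure rescaling that
never reorders), and converts to percentages of each row's total.

## Pressure and risk

National totals are spread over each region's cells proportionally to a
discharge raster; per-region sums equal the totals to floating-point
accuracy, and a positive total over a zero-discharge region is an error
naming the region. Cells outside any region are masked (no data), not
zero (no pressure). The distributed layer is resampled bilinearly to the
analysis grid and then min-max rescaled to [0, 1]; a
`normalize_first` toggle swaps the order for strict emulation of
pipelines that resample a pre-scaled layer. Both the EMmw suitability
and the pressure layer are rescaled to [0, 1] before the product, so the
two factors enter the risk map with equal weight; the product is bounded
by min(suitability, pressure) and masked wherever either factor is.

## The virtual species

The generator emulates the inputs the real workflow would download:

- predictors are Gaussian-smoothed white noise (smoothing length
  `autocorr_cells`, default 6 cells), standardized to mean 0, sd 1 —
  spatially autocorrelated like climate surfaces; a collinear pair
  (a, b, r) rebuilds b as r·a + √(1−r²)·b, emulating the strong
  inter-variable correlations of bioclimatic suites (default: one pair
  at r = 0.99 between two non-effect variables, so VIF pruning is
  exercised on every run);
- true suitability is logistic(β₀ + Σ βᵥxᵥ + Σ γᵥxᵥ²) with negative γ —
  the simplest form producing the unimodal environmental preferences
  reported for real niches. Reference conditions: 3 effect variables of
  10, β = (1.0, 0.8, 0.6), γ = (−2.0, −1.6, −1.2), intercept 1;
- presences are 300 distinct cells sampled with probability proportional
  to true suitability and placed at cell centroids (duplicate records for
  thinning tests are added deliberately in fixtures);
- pressure inputs are Voronoi-block regions from random centres, a
  log-Gaussian discharge field, and log-uniform totals in [1, 100].

What the generator does *not* emulate: coastlines and masks, anisotropic
climate gradients, sampling bias in occurrence data, and observation
error. Passing recovery tests therefore demonstrates the machinery is
correct and self-consistent — not that any particular real species'
map would be accurate.

The reference grid is 64 × 64 cells of 0.125° with north-west corner
(0° E, 50° N): binary-representable geometry (edges and centroids are
exact in floating point, so file round-trips are bit-exact) spanning
~8°, within which the 50–100 km annulus around a 300-cell presence cloud
occupies roughly a fifth of the grid — comfortably feasible for
rejection sampling.

## Problem sizes and numerical choices

- The full-design check runs the complete 9 methods × 10 absence
  datasets × 10 repeats factorial (900 fits, 1300-row tables) on the
  64 × 64 reference grid; the recovery experiment uses 4 methods
  (GLM, RF, GBM, SRE) × 3 datasets × 3 repeats over 3 master seeds,
  passing on a majority of seeds. These sizes exercise every code path
  at full design arithmetic while keeping a complete run in minutes on
  one CPU.
- Quantiles (SRE, MARS knots) use the linear-interpolation definition.
- Normal-equation solves in the MARS learner add a 1e−9 ridge for
  numerical stability; GCV penalty is 2 per extra term pair.
- `normalize01` refuses constant grids (the [0, 1] contract is
  unsatisfiable); this propagates deliberately from degenerate pressure
  configurations such as a single region with uniform discharge.
- Annulus bounds are open at 50 km, closed at 100 km.
- Seeds derived from the master seed are 31-bit BLAKE2 hashes of
  (master, stage, index).

## Known limitations

- Geographic degrees are treated as the grid metric; no equal-area
  handling, no antimeridian crossing, single-band rasters only.
- The MARS learner is additive; interaction hinges are out of scope.
- ANN ignores case weights (backend limitation); with the default
  near-balanced designs this is minor but it is not corrected for.
- The explicit member drop list is a modelling judgment the package
  exposes but does not automate beyond the AUC floor.
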