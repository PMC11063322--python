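# Methods

This note records the statistical conventions, numerical choices and design
decisions behind `vegtrend`, and what its synthetic-scene validation does and
does not demonstrate.

## Raster model

A `RasterGrid` is one 2-D float band with a boolean NoData mask, a north-up
affine transform (square cells in metres, row 0 northernmost, cell-centre
registration) and an opaque CRS tag. Reprojection between coordinate systems
is out of scope: grids must already share a lattice, and geometry mismatches
are contract errors rather than silent resampling. GeoTIFF I/O goes through
`tifffile`, writing the standard GeoTIFF tags (ModelPixelScale,
ModelTiepoint, a minimal GeoKey directory carrying the CRS tag as a citation
string) and the GDAL_NODATA convention with fill value −9999; data are
stored float32, so round trips are exact to float32 precision.

Harmonization keeps spatial and temporal compositing orthogonal:

- coarsening by an integer factor on an aligned grid uses the unmasked-cell
  block mean (continuous) or majority vote with ties to the smallest code
  (categorical);
- refining uses bilinear interpolation (continuous) or nearest neighbour
  (categorical), with nearest-neighbour fallback where a bilinear corner is
  NoData;
- maximum-value compositing is a separate, purely temporal per-pixel
  maximum over unmasked epochs.

NoData is never invented: an output cell is masked only when every
contributing source cell is masked, and window/series statistics report the
count of values actually used.

The fishnet lattice is anchored at the sampling extent's lower-left corner
with points at cell centres of the spacing×spacing lattice (default spacing
3,000 m); only centres inside the extent are kept, so for exact-multiple
extents the count is ⌈w/s⌉·⌈h/s⌉. Point sampling reads the nearest cell
centre; a NoData or out-of-extent lookup yields a missing value and clears
the row's valid flag.

## Trend statistics

The Theil–Sen slope is the median of all pairwise slopes; an even pair count
takes the mean of the two middle slopes (`numpy` median). Pairs at identical
times are skipped. The Mann–Kendall statistic uses the standard tie-corrected
variance and the ±1 continuity correction; with fewer than 4 valid epochs
Var(S) is not meaningful and the pixel is reported missing (the Sen slope
alone is defined from 2 points, but the joint trend product requires 4, the
package default `min_epochs`).

Trend classes are the product of the slope sign with the |Z| bins cut at
1.65, 1.96 and 2.58 — the two-sided normal nodes near α = 0.10, 0.05, 0.01 —
kept as literal thresholds rather than recomputed quantiles. Codes are
signed: +1…+4 (not significant → highly significant increase), −1…−4 for
decreases, and 0 for a zero slope or an undefined pixel. This is the only
partition of "eight classes" consistent with three Z nodes and two signs;
the no-change code is kept separate so class-area tables always sum to 100%
of the valid area.

No pre-whitening is applied: the intended inputs are annual growing-season
composites, where serial autocorrelation is weak compared to the monthly
case. Seasonal MK variants are out of scope.

The temporal standard-deviation map uses the population denominator n, and
masks pixels with fewer than 2 valid epochs.

## Cover classes and transfer matrix

Cover breaks are 0.2/0.4/0.6/0.8 with left-closed/right-open intervals and
the top class closed — so NDVI = 0.4 is "medium", a documented convention
(interval ownership at the break is a free choice; any consistent closure
works). Negative NDVI is classed low rather than masked, because lake and
bare surfaces are legitimately part of the low-cover area unless a water
mask is applied upstream. Areas are pixel-count × cell area in km²; no
vectorization or sub-pixel estimation. The transfer matrix counts only
pixels valid at both dates, which makes its conservation identities exact:
total = jointly valid area, row sums = date-1 class areas, column sums =
date-2 class areas.

## Sensor comparison

The conversion equation is an OLS fit over fishnet samples, pooling epochs
by default (per-epoch fits are available); the finer sensor is the predictor
x by convention and the direction is recorded in the result. R² = r² is an
identity for this fit and is asserted rather than assumed. Note that when
the predictor itself carries independent noise the slope estimate attenuates
(errors-in-variables); the synthetic sensor link adds noise only on the
coarse side, so recovery tests are unbiased.

## Geographical detector

q is computed from sums of squared deviations (the population form
N_h σ_h²): q = 1 − SSW/SST exactly, for any stratum sizes. The σ² notation
in the defining ratio is ambiguous between sample and population variance,
but only the population convention makes the ratio independent of the
per-stratum denominators; this choice is oracle-tested.

Factor significance defaults to the noncentral-F transform standard in the
geodetector literature: F = (N−L)/(L−1) · q/(1−q) with noncentrality
λ = [Σ_h ȳ_h² − (Σ_h √N_h ȳ_h)²/N]/σ², compared against the noncentral
F(L−1, N−L; λ) distribution. A seeded permutation test (default 999
shuffles, p = (1 + #{q* ≥ q})/(B + 1)) is the assumption-free alternative.

Interaction categories follow the canonical five-way scheme on
(q1, q2, q12): below min → nonlinear weaken; between min and max →
single-factor nonlinear weaken; at/above max but below the sum → two-factor
enhancement; equal to the sum (±1e−10) → independent; above the sum →
nonlinear enhancement. Empty intersection cells are dropped, not imputed.
The category function is total on [0,1]³.

The ecological detector reports F = N_X1(N_X2−1)SSW_X1 / [N_X2(N_X1−1)SSW_X2]
as a one-sided test at α = 0.05 against F(N_X1−1, N_X2−1); a zero SSW in the
denominator reports infinite F, significant, with a degeneracy flag. The
risk detector uses Welch t with sample variances (ddof = 1) and
Welch–Satterthwaite degrees of freedom, two-sided at 95% confidence; strata
with n < 2 keep their mean but are excluded from the tests, and the "best"
stratum is the argmax of the stratum means.

Discretization methods: equal-width; quantile; Fisher–Jenks natural breaks
(exact O(kn²) dynamic program over prefix sums, subsampled to 2,000 values
above that size, with boundaries reported as midpoints so left-closed
labelling preserves the optimal classes); geometric (log-spaced breaks on
the shifted-positive range); and standard-deviation bands one SD apart
centred on the mean, clipped to the data range. Labels are left-closed;
empty strata are merged with a warning; a constant covariate yields a single
stratum flagged unusable. Optimal discretization searches methods ×
k ∈ 3..8 and returns the argmax-q assignment, breaking ties toward smaller k
then method order. Because q never decreases under refinement, the search
tends to prefer large k for noisy data; the reported q of an irrelevant
driver at n = 1000 stays below ≈ 0.05, which is the relevant calibration.

## Synthetic scenes

Generators emulate three structures with exactly known truth, all with
Gaussian noise (configurable SD) and single-Generator seeding for bit
reproducibility:

- trend scenes: value = base + slope·(t − t₀) + ε on rectangular slope
  regions (default 100×100 cells of 250 m, 7 annual epochs 2016–2022, base
  0.3, slopes 0 and +0.02 NDVI/yr, noise SD 0.01, matching a short
  annual-composite monitoring record);
- stratified responses: y = μ_h + ε with theoretical
  q* = Var_b/(Var_b + σ_w²), plus a monotone continuous carrier of the
  strata;
- sensor pairs: block-mean aggregation then gain·v + bias + ε (defaults
  gain 1, bias 0.05, noise SD 0.01 — an NDVI-scale inter-sensor offset).

These scenes omit much of real imagery: spatial autocorrelation of noise,
clouds and atmospheric artifacts, sensor spectral response differences,
phenology, and irregular geography. Passing the validation therefore shows
the estimators are implemented correctly and calibrated under their own
assumptions (iid Gaussian noise, linear trends, affine sensor links), not
that real scenes meet those assumptions.

## Pipeline

Stages run in a fixed order — stack load, trend + SD maps, cover classes and
first-to-last transfer matrix, fishnet sampling of the temporal-mean NDVI,
sensor comparison, detector report — and are gated by input presence rather
than flags. All randomness derives from the single configured seed; CSV
floats are formatted with `%.10g` and newline-normalized, so re-running an
unchanged config is byte-identical (verified by SHA-256 in the run
manifest, which lists every file written).

## Problem sizes and runtime

Validation uses 100×100 × 7-epoch trend scenes, 10,000-sample q recovery,
10,000 null replicates for the Mann–Kendall type-I check, and 1,000 random
series for the pairwise-oracle equivalence — sizes at which the Monte-Carlo
error of each check is far below its decision margin while the full suite
runs in seconds.

## Known limitations

- No CRS reprojection, atmospheric correction, or cloud masking; inputs
  must be preprocessed, co-registered products.
- No correction of q for spatial autocorrelation; with strongly
  autocorrelated residuals the effective sample size is smaller than N and
  factor p-values are optimistic.
- The Mann–Kendall test assumes serial independence; monthly or finer series
  would need pre-whitening or a seasonal variant.
- Transfer matrices are pixel-count exact but ignore sub-pixel mixing, so
  class-change areas at coarse resolution inherit the mixing bias of the
  classification itself.
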