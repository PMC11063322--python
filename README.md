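# vegtrend

Tools for quantifying vegetation dynamics from NDVI raster time series and
attributing them to environmental drivers. The package targets the analysis
chain used in arid-zone vegetation monitoring: harmonize multi-sensor NDVI
stacks onto a common grid, map per-pixel trends with the Theil–Sen /
Mann–Kendall pair, account for vegetation-cover class transitions between
dates, compare sensors through fishnet-point conversion equations, and
attribute the spatial pattern of NDVI to candidate drivers with the
geographical detector.

It is written for remote-sensing ecologists who have per-epoch NDVI (or
climate) GeoTIFFs and driver layers or sample tables, and want a scripted,
reproducible alternative to the usual ArcGIS + spreadsheet workflow. All
stages also run on seeded synthetic scenes with known ground truth, so every
estimator in the chain can be validated end to end.

## Methods at a glance

**Trend.** For each pixel's series $v_1,\dots,v_n$ at years $t_1,\dots,t_n$:

- Theil–Sen slope $\beta = \mathrm{median}_{i<j}\,(v_j - v_i)/(t_j - t_i)$;
- Mann–Kendall $S = \sum_{i<j}\mathrm{sign}(v_j - v_i)$, with tie-corrected
  $\mathrm{Var}(S) = [n(n-1)(2n+5) - \sum_t t(t-1)(2t+5)]/18$ and the
  continuity-corrected standardization $Z = (S \mp 1)/\sqrt{\mathrm{Var}(S)}$;
- a signed eight-class trend label from $\mathrm{sign}(\beta)$ and $|Z|$
  against the nodes 1.65, 1.96, 2.58.

**Cover.** NDVI is cut into five equal-interval classes (breaks 0.2, 0.4,
0.6, 0.8); the transfer matrix cross-tabulates class areas (km²) between two
dates, with row/column marginals equal to the per-date class areas.

**Sensors.** Two stacks harmonized to one grid are sampled at a regular
fishnet (default 3 km spacing) and related by the OLS conversion equation
$y = a x + b$ with $R^2$ and Pearson's $r$ ($R^2 = r^2$ for this fit).

**Drivers.** The geographical detector measures the power of a stratification
$h = 1,\dots,L$ of space (a discretized driver $X$) to explain response $Y$:

$$q = 1 - \frac{\mathrm{SSW}}{\mathrm{SST}}, \qquad
\mathrm{SSW} = \sum_h N_h \sigma_h^2, \quad \mathrm{SST} = N \sigma^2 .$$

Factor significance uses the noncentral-$F$ transform of $q$ (a seeded
permutation test is available); interactions compare $q$ of two factors'
cross-classification with their individual values; the ecological detector's
$F$-ratio compares two factors' within-strata variance; the risk detector
runs pairwise Welch $t$-tests on stratum means. Continuous drivers are
discretized by equal-width, quantile, Fisher–Jenks natural-breaks, geometric
or standard-deviation breaks, choosing the (method, $k$) pair that maximizes
$q$.

## Worked example

Simulate a 100×100, 7-epoch NDVI scene (flat left half, +0.02 NDVI/yr right
half, noise SD 0.01) and map its trends:

```sh
$ vegtrend simulate trend --out scene --seed 7
wrote 7 epochs to scene
$ vegtrend trend --stack scene/manifest.csv --out trendmaps
trend products in trendmaps
$ cat trendmaps/trend_class_percent.csv
trend_class,percent
-4,0.04
-3,0.69
-2,0.82
-1,23
1,23.59
2,1.07
3,4.09
4,46.7
```

Nearly all flat-half pixels land in the not-significant classes (codes ±1,
together ≈ 47%), while most greening-half pixels reach the highly
significant increase class (+4, 46.7% — the trend half is 50% of the scene).

Sensor cross-calibration against a 5×-coarser counterpart with a known
+0.05 bias:

```sh
$ vegtrend simulate sensors --out pair --seed 7
$ vegtrend compare --a pair/fine/manifest.csv --b pair/coarse/manifest.csv --out fit.csv
y = 1.0013 x + 0.0497  (R² = 0.9419, Pearson = 0.9705, n = 448)
```

The fitted conversion equation recovers the unit gain and the 0.05 bias.

Driver attribution on a stratified sample whose true explanatory power is
q = 0.5:

```sh
$ vegtrend simulate strata --out strata --seed 7 --n 1000
wrote 1000 samples (theoretical q = 0.5000) to strata
$ vegtrend detect --table strata/samples.csv --response ndvi --categorical stratum --out report
 factor        q       p_value  L      method
 driver 0.463471 4.379786e-116  8       equal
stratum 0.460560 2.101093e-127  2 categorical
```

Both the true stratum labels and the continuous driver carrying them recover
q ≈ 0.46 (the finite-sample value for this draw), highly significant under
the noncentral-F test. `vegtrend run --config run.yaml` chains all stages
and writes a manifest with per-file SHA-256 checksums.

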