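# Methods

`paleodiet` implements a complete chain for asking whether local climate or
relative population size better predicts individual bone-collagen isotope
values (δ¹⁵N‰, δ¹³C‰) across millennial time scales, together with a
synthetic-data generator that makes every stage testable against a known
ground truth. This note records the models, the defaults and why they were
chosen, and the limits of what the synthetic benchmarks demonstrate.

## Data model and inclusion rules

An *individual* is one skeletal sample: isotope values, collagen C:N ratio,
location (lat/lon, elevation in masl, distance to coast in km), a cultural
period, and a death window in calendar years BP (present = 1950 CE), either
a period-based window or a direct ¹⁴C measurement.

Inclusion filters, applied in a fixed order so counts are reproducible
(age → C:N → period):

* individuals known to be under five years old are dropped (weaning
  enrichment); unknown ages are retained, since exclusion requires evidence;
* the collagen C:N atomic ratio must lie in 2.9–3.6, or the reporting author
  must have explicitly accepted the sample (in practice extending the range
  to about 2.6–3.6), or the ratio may be missing if the source study
  validated all of its samples;
* Colonial-period individuals are dropped to keep the series pre-contact.

Elevation zones partition the (elevation, distance-to-coast) plane with
strict thresholds: coastal iff elevation < 350 masl *and* distance < 15 km;
highland iff elevation > 3500 masl; mid-elevation otherwise. A sample at
exactly 350 or 3500 masl is mid-elevation.

## Radiocarbon calibration

A measurement (age ± σ, in ¹⁴C yr BP) is calibrated against a 3-column
curve (calBP, μ, σ_curve) by evaluating, on a 1-yr calendar grid
interpolated linearly from the curve knots,

    w(t) ∝ N(age − ΔR; μ(t), sqrt(σ² + σ_curve(t)² + σ_ΔR²))

normalizing to a probability mass function, trimming masses below 1e−5 of
the peak (a common calibration-software convention that bounds support with
negligible mass loss) and renormalizing. Marine samples subtract a local
reservoir offset ΔR and inflate the variance by its error. One curve is
used per date, selected by the marine flag; hemisphere mixing is out of
scope. The grid resolution and trimming floor are configurable.

## Dates-as-data demography

Relative population size per elevation zone is proxied by the temporal
frequency of radiocarbon dates. Date QC drops ages > 15,000 BP, errors >
200 yr, duplicated lab ids, and dates without coordinates (with a per-site
exemption hook for compilations known to be single-zone). Date compilations
carry no distance-to-coast column, so a date's zone uses elevation alone:
below 350 masl counts as coastal, above 3500 masl as highland. Within each
site, dates are clustered on their median calibrated year by
complete-linkage agglomerative clustering cut at 200 yr; each cluster is a
*bin*.

The composite KDE ensemble draws, per fit, one calendar year per date from
its calibrated density, weights each date by 1/bin_size, and evaluates a
Gaussian KDE with a fixed 50-yr bandwidth on a 20-yr calendar grid
(0–7400 BP by default, aligned with the climate step), renormalized to
integrate to 1. 1000 fits is the full-study default. Choices and why:

* **bandwidth 50 yr** — no canonical value exists; 50 yr is common
  dates-as-data practice and comparable to the 20-yr climate step; it is
  configurable and recorded in the ensemble metadata;
* **1/bin-size weighting** rather than sampling one date per bin —
  preserves within-bin chronological spread while equalizing bin influence;
* **binning metric and linkage** (median calibrated year, complete linkage)
  are recorded in metadata rather than silently assumed.

The taphonomic correction divides each fit by the relative survival
proportion s(t) = n(t)/n(t_ref), with the global power-law survival model
n(t) = 5,726,442 · (t + 2176.4)^−1.3925309 and t_ref the youngest grid
year, then renormalizes. The correction factor increases strictly with age.

## Monte-Carlo exposure assignment

Each individual's covariates are means over resampled death years: uniform
over whole years of the window, or weighted by the calibrated density
(restricted to the window) when directly dated. The analysis span is
clamped to 7000–140 BP — the climate simulation ends at 140 BP — and
windows crossing it are truncated with a warning. Climate values come from
the nearest grid-cell center at the nearest 20-yr step (ties to the younger
step; the coarse grid justifies lookup over interpolation). The population
covariate draws, per iteration, a uniformly random KDE fit, then a window
year, and keeps that fit's density at that year; 10,000 draws is the
full-study default, and the mean of draws is the covariate. Sampling both
the fit and the year propagates reconstruction *and* dating uncertainty
into the design matrix.

## Trend ensembles

Isotope-vs-time trends per zone are ensembles of penalized-spline fits: per
run, one death year per individual is resampled and a cubic B-spline
smoother (basis dimension 10) with a second-divided-difference penalty is
fit, the smoothing parameter chosen by generalized cross-validation over a
log-spaced grid. The penalty uses divided differences with respect to the
Greville abscissae so that linear signals are reproduced exactly even with
repeated boundary knots, and is scaled so λ is roughly scale-free.
Pointwise standard errors come from the Bayesian posterior covariance
σ²(B'B + λP)⁻¹, which accounts for smoothing bias and gives near-nominal
interval coverage, unlike the narrower frequentist sandwich form.
Predictions clamp outside the observed year range rather than extrapolate.

Across runs the pointwise mean fit, mean standard error and SD of fits are
aggregated; the 95% band is mean ± 1.96·sqrt(mean_se² + sd²), pooling
within-fit uncertainty and between-run (dating) spread. This band
construction is a pragmatic combination rule, not an exact interval; on
synthetic data it covers a known truth at well over 85% of grid points.
Full-study default is 10,000 runs; the test suite uses a few hundred, which
changes Monte-Carlo noise, not structure.

## Driver model

The regression of isotope value on the five covariates (four climate means,
one population mean — uncorrected or taphonomically corrected KDE, giving
two model variants per isotope) is a random forest: 500 trees, ⌊p/3⌋
candidate variables per split (= 1 for p = 5), minimum node size 5, seeded.
Pairwise Pearson correlations are screened at |r| ≥ 0.70; flagged pairs are
reported but retained (tree ensembles tolerate correlated predictors).
Model quality is summarized by tenfold cross-validation: RMSE and the
VEcv-style percent of variance explained from pooled out-of-fold
predictions. Residual diagnostics: temporal autocorrelation of out-of-fold
residual means binned to 20-yr steps of mean death year, and Moran's I with
unstandardized inverse great-circle-distance weights (distances floored at
1 km), with the closed-form expectation −1/(n−1), a normal-approximation
standard deviation, and a two-sided p-value.

## Effect decomposition

For covariate j and a fitted model F̂, the centered partial dependence over
an evaluation grid v₁..v_m is PD_j(v_k) = mean_i F̂(x_i with x_ij := v_k),
centered across k; the complement PD_−j(i) is the row mean, centered across
i. Friedman's H for j is

    H_j = Σ_{i,k} (f_ik − PD_j(v_k) − PD_−j(i))² / Σ_{i,k} f_ik²

with f the grand-mean-centered prediction matrix; H is 0 for a model
additive in j and 1 when the whole joint effect is interaction. The
explained sum of squares SS_j = Σ_k PD_j(v_k)² is deducted to
SS_j · (1 − H_j) (a (1 − H²) variant is available, as verbal definitions of
the deduction differ), averaged over Monte-Carlo iterations in which the
m-point grid is resampled with replacement from the covariate's observed
values (full-study defaults: 100 iterations × 100 values). Effects are
reported in per-mil space as sqrt(SS), and as a percent of total
variability, 100 · sqrt(SS_deducted)/sqrt(SS_total) with
SS_total = (1/n)·Σ_{i,k} f_ik². The squared (sum-of-squares) forms are used
throughout: the "explained sum of squares" and "proportion" definitions
require them, matching the standard Friedman–Popescu statistic. Cumulative
climate (sum of the four climate per-mil effects) is compared with the
demography effect per zone, per isotope, per KDE variant. Because the grid
is a resampled subset, percentages do not sum to 100.

**Attribution noise floor.** A genuinely irrelevant covariate does not get
a zero effect from a forest fit to noisy data: trees with one candidate
variable per split and small leaves fit some noise along every feature. At
n = 2000 with 15% noise variance this floor is ≈0.4% of total variance —
but the per-mil/percent scale is a square root, which inflates it to ≈6–10%
of sqrt-total-variability. Judged as a share of the *summed* per-mil
effects, the null covariate carries ≈3–5%. Interpreting small single-digit
percent effects as real is therefore not supported; the package's own
benchmark treats a null share under 5% of the summed effects as recovery.

## Synthetic-data generator

The generator emulates every input at study scale with a known
data-generating process:

* **Calibration curve**: identity plus a smooth zero-mean wiggle (smoothed
  white noise scaled to a chosen amplitude, clipped at ±3 amplitudes) on a
  5-yr knot grid, σ = 10 ¹⁴C yr. Zero amplitude gives the exact identity.
* **Climate**: a regular 2.5° grid (default 6×5 = 30 cells, matching a
  Central-Andes-sized footprint) with, per variable, a cell mean (base +
  gradients + random cell anomaly) and a stationary AR(1) series (default
  lag-1 coefficient 0.7 at 20-yr steps). Each variable has its own gradient
  axis and the four variables' cell anomalies are made mutually orthogonal:
  in a 30-cell grid, chance correlations between independent anomaly draws
  reach ±0.3, which would confound the designed-null benchmark with real
  collinearity. Orthogonalization makes cross-variable correlation reflect
  only designed structure. Precipitation variables are clipped at zero.
* **Dates**: calendar death years drawn proportional to a chosen population
  curve (a two-bump curve is provided), converted through the curve mean
  plus Gaussian error; heavy-tailed site sizes exercise the binning.
* **Individuals**: uniform true death years over the span, zone-consistent
  locations, a window of configurable width (default 200 yr) containing the
  true year, and a 9% directly-dated fraction. The response is
  y = intercept + total_sd · (Σ_j sqrt(s_j)·z_j + sqrt(s_int)·z(z_a·z_b) +
  sqrt(s_noise)·ε), with every component empirically standardized, so
  sample variance shares equal the requested shares by construction.
  Default shares: temp 0.25, temp seasonality 0.15, precip 0.30, precip
  seasonality 0 (the designed null), temp×precip interaction 0.05,
  population 0.10, noise 0.15 — climate 0.75 in total. Default scale:
  intercept 10‰, total SD 2‰, typical of δ¹⁵N series.

What the generator does **not** emulate: real Andean climatology or
calibration curves, spatially uneven sampling, age-class structure,
inter-lab offsets, mobility (covariates are taken at one location), or any
dependence of preservation on climate. Passing benchmarks therefore shows
the machinery recovers known structure under the stated noise and dating
uncertainty — not that real-data effect sizes of similar magnitude are
correct.

## Benchmark scales and numerical choices

The recovery benchmark (`paleodiet.experiments.run_recovery_replicate`)
uses n = 2000 individuals, 25 effect iterations, an m = 30 grid, 150 trees,
400 exposure draws and 300 partial-dependence evaluation rows per zone —
sizes chosen so a 20-replicate study runs in about ten minutes on one CPU;
they reduce Monte-Carlo precision, not the structure being tested. The
pipeline's full-study defaults remain 10,000 draws / 1000 fits / 10,000
runs / 100×100 effect iterations. Degenerate inputs are handled explicitly:
zero-variance climate cells yield z = 0 with a warning; a single trend run
reports zero between-run SD with a warning; an all-zero prediction matrix
reports H = 0 with a warning; already-corrected ensembles refuse a second
taphonomic correction. All randomness flows from per-stage streams derived
by hashing a master seed with the stage name, so stages are independently
reproducible and full reruns are byte-identical.

## Known limitations

* The exposure means attenuate covariates (window means vs. value at
  death), which lowers explained variance and inflates the forest's
  attribution floor; narrower windows or direct dates reduce this.
* The per-mil normalization of effect sizes depends on the evaluation-grid
  size m; effects are comparable within a configuration, not across m.
* Moran's I uses a dense n×n weight matrix — fine at study scale (10³–10⁴),
  not intended for much larger n.
* The composite KDE is a relative, not absolute, population proxy; only
  comparisons over time within a zone are meaningful.
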