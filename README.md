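# paleodiet

Did local climate or regional population size drive long-term dietary
change? `paleodiet` is a Python library for answering that question from
bioarchaeological stable-isotope records: bone-collagen δ¹⁵N‰ and δ¹³C‰
values of individuals spread unevenly over space and several millennia,
paired with gridded paleoclimate simulation output and a radiocarbon date
compilation. It is aimed at archaeologists and paleoecologists who want the
full uncertainty chain — dating, calibration, demographic reconstruction —
propagated into driver attribution, rather than point estimates.

## What it computes

1. **Quality control and zoning** (`paleodiet.qc`) — inclusion filters
   (minimum age 5 yr, collagen C:N in 2.9–3.6 with author-override rules,
   pre-Colonial only) and elevation zones: coastal (< 350 masl and < 15 km
   to coast), highland (> 3500 masl), mid-elevation otherwise.
2. **Radiocarbon calibration** (`paleodiet.calibration`) — for a
   measurement *a ± σ* and curve (μ(t), σ_c(t)), the calendar-year density
   p(t) ∝ N(a − ΔR; μ(t), √(σ² + σ_c(t)² + σ_ΔR²)), with marine reservoir
   offsets, trimming, sampling and medians.
3. **Dates-as-data demography** (`paleodiet.demography`) — per-zone
   composite KDE ensembles (one calendar draw per date per fit, 1/bin-size
   site weighting via 200-yr complete-linkage binning), and the taphonomic
   correction n(t) = 5,726,442·(t + 2176.4)^−1.3925309 applied as a relative
   survival proportion.
4. **Monte-Carlo exposure assignment** (`paleodiet.exposure`) — per
   individual, the mean over resampled death years (calibration-weighted
   when directly dated) of the four climate variables and of the KDE
   population proxy; plus per-cell climate z-score series.
5. **Trend ensembles** (`paleodiet.trends`) — thousands of penalized-spline
   fits of isotope on resampled year, aggregated to a central tendency with
   a 95% band of mean_fit ± 1.96·√(mean_se² + sd²).
6. **Driver models** (`paleodiet.forest`) — random-forest regression of
   isotope on the five covariates, tenfold cross-validation (RMSE, %
   variance explained), collinearity screen at |r| ≥ 0.70, residual acf and
   Moran's I on inverse-distance weights.
7. **Effect decomposition** (`paleodiet.effects`) — centered partial
   dependence per covariate, Friedman's H interaction proportion
   H_j = Σ(f − PD_j − PD_−j)²/Σf², interaction-deducted explained sum of
   squares SS_j·(1 − H_j), reported in per-mil space (√SS) and as percent
   of total variability, with cumulative climate vs. demography tables.
8. **Synthetic studies** (`paleodiet.synthetic`) — a generator for every
   input with known variance shares per covariate, so the whole chain is
   testable for parameter recovery end to end.

A thin CLI (`paleodiet run simulate|qc|calibrate|kde|assign|trends|model|
effects|report|all`) orchestrates the stages over CSV/JSON artifacts with
one master seed; `examples/` contains one short narrative script per
capability.

## Worked example

Calibrate one radiocarbon date and reconstruct a population curve
(`examples/02_calibrate_date.py`, `examples/03_population_kde.py`):

```
$ python examples/02_calibrate_date.py
median calendar age: 3005 cal BP
95% interval: 2938 - 3055 cal BP (222 grid years retained)
five Monte-Carlo calendar-year draws: [3006. 3049. 2963. 3049. 2985.]

$ python examples/03_population_kde.py
date QC kept 800 of 836
dates: 800, site bins: 321, fits: 200
correlation of ensemble mean with the true curve: 0.959
taphonomic correction boosts the oldest grid year by x1.83 (relative to the youngest)
```

The 3000 ± 25 ¹⁴C yr measurement maps to a ~120-yr calendar interval
because curve wiggles and curve error add to the lab error. The composite
KDE rebuilt the known two-bump population history from 800 noisy dates
(r = 0.96 with the truth), and the taphonomic correction boosts old,
preferentially-lost material — by ×1.83 at 7400 vs 0 cal BP here.

`examples/05_drivers_and_effects.py` runs the full driver analysis on a
synthetic study whose response is 75% climate, 10% population and 15%
noise by construction, and prints the per-zone cumulative climate vs.
demography effect table:

```
         zone  cumulative_climate_permil  ...  climate_over_demography
      coastal                   9.086115  ...                 3.938295
     highland                   9.321108  ...                 3.945968
mid-elevation                   9.328949  ...                 4.167993

cross-validated variance explained: 61.2% (RMSE 1.16 permil)
climate outranks demography in every zone: True
null covariate share of summed effects: 2.0%
```

The recovered cumulative climate effect exceeds demography's roughly
four-fold in every zone, matching the generator's built-in dominance; the
variance explained sits below the 85% signal share because the Monte-Carlo
window means attenuate the covariates, and the deliberately irrelevant
covariate keeps a small residual share — the attribution noise floor.

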