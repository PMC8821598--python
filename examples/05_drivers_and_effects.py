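"""Ask whether climate or population better predicts synthetic diets.

Runs one seeded replicate of the full chain: synthetic study (climate holds
75% of the response variance, population 10%, noise 15%, precipitation
seasonality deliberately irrelevant), Monte-Carlo exposure assignment,
random-forest driver model, and interaction-deducted partial-dependence
effect sizes, compared cumulatively per elevation zone.
"""

from paleodiet.experiments import run_recovery_replicate

r = run_recovery_replicate(seed=1, cv=True)
print(r.cumulative.to_string(index=False))
print(f"\ncross-validated variance explained: "
      f"{r.cv_pct_variance_explained:.1f}% (RMSE {r.cv_rmse:.2f} permil)")
print(f"climate outranks demography in every zone: {r.climate_wins_all_zones}")
print(f"null covariate share of summed effects: {r.null_effect_share:.1f}%")
# Cumulative climate effect (sum of the four climate variables' per-mil
# effects) should exceed demography's several-fold, matching the generator's
# built-in 0.75 vs 0.10 variance shares; the null covariate's small residual
# share is the attribution noise floor of the forest.
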