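# propstrat

Propensity-score stratification for **continuous** land-cover treatments in
stream monitoring data.

## The problem

National river monitoring networks record physical habitat, water chemistry
and macroinvertebrate communities at thousands of sites, which makes them
attractive for estimating the effects of agricultural land cover (arable and
improved pasture, measured as percent of the upstream catchment or of a
riparian strip). The catch is confounding: across a country, land cover
covaries strongly with altitude, slope, climate, geology and soils, so naive
multiple regression attributes covariate effects to agriculture — or, with
nonlinear covariate relationships, is simply misspecified.

`propstrat` implements the stratified-propensity alternative for ecologists
and environmental statisticians working with such observational data:

1. **Propensity model** — an additive spline regression predicts each site's
   percent treatment cover from environmental covariates (plus a
   tensor-product spatial surface over Easting/Northing).
2. **Stratification** — sites are split into *k* quantile groups of the
   predictions (*k* = 5 by default, 4 and 6 as sensitivity checks). Within a
   group, treatment–covariate correlation is far weaker.
3. **Within-group models** — a GLM per group relates each response to percent
   cover, with the propensity covariates entered linearly to absorb residual
   within-group variability.
4. **Pooling** — group coefficients b_k are combined as a weighted mean with
   weights n_k / N, and a 95% interval

   CI = 1.96 · sqrt( Σ_k SE_k² · (n_k / N)² ).

   With m response models per family of tests, intervals are widened to level
   α / c(m), c(m) = Σ_{i≤m} 1/i (Benjamini–Yekutieli), before an effect is
   flagged significant (interval excluding 0 on the link scale, equivalently
   1 for odds ratios).

Commonality analysis (unique vs shared explained variance of treatment and
covariates) quantifies how much confounding the stratification removed
relative to direct whole-data regression, compared by a paired t-test.

Because real national monitoring extracts are not redistributable, the
package ships a synthetic confounded-landscape generator with *known* true
effects per 1% cover, spatially structured covariates and a tunable share of
treatment variance explained by covariates. Every stage is validated against
it by parameter recovery, plus closed-form and independent-oracle checks
(regression-on-order-statistics censored medians, ASPT, feeding-guild
Simpson diversity, commonality identities).

## Worked example

```python
from propstrat import (GeneratorConfig, generate_sites, fit_propensity, stratify,
                       balance_report, ModelSpec, fit_group_models, pool_estimates,
                       adjust_fcr, translate_effect)

config = GeneratorConfig(n_sites=2000, seed=7, confounding_strength=0.76)
sites, truth = generate_sites(config)

fit = fit_propensity(sites, "arable_catch")
strat = stratify(fit, k=5)
bal = balance_report(sites, "arable_catch", strat)
print(f"propensity model R2: {fit.explained:.2f}")
print(f"collinearity reduction within groups: {bal.attrs['reduction']:.0%}")

spec = ModelSpec(response="silt_deposits", family="binomial")
groups = fit_group_models(sites, strat, spec)
pooled, = adjust_fcr([pool_estimates(groups, "silt_deposits", "binomial")], m=20)
lo, hi = pooled.adj_ci
print(f"log-odds per 1% arable cover: {pooled.estimate:.5f} "
      f"(adjusted CI {lo:.5f} to {hi:.5f}), true {truth.true_effects['silt_deposits']}")
print(f"odds multiplier 0 -> 100% cover: "
      f"{translate_effect(pooled, 100)['odds_multiplier']:.2f}")
```

prints

```
propensity model R2: 0.77
collinearity reduction within groups: 68%
log-odds per 1% arable cover: 0.01727 (adjusted CI 0.00227 to 0.03226), true 0.01386
odds multiplier 0 -> 100% cover: 5.62
```

Read: the covariates explain 77% of arable-cover variance; stratifying on
the model's predictions cuts the mean treatment–covariate association by
68%; the pooled within-group effect on the odds of silt/sand deposits is
0.017 per percentage point of arable cover (true generating value 0.0139,
inside the widened interval), i.e. going from a catchment with no arable
cover to one fully arable multiplies the odds roughly five-fold.

The same objects are available as scikit-learn estimators
(`PropensityStratifier`, `StratifiedEffectEstimator`) for use in pipelines,
and as a CLI:

```sh
propstrat generate --n-sites 1000 --seed 1 --out data/
propstrat run --seed 1 --out results/        # four treatments x ten responses
propstrat sensitivity --seed 1 --out results/   # k in {4,5,6} + alt thresholds
propstrat report --results results/
```

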