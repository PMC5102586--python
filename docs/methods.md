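# Methods

## Estimand and procedure

The quantity of interest is the change in a stream response (habitat
feature occurrence, log10 nutrient concentration, invertebrate metric) per
1% increase in agricultural land cover, holding the environmental template
fixed. With observational monitoring data the treatment is continuous and
strongly collinear with covariates, so the package estimates it by
stratification on a modelled treatment intensity:

1. fit an additive model T ~ covariates (the "propensity" model);
2. split sites into k quantile groups of the predictions;
3. fit response ~ T + covariates by GLM within each group;
4. pool the k treatment coefficients with weights n_k/N and interval
   half-width z·sqrt(Σ SE_k²(n_k/N)²), z = Φ⁻¹(0.975).

Step 4's interval treats group estimates as independent, which holds because
groups partition the sites. Across a family of m response models the
interval is re-computed at level α/c(m), c(m)=Σ_{i≤m}1/i — a deterministic,
conservative Benjamini–Yekutieli widening. The selection-dependent
false-coverage-rate variant (level 1 − R·α/m, R = count of nominally
significant effects) is available via `adjust_fcr(..., method="fcr")`; the
deterministic widening is the default because it needs no selection step and
is reproducible row by row.

Assumptions: no unmeasured confounders (the covariate set captures what
drives land-cover placement); within-group linearity of the
treatment–response link (stratification shrinks the covariate range so a
linear term suffices even when the global relationship is nonlinear);
enough sites per group for GLM asymptotics. The method's payoff is
robustness to *misspecified* covariate–response links, not to omitted
variables.

## Propensity model

Continuous covariates (altitude m, slope m/km, rainfall mm/yr, temperature
°C, urban %, other-agriculture %) enter as cubic regression splines
(`n_knots=5`, 7 basis columns each); lithology (hard, chalk, limestone,
sandstone, sedimentary) and soil (loam, clay, sand, other) as treatment-coded
factors; Easting×Northing as a tensor product of two marginal cubic B-spline
bases (`spatial_knots=4`, 49 columns). The design is solved by
least squares (`lstsq`), which tolerates rank deficiency; constant covariates
are dropped with a warning. No term selection or simplification is applied:
the model's sole job is to rank sites by expected treatment intensity, and
only the ranks feed the stratification. Fixed-df unpenalized regression
splines were chosen over penalized smooths with data-driven penalty
selection: they are fast, exactly reproducible, and at n in the thousands
with ~86 columns the in-sample R² inflation is ≤ ~0.04 (visible in the
unconfounded null, where R² < 0.05), which leaves quantile ranks essentially
unchanged. Predictions are reported unclipped; percent-scale outputs are
clipped to [0,100] only for display.

Stratification is by rank with stable tie-breaking (input order), so group
sizes differ by at most one (n = qk + r puts the extra site in the first r
groups). All-identical scores raise an error; ties straddling a boundary
warn. k ∈ {2..10}; 4/5/6 cover the sensitivity design.

## Balance diagnostic

Association between treatment and a continuous covariate is Pearson r;
for a categorical covariate it is the correlation ratio
η = sqrt(SS_between/SS_total) of treatment across classes (a dummy-variable
max-|r| switch is not provided; η is the single documented convention).
The report compares mean |association| over covariates for the whole data
set against the group-size-weighted mean of within-group values, and states
the relative reduction. When the overall mean association is below the
sampling noise floor 3/√n the reduction is reported as 0 with a flag —
a ratio of two near-zero quantities would otherwise report large spurious
"increases" on unconfounded data.

## Response models

Error families: binomial for dichotomized habitat features, Gaussian for
log10 chemistry and the invertebrate metrics (richness, ASPT, guild
diversity). Richness can be switched to Poisson (`richness_family`), which
matches a count-generating process exactly; the Gaussian default keeps the
effect size in "families per 1% cover" units. Covariates enter linearly —
deliberately the same misspecification the stratification is meant to
absorb. Within-group binomial fits that separate (constant response,
non-finite or absurd treatment SE) are excluded with a warning and the
pooling weights renormalize over the remaining groups, keeping the interval
formula exact. Note the finite-sample cost of stratification: k GLM fits of
n/k sites each carry more logistic MLE bias than one fit of n sites, so
pooled binomial coefficients run a few percent high at group sizes of a few
hundred with ~15 parameters.

Effect translation to a 0→100% cover contrast: odds multiplier
exp(100·b) for binomial; baseline·(10^{100·b} − 1) mg/L for log10 chemistry;
baseline·(exp(100·b) − 1) for counts. The baseline is the model prediction
at 0% cover with covariates held at sample medians (continuous) and modes
(categorical) — a documented convention, since any covariate reference point
is defensible.

The residual semivariogram γ(h) = mean squared residual difference / 2 per
distance bin flags a non-flat profile (any bin departing from the residual
variance by more than 35% of it) as residual spatial structure. It is a
diagnostic only; no spatial GLMM is fitted.

## Commonality analysis

For each response model, explained variance (ordinary R² for Gaussian,
McFadden pseudo-R² for binomial) is partitioned into the treatment's unique
share R²(T,C) − R²(C), the covariates' unique share R²(T,C) − R²(T), and the
signed common share R²(T) + R²(C) − R²(T,C) (negative under suppression).
The treatment-vs-covariates block partition is the working granularity; a
full 2^p expansion over ≤5 named predictors exists for verification. Group
values are averaged with group-size weights (consistent with the pooled
estimator; unweighted averaging is available), and the propensity and direct
arms are compared with a paired t-test across responses.

## Censored chemistry and biotic metrics

Annual medians of monthly determinand series (nitrate = total oxidized
nitrogen, orthophosphate; mg/L): with <50% of values below the detection
limit, the plain median of reported values (censored observations stand at
the limit) — the median rank falls in the uncensored tail, so imputation
cannot change it. At ≥50% censoring, regression on order statistics:
censored observations occupy the lowest ranks, Weibull plotting positions
i/(n+1) map ranks to normal quantiles, log uncensored values are regressed
on their quantiles, censored values are imputed from the fit, and the median
of the completed sample is returned (midpoint convention for even n). All
observations censored leaves the median inestimable (`ros_median` raises);
the batch `annual_median_table` substitutes the detection limit as an upper
bound with a warning so one sensor-floor site cannot abort a network run.

ASPT is the mean sensitivity score (1 tolerant … 10 highly sensitive) of
families present (spring∪autumn presence). Guild diversity is Simpson's
1 − Σp² over guild proportions p_g defined by normalized sums of the present
families' affinity vectors — summing and averaging affinities differ by a
constant factor, so the proportions (and the index) are identical either
way. Habitat features are dichotomized from 10-spot-check counts (e.g.
bankside trees: ≥50% of spot checks; alternatives ≥40%/≥60% in the
sensitivity suite).

## The synthetic landscape

The generator emulates the statistical structure the method assumes, not any
real geography. Covariates are smooth plane-wave random fields over a
500×500 km square plus site noise; lithology and soil are nearest-centre
blocked categorical fields. A standardized covariate index η (linear, plus
quadratic/threshold terms scaled by `nonlinearity`) is mixed with
independent noise as √s·η + √(1−s)·ε, scaled by (mean 35, sd 18) and clipped
to [0,100]; s = `confounding_strength` is the target covariate-explained
share of treatment variance, and the realized value (computed by
Gauss–Hermite integration of the clipped conditional mean) is recorded in
the truth object. Defaults: n_sites = 1000, s = 0.76 — the strongly
confounded arable-catchment regime where stratification matters most; the
pasture treatment uses 0.6·s (pasture is empirically less predictable from
the environment), and riparian covers are ρ=0.85 latent copies of catchment
covers. Responses take intercept + effect·T + amplitude·g(covariates) on
the link scale with families binary / Poisson count / Gaussian /
Gaussian-on-log10. Default true effects per 1% cover were set once from the
effect magnitudes such a landscape plausibly produces (e.g. silt-deposit
log-odds 0.01386 ⇒ fourfold odds over 0→100%; nitrate log10 slope 0.00845 ⇒
roughly a 2→14 mg/L contrast; richness log slope 0.00232 ⇒ ~6 extra
families on a baseline of 23). Spot-check counts are 10 Bernoulli draws per
feature with per-draw intercepts calibrated so the dichotomized features are
non-degenerate.

What the generator does **not** emulate: real marginal distributions of
land-cover percentages (unknown; defaults are stated, not calibrated),
spatial autocorrelation of response *residuals*, measurement error in
covariates, network topology (one-site-per-tributary filtering), or
species-to-family trait aggregation (the trait table carries family-level
scores and Dirichlet affinities directly). Passing recovery tests therefore
shows the estimator is correct under its stated assumptions — not that
those assumptions hold in any particular national data set.

## Simulation evidence (computed by the test suite / acceptance script)

- Pooled-interval coverage of the true binomial effect under the linear
  confounded generator, and the bias comparison against direct regression
  under nonlinear confounding, use n = 2000 sites per replicate with
  300/200 replicates (900 aggregated for coverage) — sizes chosen to hold
  Monte-Carlo error on a coverage percentage near one point.
- Null calibration uses 20 seeds × 20 zero-effect responses at n = 1000.
- The commonality identity is exact (≤1e-9) by construction of the three
  nested fits; the closed-form pooling and widening checks are arithmetic.

## Known limitations

- Stratification multiplies logistic small-sample bias (see above); with
  very small groups prefer fewer strata or Gaussian working models.
- The BY widening is conservative; true null exceedance runs well below the
  nominal rate, trading power for familywise caution.
- The propensity model is fit and applied in-sample, as is standard for
  stratification; no cross-fitting is implemented.
- No inverse-probability weighting, matching, caliper or doubly robust
  estimators; stratification only.
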