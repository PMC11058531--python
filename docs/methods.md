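# Methods

## The question and the decomposition

Repeated cross-sectional surveys measure the same items on fresh samples
every few years. Aggregate opinion change in such data can arise from two
broad individual-level processes: *settled dispositions* (beliefs crystallise
during a formative period, so aggregates move only as older birth cohorts are
replaced by younger ones with different settled views) and *active updating*
(individuals keep revising beliefs, so cohorts themselves drift — age and
period effects, which we deliberately do not try to separate). The package
adjudicates between them per item and country with a nested-model comparison:

- **Model 1** regresses the response on birth-cohort indicators only
  (each respondent predicted by their cohort mean);
- **Model 2** adds a centred linear survey-year term and a cohort x year
  interaction, i.e. a separate linear time trend per cohort.

Because Model 1 is nested in Model 2, `R2_full >= R2_cohort_only`, and

```
tau = R2_cohort_only / R2_full   in [0, 1]
```

is the share of explainable linear change preserved when within-cohort change
is forced to zero. Formal age-period-cohort identification is impossible in
cross-sections (age + cohort = period) and is not attempted: the contrast that
matters is between-cohort differences versus all within-cohort change pooled.

Only *linear* within-cohort change is modelled. Temporary shocks that leave no
lasting mark are part of within-cohort variance but cannot produce directional
change, which is the quantity of interest; this is an explicit modelling
assumption, not an oversight.

`tau` is flagged **undefined** (not 0) when `R2_full < 1e-6`: with no linear
structure at all there is nothing to decompose. Undefined rows are retained in
the summary table, excluded from the tau models (counts logged).

Aggregate change is summarised as `|mean(last wave) - mean(first wave)|`
divided by the sample SD of the pooled first+last wave responses — a
scale-free effect size invariant under affine rescaling of the response
scale. Items above 0.8 pooled SDs are flagged for plot labelling.

## Cohort binning and OLS details

- Default bins are 5 birth years wide, half-open, with the origin at the
  earliest observed birth year rounded down to a multiple of 5. The width is
  configurable and echoed in the output metadata.
- Cohorts with fewer than 5 observations are merged into the nearest
  surviving cohort (ties to the older one) to avoid rank-deficiency in the
  interaction model; every merge is logged.
- Model 2's fitted values are computed as separate per-cohort simple linear
  regressions, which span exactly the same column space as cohort dummies +
  centred year + interactions; a cohort observed in a single survey year has
  its (unidentifiable) trend dropped and contributes its cell mean. The tests
  verify both R2 values against a brute-force `lstsq` solve of the explicit
  dummy design matrix to 1e-10.
- R2 is the plain in-sample coefficient of determination; an adjusted-R2
  variant of tau would penalise Model 2's extra parameters, but tau is defined
  here as a ratio of raw explained variances.
- Year centring in Model 2 leaves fitted values and R2 unchanged; it is done
  purely for numerical conditioning.
- No survey weights are used anywhere.

## Synthetic study conditions

The generator emulates a WVS-style design: 8 survey waves evenly spaced over
1981-2020, five 10-year birth cohorts born 1930-1979, and a configurable
number of respondents per cohort-wave cell (default 100). A cohort enters
observation once its youngest member is 18 at the survey year — so the two
youngest reference cohorts enter in the late 1980s and late 1990s and the
aggregate composition genuinely shifts over the window. There is no mortality
or panel attrition process; responses are continuous Gaussian draws around
the cohort's linear trajectory, optionally clipped/rounded to a bounded
integer scale.

Three reference regimes (all with noise SD 1):

| regime | cohort intercepts | common slope /yr | mean tau (50 seeds) |
|---|---|---|---|
| settled | 0, 0.5, 1.0, 1.5, 2.0 | 0 | ~0.99 |
| mixed | 0, 0.25, 0.5, 0.75, 1.0 | 0.05 | ~0.39 |
| within-only | all 1.0 | 0.05 | ~0.06 |

The idealised-scenario parameters behind published illustrations of these
three regimes are not standardised anywhere; these defaults were fixed once
so that the settled and within-only regimes sit near the ends of the tau
scale with the mixed regime strictly between, and are exposed as free
parameters rather than treated as canonical.

The sensitivity survey generator draws each respondent's rating of each item
as `round(latent + N(0, 1.5))` clipped to 1..10, with a country-level latent
sensitivity per item. Attention-check failures are Binomial(4, 0.125) per
respondent, making ~0.7% of respondents fail more than two checks — the
exclusion rate typical of attentive online panels. Respondents rate
second-order difficulty ("how hard for most compatriots to discuss"); the
generator models this directly as a country-level latent value with rater
noise, with no link to the respondent's own opinion and no IRT-style rater
model.

The joint-study generator couples the two: each item x country is assigned
the settled regime with probability `logit^-1(mixing_effect * z)` where `z`
is the item's latent sensitivity standardised across items, and the mixed
regime otherwise. The emitted truth table (regime, latent sensitivity,
generative slopes) exists purely to support parameter-recovery tests.

What passing these tests does *not* show about real data: the generator has
no item nonresponse, no sampling weights or stratification, no nonlinear
trajectories, no measurement error in birth year, and its regime dichotomy is
sharper than reality's continuum — recovery results bound what the method can
do under its own assumptions, not under survey practice.

## Sensitivity scores

Respondents missing more than two attention checks are excluded (the filter
is idempotent and reports counts). Ratings are aggregated per item x country
by the median (robust to extreme raters; the mean is carried alongside as a
robustness column, standard midpoint convention for even n). Scores are
standardised to `sensitivity_z` — by default over the *global* pool of all
item x country medians, because the hierarchical models place all countries
on a common sensitivity axis with country-varying slopes; per-country
standardisation is available as an option since either convention is
defensible.

## Hierarchical models

All three models share the linear predictor
`a + b*z + u_country + v_country*z` with correlated country-varying
intercepts and slopes (non-centred parameterisation).

- **Change model**: `abs_change_sd ~ Lognormal(eta, sigma)` — change is
  positive by construction, so the linear predictor acts on the log scale.
  Non-positive outcomes (possible only in degenerate inputs) are rejected by
  default; the caller may choose to drop or floor them, and either remedy is
  logged. Whether near-zero-change items should be excluded has no canonical
  answer; the default keeps them.
- **Tau mixture**: `tau ~ pi * Beta(mu_hi, phi_hi) + (1-pi) * Beta(mu_lo,
  phi_lo)` in mean-precision form, with `logit(pi) = eta`. Empirically tau is
  strongly bimodal (items cluster near "pure cohort replacement" and "mostly
  within-cohort change"), which motivates the mixture. The component means
  are ordered *by construction* — `logit(mu_hi) = logit(mu_lo) + exp(gap)` —
  so label switching is impossible rather than corrected post hoc, and `pi`
  is unambiguously the probability of the high-tau component. The population
  slope `b` of the mixing regression is the headline quantity: on the
  log-odds scale, positive values mean more sensitive issues are more likely
  to change via cohort replacement. Exact-boundary tau values are shrunk by
  the standard `(tau*(n-1) + 0.5)/n` adjustment (recorded in metadata);
  fits are refused below 20 rows, where a two-component mixture is not
  identifiable in practice.
- **Gaussian robustness model**: a plain Normal regression of tau on the same
  predictor, kept to check that the mixture's directional conclusion is not
  an artefact of the likelihood choice. It is knowingly misspecified for
  bimodal, boundary-hugging tau.

Priors (weakly informative on standardised scales, all overridable in code):
Normal(0,1) population coefficients, half-Normal(1) group SDs and residual
SDs, LKJ(2) on the intercept-slope correlation, Normal(0,1.5) on the low
component's logit mean, lognormal(0,1) gap, Gamma(2, 0.1) on beta precisions
(mean 20). With a single country the varying-effects block is dropped with a
warning.

### Sampling and diagnostics

Posteriors are drawn with an affine-invariant ensemble sampler using
differential-evolution moves (80% DEMove / 20% snooker), which handles these
correlated, funnel-prone posteriors far better than the stretch move and
needs no gradients. Defaults: 4 *independent* ensembles of >= 48 walkers,
1200 burn-in steps, 1800 retained steps thinned by 6, all seeded from the
single run seed.

Convergence is diagnosed by rank-normalised split-R-hat across the
independent ensembles (each ensemble's pooled walkers form one chain,
time-major), a stricter check than comparing coupled walkers within one
ensemble; the gate is R-hat < 1.01 on every reported parameter. Bulk ESS is
reported on the same pooled chains and should be read as optimistic, since
draws within an ensemble interleave walkers. Divergence counts are a
Hamiltonian-specific diagnostic and do not exist for an ensemble sampler;
the mean acceptance fraction is reported as the complementary sanity check.
Non-convergence produces a loud warning and a nonzero pipeline exit code
(2), never a silent result.

Prediction curves report, per country and grid point over `sensitivity_z` in
[-1.5, +1.5] (step 0.25), the posterior mean of the model's mean function:
`exp(eta + sigma^2/2)` for the lognormal model, `eta` for the Gaussian, and
`pi*mu_hi + (1-pi)*mu_lo` for the mixture. Grids beyond +-3 SD trigger an
extrapolation warning.

## Problem sizes and budgets

The test suite exercises recovery at the full study scale (56 items x 8
countries = 448 rows for the model fits) with the default sampler budget;
reduced-replication checks (the 20-run null calibration, the end-to-end
paired runs) use smaller ensembles and 40 respondents per cell, sizes chosen
to keep the whole suite in single-digit minutes on one CPU while leaving
Monte-Carlo error well inside the asserted tolerances. The acceptance script
reruns the same computations from scratch at those scales.

## Known limitations

- tau is a ratio of in-sample R2 values: with weak signal it is noisy, and
  the undefined-tau epsilon is a pragmatic (configurable) cutoff.
- The within-cohort component is strictly linear; saturating or reversing
  trends are attributed partly to noise.
- The ensemble sampler's ESS is approximate (see above), and very small
  group SDs can still mix slowly despite the non-centred parameterisation —
  the R-hat gate, not the ESS, is the operative check. On small bimodal
  datasets the (misspecified) Gaussian robustness model occasionally sits
  just above the gate; the warning is the intended behaviour.
- Sensitivity enters the models as a point value; rater disagreement is not
  propagated (no measurement-error model).
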