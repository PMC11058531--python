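# cohortshift

Do public opinions change because individuals change their minds, or because
older birth cohorts die and are replaced by younger ones who grew up under
different conditions? `cohortshift` implements a variance-decomposition
analysis of repeated cross-sectional survey data (World Values Survey-style:
fresh national samples answering the same items over decades) that separates
these two mechanisms per item and country, and hierarchical Bayesian models
that test whether *sensitive* issues — those hard to discuss — change more
through cohort replacement. It is aimed at computational social scientists
and survey methodologists; everything runs from Python (or a thin CLI) on
long-format CSVs, and a seeded synthetic-data generator makes the entire
chain testable without any survey download.

## The statistic

For each item x country, two nested OLS models are fitted to individual
responses *y*:

- Model 1: `y ~ cohort` (one mean per birth cohort — pure settled
  dispositions, change only by cohort replacement);
- Model 2: `y ~ cohort + year + cohort:year` (each cohort follows its own
  linear time trend — within-cohort change allowed).

With coefficients of determination R²₁ ≤ R²₂,

```
tau = R²₁ / R²₂
```

is the share of explainable linear change preserved when within-cohort
change is forced to zero: tau ≈ 1 means cohort replacement alone accounts
for the trend, tau ≈ 0 means cohorts themselves moved. Aggregate change is
measured as |Δ mean| between first and last waves in pooled-SD units. Issue
sensitivity is the median of respondent ratings ("how difficult would it be
for the majority of people from your country to discuss this", 1–10), after
excluding respondents who miss more than two attention checks, standardised
to z-scores. Two hierarchical models with country-varying intercepts and
slopes relate these: a lognormal regression of absolute change on
sensitivity, and a two-component beta mixture for tau whose high-component
probability follows `logit(pi) = a + b·z` — a positive population slope *b*
means sensitive issues change more via cohort replacement.
See `docs/methods.md` for assumptions, priors and diagnostics.

## Worked example

`examples/01_idealised_regimes.py` generates one item under each idealised
change regime and prints:

```
     settled: R2(cohort)=0.308  R2(full)=0.311  tau=0.992  abs change=0.47 SD
       mixed: R2(cohort)=0.126  R2(full)=0.372  tau=0.339  abs change=1.50 SD
 within_only: R2(cohort)=0.010  R2(full)=0.289  tau=0.035  abs change=1.45 SD
```

Cohort membership alone preserves 99% of the explainable variance when
cohorts never move, 34% when cohorts drift on top of their differences, and
4% when all cohorts share one trend and differ in nothing.

`examples/04_full_pipeline.py` runs the whole chain on a synthetic joint
study in which sensitive items are more likely to follow the settled regime
(coupling strength 2 on the log-odds scale) and prints:

```
tau computed for 80 item x country pairs; 40 changed by more than 0.8 pooled SDs
mixing slope (log-odds of the high-tau component per SD of sensitivity): +2.10 [+0.91, +3.11], P(>0) = 0.999
```

i.e. the fitted mixing slope recovers the built-in coupling with essentially
all posterior mass above zero. The other examples cover the sensitivity
survey preprocessing and mixture-model parameter recovery.

The same pipeline is available from a shell:

```bash
cohortshift run-all --outdir my_run --seed 3 --mixing-effect 2.0
```

writing `tau_summary.csv`, `sensitivity_summary.csv`, posterior summaries,
prediction curves over sensitivity in [−1.5, +1.5] SD, figures, a
diagnostics JSON and an echo of the exact config. Real data enter through
`mode: csv` with long-format opinion
(`country,survey_year,birth_year,item,response`) and rating
(`respondent_id,country,item,rating,n_checks_missed`) tables.

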