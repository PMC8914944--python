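# Methods

## Estimands and identification

Let Y be an outcome measured at up to J annual visits per person within each
of two periods, G ∈ {0,1} a treatment-eligibility genotype and P ∈ {0,1} the
period of observation. Treatment X is deterministic: X = 1 exactly in the
cell (G=1, P=1). The estimand is the average treatment effect in the
treated, E(Y^{X=1} | G=1, P=1) − E(Y^{X=0} | G=1, P=1). Because Y^{X=0} is
never observed in the treated cell, identification rests on a model for the
untreated-world mean,

    E(Y^{X=0} | P=p, G=g) = α + β_P p + β_G g + γ_PG p g.

Under γ_PG = 0, the difference-in-differences combination NTE − NCE (naive
effect minus negative control effect) identifies the estimand for either
choice of control group: historical (time-period comparison, NCE taken
across periods in the ineligible genotype) or genotype (NCE taken between
genotypes in the pre-introduction period). γ_PG = 0 is not verifiable from
the data; the negative control effect itself is the diagnostic — a clearly
nonzero NCE demonstrates that the matching naive effect is biased.

## Fitted models

**Continuous outcomes** use the step/slope marginal model
E(Y_ij | X_i) = β₀ + β_St X_i + β_Sl X_i j + β_J j, with β_St the immediate
level shift and β_Sl the change in annual slope. **Count outcomes** use a
log-link marginal model with year-specific treatment terms,
log E(Y_ij | X_i) = γ₀ + visit terms + Σ_k γ_Xk X_i 1(j = k−1), so
exp(γ_Xk) is the rate ratio after k years of treatment (treatment year k
maps to post-period visit j = k−1, the only mapping consistent with annual
reviews that start in the introduction year). Visit terms default to one
indicator per visit index — a saturated secular trend, chosen because the
linear-in-j form is only warranted for the continuous model — with a
linear-in-j option.

Both models are estimating-equation fits with an *independence working
correlation*: point estimates coincide with stacked-data ordinary least
squares (continuous) and with the log-link quasi-score / GLM-Poisson
solution (counts; a gamma-frailty-overdispersed truth scales the quasi-score
uniformly and leaves the point estimates unbiased). The package solves these
directly — LAPACK least squares, and IRLS converging at relative parameter
change < 1e-10 within 100 iterations (non-convergence is an error) — rather
than delegating to a GEE library, because bootstrap inference refits each
model tens of thousands of times; the test suite verifies equality of the
point estimates with statsmodels GEE (independence) and GLM-Poisson to
1e-6–1e-8. Collinearity is detected by singular values below 1e-8 of the
largest, with the dependent columns named via pivoted QR. A cluster-robust
sandwich variance is attached to each fit as a diagnostic; it is *not* the
reported interval.

## Covariate adjustment

Baseline covariates are measured in the year before visit 0 of each period
and are constant within (person, period); a person present in both periods
may carry different baseline values in each. Encodings: identity for
continuous, 0/1 for binary, and a `count_baseline` encoding that expands a
baseline count into a nonzero indicator plus a linear term for the nonzero
counts. Two adjustment routes exist:

- **conditional** — covariates enter the fitted model; valid as an estimate
  of the adjusted effect when the covariate effect on Y is not modified by
  G or P;
- **standardized** — g-computation: fit the outcome model in the X=0
  records at a visit, average its predictions over the empirical covariate
  distribution of the X=1 records, subtract from the observed X=1 mean.
  Overlap is checked exactly for discrete covariates (an X=1 stratum absent
  from X=0 is an error) and warned about for continuous ones. With no
  covariates the procedure collapses to the unadjusted mean difference. A
  standardized step/slope pair is formed by computing the per-visit
  standardized differences and regressing them on visit index.

Standardized adjustment is implemented for continuous outcomes only; the
adjusted count analysis is conditional (covariates in the log-linear model).
Supporting a standardized count path would require choosing a marginal
standardization scale (rate vs. log-rate) that the year-specific model does
not pin down; the conditional route is the documented default.

Missing data are handled by complete cases within each fitted model: rows
missing the outcome are dropped at read time, and persons missing a
requested covariate are dropped per analysis, both with logged counts. No
imputation is provided.

## Inference

All reported intervals and p-values come from a nonparametric cluster
bootstrap with persons as the resampling unit (default B = 1,000; B < 100
logs a warning). One person-level resample per iteration feeds the NTE, NCE
and NCCTE together: persons contributing records to two groups move as a
unit, so the corrected effect's interval reflects the joint sampling
variation of all four groups and their shared membership. Confidence
intervals are 95% percentile intervals. P-values invert the percentile
interval — the smallest α on the grid {0.001, …, 0.999} at which the
(1−α) interval excludes the null (0 on the difference scale, 1 on the
rate-ratio scale); this is a documented choice consistent with percentile
intervals, not the only possible bootstrap p-value. Resamples on which a fit
fails (an empty pseudo-treatment arm, an all-zero treated count cell) are
dropped and counted; more than 5% failures aborts with an error rather than
silently narrowing the interval. The corrected point estimate always equals
the combination of its components exactly: NTE − NCE on the difference
scale, a log-scale subtraction on the rate-ratio scale.

In simulation the corrected effect's interval is usually at least as wide as
the wider of its two components' intervals — the price of the correction is
honest extra uncertainty — but this is an empirical tendency, not an
enforced invariant, since the components are positively correlated through
shared persons.

## Synthetic registry generator

The generator emulates the structure the estimators assume, not any real
registry's marginals. Persons are drawn per genotype group; each appears in
both periods with probability `p_both_periods` (default 0.7, mimicking the
substantial overlap between a registry's pre- and post-period panels) and
otherwise in one period at random. Outcomes follow the untreated-world mean
above plus β_J·j, a treatment step δ_St and slope δ_Sl applied only in
(G=1, P=1), a person-level Gaussian random intercept shared across periods
(SD `sd_person`), and residual noise (SD `sd_noise`). Counts use the
log-linear analogue with per-year treatment log-rate-ratios and a
person-level gamma frailty of variance `dispersion`. Covariates are drawn
per (person, period) with G- and P-dependent means or prevalences and
additive effects on the outcome. Visit missingness is completely at random
(`p_missing_visit`, default 0.1), with visit 0 re-added when a person-period
would otherwise vanish. Everything is driven by one seed; identical configs
give bit-identical cohorts.

Default scale mimics a lung-function outcome: baseline α = 70 points,
annual decline β_J = −0.5, between-person SD 10, residual SD 5, treatment
step 5 and slope change +0.5; counts default to a baseline rate of 18
events/year with treatment rate ratios (0.5, 0.4, 0.4, 0.4) and dispersion
0.5. Scenario presets: `scenario1` (β_P = β_G = 0), `scenario2` (G and P
act on Y only through a binary covariate H: prevalence 0.5 + 0.2·G + 0.1·P,
effect 5), `scenario3` (β_P = 1, β_G = 2, γ_PG = 0). G=0 persons carry a
free-text genotype label (54% / 36% / 10% across three categories) used
only to exercise the sensitivity filter that restricts the comparison
genotype group.

`ground_truth` returns the closed-form effects implied by a configuration —
e.g. NTE_G step = δ_St + β_G + γ_PG, NCE_G step = β_G, NCCTE step =
δ_St + γ_PG, with covariate-mediated shifts entering the naive and control
contrasts and cancelling in the correction — verified against large-n
simulation in the tests.

What passing tests on this generator do **not** show: robustness to
informative dropout, to covariate-dependent missingness, to non-linear
secular trends within a period, or to treatment-effect heterogeneity across
persons; none of these are generated, and real registry data contain all of
them.

## Problem sizes and numerical choices

Recovery tests use 2,000 persons per genotype group (about 25,000
person-visit rows), where the Monte-Carlo standard error of a step estimate
is ≈ 0.35 points; assertions use 3 standard errors computed from the
cluster-robust sandwich. Calibration studies use 300 replicate registries of
400 persons per group with B = 200 bootstrap resamples — sizes at which
percentile-interval coverage of the corrected step is expected in the
93–97% band and the type-I error of its p-value in 3–8% at nominal 5%.
Oracle-equivalence checks run 50 random small panels (20 persons, 1–4
visits) against statsmodels. Rate-ratio results are reported to the integer
percent reduction and differences to two decimals in the CLI report; stored
JSON keeps full precision. Ties and degenerate inputs: a single-visit
analysis set makes the slope columns collinear and is refused by the rank
check; an all-zero treated count cell is refused before fitting.
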