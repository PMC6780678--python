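# Methods

`bdrscreen` implements a pharmacometabolomic interaction screen: does the
level of a circulating metabolite modify the estimated effect of age on
bronchodilator response (BDR) in children with asthma?  This note records
the models, the synthetic-data generator, the numerical choices, and the
limits of what the tests demonstrate.

## Phenotype

BDR is (best post-bronchodilator FEV1 − pre-bronchodilator FEV1) /
pre-bronchodilator FEV1, a dimensionless fraction.  "Best" is the maximum
over recorded post maneuvers; the single recorded pre value is used as-is.
BDR is kept as a fraction everywhere internally (0.11, not 11%); only
display layers multiply by 100.  Negative BDR (paradoxical response) is
valid data, not an error.

## LC-MS preprocessing

The pipeline order is fixed:

1. **Pooled-reference standardization.**  Each value is divided by the
   value of the nearest pooled-reference injection (by absolute
   injection-order distance, ties to the earlier injection) and multiplied
   by the feature's median reference value.  If the nearest reference is
   missing or zero, the next nearest positive reference is used.  A
   feature with no usable reference becomes all-missing and is removed by
   the missingness filter.
2. **SNR filter.**  Features with instrument signal-to-noise < 10 are
   dropped.  SNR is consumed as per-feature metadata, as produced by
   instrument software; no SNR formula is applied to spectra.
3. **Missingness filter.**  Features missing in > 10% of *study* samples
   are dropped; pooled references are excluded from the denominator.
4. **Median imputation.**  Remaining missing study values are replaced by
   the feature's observed study median.  Pools are never imputed.
5. **CV filter.**  Features whose pooled-reference coefficient of
   variation (SD/mean, n−1 denominator) exceeds 25% are dropped.  The CV
   is computed on **raw** pool values: standardization forces pool ratios
   toward 1 and would mask exactly the technical variance the filter is
   meant to catch.  Because pools are never imputed, evaluating this
   filter before or after imputation is observationally identical; the
   standalone `filter_features` therefore runs the whole cascade in one
   pass.
6. **log10 + pareto.**  Per feature over study samples:
   z = (log10 x − mean) / sqrt(SD), SD with the n−1 denominator.  Pareto
   scaling (dividing by the square root of the SD rather than the SD) is
   intermediate between no scaling and unit-variance scaling and is the
   field's convention for peak-area data.  Zeros or negatives at this
   stage are replaced by half the feature's smallest positive value
   (counted in the log); constant features are dropped.

All thresholds are strict inequalities: SNR exactly 10, missingness
exactly 10% and CV exactly 25% are retained.

## The interaction screen

For each metabolite *f*, the longitudinal model is a random-intercept
linear mixed model

    BDR_ij = x_ij' beta + b_i + e_ij,
    b_i ~ N(0, sigma_b^2),  e_ij ~ N(0, sigma^2)

with fixed effects: intercept, race, sex, clinic, treatment (dummy-coded,
lexicographic level order, first level as reference), age in years, the
preprocessed metabolite z_f, and the product age × z_f.  The quantity of
interest is the interaction coefficient: BDR-fraction units per
(year × scaled-metabolite unit).

**Estimation** is restricted maximum likelihood (REML), profiled to one
dimension.  Writing lambda = sigma_b^2/sigma^2, each subject block of the
marginal covariance is sigma^2 (I + lambda J) with the rank-one inverse
I − (lambda/(1 + lambda n_i)) J, so GLS sufficient statistics cost O(n)
per subject and log det V = sum log(1 + lambda n_i).  sigma^2 has a
closed-form profile (REML denominator n − p), leaving a 1-D search over
log lambda on [1e-8, 1e4] by bounded scalar minimization (tolerance 1e-10
on log lambda) with the lambda = 0 boundary evaluated explicitly.
Standard errors come from the GLS information matrix,
sigma-hat^2 (X'V^-1 X)^-1.  A maximum-likelihood criterion is available
behind a flag.  Degenerate inputs: a rank-deficient design raises an
estimability error naming the aliased columns; an all-singleton grouping
fixes lambda at 0 with a logged warning (the model collapses to OLS).

**Inference** on the interaction is a Wald z test against the standard
normal, with the 95% CI at beta ± 1.96·se.  A t reference with n − p
residual degrees of freedom is available behind a flag.  The normal
reference is a documented choice — with ~1400 observations the difference
is negligible, and the calibration suite verifies type-I error and CI
coverage empirically.

An independent **oracle fitter** maximizes the same restricted likelihood
over (sigma_b^2, sigma^2) by generic 2-D optimization (L-BFGS-B
multistart, Nelder-Mead polish) on the explicit n × n covariance.  It
exploits no block structure and exists purely so the fast path can be
tested against an independent computation; the suite also cross-checks
against statsmodels' MixedLM.

The **cross-sectional screen** (single-visit cohorts) is per-feature OLS
with t-based Wald inference, fitted via statsmodels.  Single-level
covariates (e.g. race in a single-race cohort) are dropped from the
design with a log line rather than raising.

**Multiple testing** is Benjamini-Hochberg step-up,
q_(i) = min_{j>=i} (p_(j) m / j) capped at 1, with the family equal to all
features tested in one screen invocation.  q-values are reported alongside
nominal p-values; replication tiers use nominal thresholds only.

**Replication tiers** (exact feature-name matching across cohorts):
*replicated* = discovery p < 0.05, replication p < 0.05, same sign;
*nominal* = discovery p < 0.05, replication p < 0.10, same sign;
*untested* = feature absent from the replication screen; everything else
*not_replicated*.  The nominal threshold is strictly < 0.10.

**Stratified screens** run the same model independently per stratum (sex
or race), with strata under 30 samples skipped and reported.
**Metabolite-age trends** are per-visit OLS of the preprocessed metabolite
on age plus covariates, with BH across the features tested in the call.

## Predicted-effect curves

Predicted BDR at age a and metabolite level m* is x(a, m*, profile)' beta:
a straight line in age with slope beta_age + beta_int · m*.  m* is taken
at the 25th/50th/75th empirical percentiles (numpy's linear interpolation
convention, quantile q at index q(n−1)), pooled across all study samples
in the fitting cohort (per-visit percentiles behind a flag).  Categorical
covariates are held at their reference level by default; a
population-average profile (design-column means) is available and labeled
in the output.  Default age grids are 5–25 years for longitudinal fits
and 5–15 for cross-sectional fits, matching the cohorts' observed ranges.
No uncertainty bands are drawn.

## Synthetic-data generator

The generator emulates the discovery design: 565 subjects, three visits
with age means (SD) 8.8 (2.1), 12.8 (2.2), 16.8 (2.9) years; subjects
carry 3/2/1 available samples with probabilities (294, 265, 6)/565, and
which visits a partial subject has is drawn with weights (0.45, 0.45,
0.10), approximately reproducing per-visit sample counts of ~560/563/295.
Covariate frequencies: sex 64/36, race 70.5/14.6/10.0/4.9 (White/Black/
Hispanic/Other), treatment 27/30.5/42.5 (budesonide/nedocromil/placebo),
eight clinics uniform (the study had eight centers; per-clinic counts are
an assumption).  A single-visit design mirrors the replication cohort:
320 subjects, age 9.1 (1.8), all Hispanic, mean BDR 5%.

The BDR model is

    bdr = intercept + covariate effects + beta_age·age
        + sum_{f active} [ beta_metab·z_f + beta_int·(age − mean age)·z_f ]
        + b_subject + e

with z_f the feature's metabolite level on the preprocessed scale.  The
interaction uses *centered* age in the data-generating process: this is a
pure reparameterization (the uncentered fitted interaction coefficient is
still exactly beta_int; only the metabolite main effect absorbs the
shift), chosen so each active feature contributes a realistic ~0.015 BDR
units of variance rather than ~0.05.  Defaults are assumptions, not
estimates — the source cohorts report no variance components:
beta_age = −0.004/year (mean BDR 0.11 → 0.08 across visits),
sigma_subject = 0.04, sigma_resid = 0.07 (marginal BDR SD ≈ 0.08,
matching the observed 0.07–0.10), beta_int = 0.004 at the reported
effect magnitude, small covariate effects (female −0.005, placebo +0.01).
In the single-visit design the subject effect is absorbed into the
residual.  Pre-bronchodilator FEV1 is log-normal around 2.0 L; the single
post maneuver is pre·(1 + bdr), so `compute_bdr` round-trips the latent
BDR to machine precision.

The LC-MS layer: clean peak areas are exp(loc_f + 0.4·u) with
u ~ N(0, 1) and loc_f ~ N(log 1e6, 1); pooled references (the
population-average material, u = 0) are injected after every 20 study
samples; drift is multiplicative, exp(a_f (sin(2π·order/150) +
1e-4·order)) with a_f ~ U(0, 0.08), so a drift amplitude of zero disables
the layer entirely; technical noise is log-normal with sigma 0.05 (pool CV
≈ 5%); missingness is MCAR at 2% of study values; per-feature SNR is
log-normal (median 40, log-SD 0.7, so ~2–3% of features fail the SNR
gate).  The generator does **not** emulate retention times, m/z, isomer
ambiguity, batch boundaries, value-dependent (left-censored) missingness,
or correlated metabolite modules — passing tests therefore demonstrate
correctness of the pipeline's statistics under its stated model, not
robustness to those real-data features.

## Calibration and problem sizes

The validation suite (and `scripts/acceptance.py`) uses these problem
sizes, chosen as the package's standard verification conditions:

- REML vs oracle: 20 datasets of 5–40 subjects with 1–3 observations
  each; agreement to 1e-6 relative in beta, sigma^2, sigma_b^2.
- Type-I error: four null cohorts (300 subjects, 500 features) through the
  full simulate → preprocess → screen path, ~2000 tests pooled; the
  p < 0.05 fraction must land in [0.040, 0.060].
- CI coverage: 500 cohorts with a planted interaction of 0.004; 95% Wald
  coverage must land in [0.93, 0.97], mean estimate within 5% of truth.
- End-to-end recovery: 100 seeded discovery-style runs (565 subjects, 500
  features, 5 planted interactions at beta 0.01 — the standard ranking
  calibration); every planted feature that survives QC must rank in the
  top 10 by p in at least 95 runs.  QC dropout is independent of activity
  by design, so recovery is assessed among QC-surviving planted features.

## Known limitations

- Wald z inference ignores the uncertainty in the variance components; at
  the target cohort sizes this is negligible, and the t option exists for
  small strata.
- The nearest-pool standardization is a step-function drift correction;
  smooth (e.g. LOESS) correction is out of scope.
- Ages are drawn independently per visit, so a subject's ages are not
  forced to be increasing; the fitted models only use age at sample, which
  is unaffected.
- Ancestry principal components are accepted as numeric covariate columns
  but never computed.
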