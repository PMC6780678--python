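# bdrscreen

Age-by-metabolite interaction screening on bronchodilator response (BDR)
in asthma cohorts — a tested, reusable pharmacometabolomics pipeline with
a synthetic-data generator, so every stage runs and is verifiable without
access to clinical data.

Bronchodilator response, the fractional change in FEV1 after a
short-acting β2-agonist,

    BDR = (best post-bronchodilator FEV1 − pre-bronchodilator FEV1)
          / pre-bronchodilator FEV1,

declines with age in children and adolescents with asthma.  `bdrscreen`
asks whether circulating metabolites modify that decline: for each
metabolite *f* measured by LC-MS it fits the random-intercept linear
mixed model

    BDR_ij = β₀ + covariates + β_age·age_ij + β_m·z_f,ij
             + β_int·(age_ij × z_f,ij) + b_i + ε_ij

across repeated measures of subject *i* (b_i ~ N(0, σ_b²), fitted by
profiled REML) and tests H₀: β_int = 0 with a Wald z statistic, applying
Benjamini-Hochberg FDR across the metabolome.  Single-visit replication
cohorts use per-feature OLS with the same fixed-effect structure, and
discovery hits are tiered by direction-consistent replication.

The package covers the full path from raw peak areas to figures:

- **`bdrscreen.simulate`** — longitudinal (three-visit, unbalanced) and
  cross-sectional cohort generators with known interaction effects, plus a
  raw LC-MS layer (pooled references every 20 injections, multiplicative
  drift, missingness, per-feature SNR) and a ground-truth record.
- **`bdrscreen.phenotype`** — BDR computation and cohort-table validation.
- **`bdrscreen.lcms`** — nearest-pooled-reference standardization, the QC
  cascade (SNR < 10, > 10% missing, pool CV > 25%), median imputation,
  log10 + pareto scaling.
- **`bdrscreen.lmm`** — the profiled-REML random-intercept fitter, a
  brute-force restricted-likelihood oracle for testing, Wald inference.
- **`bdrscreen.screen`** — metabolome-wide screens, BH adjustment,
  replication tiers, stratified screens, metabolite–age trends, QQ tables.
- **`bdrscreen.effects`** — predicted BDR-versus-age curves at metabolite
  percentiles, with plotting helpers.

## Worked example

```python
import bdrscreen as b
from bdrscreen.screen import run_longitudinal_screen

cfg = b.SimConfig(n_subjects=565, n_features=100, frac_active=0.05,
                  beta_int_active=0.01, seed=3)
cohort, raw, truth = b.simulate_cohort(cfg)
processed, qc = b.preprocess(raw)
results = run_longitudinal_screen(cohort, processed)
print(results.head(5)[["feature_id", "beta", "se", "p", "q"]].to_string(index=False))
```

prints (run `examples/03_interaction_screen.py` for the full script):

```
feature_id     beta       se            p            q
  met_0076 0.011459 0.001302 1.386053e-18 1.358332e-16
  met_0040 0.011755 0.001372 1.082119e-17 5.302382e-16
  met_0033 0.008536 0.001380 6.258847e-10 2.044557e-08
  met_0063 0.007534 0.001309 8.688573e-09 2.128700e-07
  met_0053 0.006537 0.001339 1.060774e-06 2.079117e-05
```

`beta` is the interaction coefficient in BDR-fraction units per
(year × scaled-metabolite unit): a beta of 0.01 means each additional
year of age changes the metabolite's association with BDR by +0.01 per
scaled unit — at these settings the five planted features head the
ranking, with BH q-values far below any conventional threshold.

The `examples/` directory holds one short narrative script per
capability: simulation, preprocessing, screening, replication, and
predicted-effect curves.  A thin CLI wraps the same functions
(`bdrscreen simulate | preprocess | screen | replicate | trends |
effects | qq`); run `bdrscreen --help`.

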