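# mixqspr

QSPR modeling of binary-mixture properties, built for the deep-eutectic-
solvent (DES) setting: a hydrogen-bond acceptor (HBA, typically a
quaternary ammonium halide salt, described via its cation) mixed with a
hydrogen-bond donor (HBD) at a fixed molar ratio, with a property such as
density ρ (g/cm³) measured over a temperature series.

The package is aimed at cheminformatics practitioners who have per-component
molecular descriptor tables (from any descriptor engine) and a table of
mixture measurements, and want interpretable multiple-linear-regression
models whose predictivity has been stress-tested against genuinely new
mixtures and new chemicals.

## The method

**Weighted-mixture descriptors.** For each base descriptor d with component
values D₁ (HBA) and D₂ (HBD) and mole fractions x₁, x₂:

    d_pmix = x₁·D₁ + x₂·D₂          (weighted sum)
    d_nmix = |x₁·D₁ − x₂·D₂|        (weighted absolute difference)

plus three passthrough variables: temperature T(K) and chloride/bromide
indicator flags.

**Data divisions.** Train/test divisions are enumerated deterministically
from two integers, *seed* and *interval*, applied to instance-count-sorted
lists — of unique mixtures (**mixtures-out**, MO: every mixture wholly on
one side) or of unique chemicals per component slot (**compounds-out**, CO:
all records of the selected chemicals go to test, so those chemicals are
never seen in training). The most-populated element always trains; divisions
with under 20 % of records in test are discarded.

**Model building.** Descriptors surviving a |r| > 0.95 correlation prefilter
enter sequential forward selection over MLR, scored by R², negative MAE, or
negative mean Poisson deviance (in-sample or k-fold CV). A proposed
descriptor is accepted only if it cuts the leave-one-out MAE (MAE_LOO) by at
least 5 %; the first rejection stops selection, so no descriptor is force-fed.

**Validation battery.** Q²_LOO/MAE_LOO; the stricter leave-chemical-out
Q²_LCO/MAE_LCO (remove each HBA, then each HBD, with all its mixtures;
average the two passes); external Q²_F1 = 1 − Σ(y−ŷ)²/Σ(y−ȳ_train)²,
MAE_test, %AARD = (100/N)Σ|y−ŷ|/y; the rm² pair built from
observed-vs-predicted regressions with and without intercept; and
Y-randomization summarized as cR²_P = R·(R² − R_r²).

**Applicability domain.** Williams-plot quantities: leverage h = x(XᵀX)⁻¹xᵀ
against the warning threshold h\* = 3(p+1)/n, and standardized residuals
with |SDR| > 3 marking response outliers.

**Consensus.** Ensembles of fitted models are combined per record: plain
average (CM0), average of qualified models (CM1), error-weighted average
(CM2, weights ∝ 1/cross-validated-MAE over the most similar training
records), or compound-wise best selection (CM3).

## Worked example

`examples/03_train_and_validate.py` generates a synthetic dataset with a
planted linear model, trains on a mixtures-out division and validates:

```
planted features:  ['desc1_pmix', 'desc2_nmix', 'desc3_pmix', 'T_K']
selected features: ['desc1_pmix', 'desc2_nmix', 'T_K', 'desc3_pmix']
y = +1.0988(±0.0042) +0.0803(±0.0004) desc1_pmix -0.0508(±0.0009) desc2_nmix -0.0005(±0.0000) T_K +0.0412(±0.0012) desc3_pmix
  step 1: desc1_pmix   MAE_LOO 0.05182 -> 0.02000 accepted
  step 2: desc2_nmix   MAE_LOO 0.02000 -> 0.01532 accepted
  step 3: T_K          MAE_LOO 0.01532 -> 0.00969 accepted
  step 4: desc3_pmix   MAE_LOO 0.00969 -> 0.00404 accepted
  step 5: has_Br       MAE_LOO 0.00404 -> 0.00403 rejected (stop)

Q2_LOO  = 0.9939   MAE_LOO  = 0.00404
Q2_LCO  = 0.9938   MAE_LCO  = 0.00404
R2_pred = 0.9960   MAE_test = 0.00370
%AARD(test) = 0.303   rm2(test) = 0.9909  delta = 0.0001
Y-randomization cR2_P = 0.9777 (as_printed variant)
```

Selection recovers exactly the planted descriptors (the candidate `has_Br`
fails the 5 % MAE_LOO reduction test and stops the search); LOO and
leave-chemical-out statistics agree because no chemical carries signal of
its own, and cR²_P ≫ 0.5 rules out chance correlation. The other examples
cover featurization (`01`), split enumeration (`02`), the applicability
domain (`04`) and grid + consensus modeling (`05`).

A thin CLI mirrors the library:
`mixqspr simulate | featurize | split | train | validate | domain | consensus | run-grid`.

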