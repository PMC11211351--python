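# IWPC pharmacogenetic dosing algorithm (Klein et al., N Engl J Med 2009).
# EXTERNAL PROVENANCE: coefficients transcribed from the original publication,
# not from the study this package models; editable.  The linear predictor is
# on sqrt(weekly dose).  Terms constant in a Han cohort are folded into the
# intercept (Asian race -0.1092 applied; enzyme inducer and missing-genotype
# terms omitted as 0).
name: IWPC
form: sqrt
scale: weekly
provenance: "Klein et al. 2009 pharmacogenetic algorithm; Asian indicator folded into intercept"
intercept: 5.4952
terms:
  - {covariate: age_decades, coef: -0.2614}
  - {covariate: height_cm, coef: 0.0087}
  - {covariate: weight, coef: 0.0128}
  - {covariate: vkorc1_ga, coef: -0.8677}
  - {covariate: vkorc1_aa, coef: -1.6974}
  - {covariate: cyp2c9_12, coef: -0.5211}
  - {covariate: cyp2c9_13, coef: -0.9357}
  - {covariate: cyp2c9_22, coef: -1.0616}
  - {covariate: cyp2c9_23, coef: -1.9206}
  - {covariate: cyp2c9_33, coef: -2.3312}
  - {covariate: amiodarone, coef: -0.5503}
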