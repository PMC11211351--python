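# Gage clinical+pharmacogenetic dosing algorithm (Gage et al., Clin
# Pharmacol Ther 2008).  EXTERNAL PROVENANCE: coefficients transcribed from
# the original publication; editable.  Linear predictor on ln(mg/day).
# Terms constant or near-constant in a Han cohort (smoker, African-American,
# DVT indication) are omitted; the target-INR term is folded into the
# intercept at target INR 2.2 (0.2029 x 2.2).
name: Gage
form: log
scale: daily
provenance: "Gage et al. 2008; target-INR term folded at 2.2, race/smoking/DVT omitted"
intercept: 1.42148
terms:
  - {covariate: vkorc1_a_count, coef: -0.3238}
  - {covariate: cyp2c9_star2_count, coef: -0.2066}
  - {covariate: cyp2c9_star3_count, coef: -0.4008}
  - {covariate: age, coef: -0.00745}
  - {covariate: bsa, coef: 0.4317}
  - {covariate: amiodarone, coef: -0.2538}
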