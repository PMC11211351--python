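# Default population parameters of the warfarin INR model (final published
# estimates; PK side and transit/INR scale fixed, PD covariate side estimated).
theta:
  cl_allele_1: 0.174      # L/h per CYP2C9 *1 allele
  cl_allele_2: 0.0879     # L/h per *2 allele
  cl_allele_3: 0.0422     # L/h per *3 allele
  age_slope: -0.00571     # fractional CL change per year (-0.571 %/yr)
  v_f: 14.3               # L
  ka: 2.0                 # 1/h (absorption; conventional value, not reported)
  emax: 0.174             # maximal fractional inhibition (as published)
  gamma: 1.39             # Hill coefficient
  ec50_g: 4.3             # mg/L per VKORC1 G allele
  ec50_a: 1.14            # mg/L per VKORC1 A allele
  theta_wt: 1.34          # power of (WT/60) on EC50
  theta_cm1: -0.602       # mg/L EC50 shift on amiodarone
  mtt1: 27.2              # h
  mtt2: 110.9             # h (27.2 + 83.7)
  n1: 2
  n2: 2
  inr_max: 20.0
  age_ref: 60.0
  wt_ref: 60.0
omega: 0.558              # SD of lognormal eta on EC50 (55.8% CV)
sigma: 0.365              # proportional residual error (36.5%)
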