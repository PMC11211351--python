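# warfinr

Population pharmacokinetic/pharmacodynamic modelling of warfarin
anticoagulation response (INR) for a Han Chinese population, with MAP
Bayesian dose individualization.

Warfarin dosing is notoriously hard: the dose producing a therapeutic INR
(typically 2–3) varies several-fold between patients, driven by CYP2C9
variants (S-warfarin clearance), the VKORC1 −1639G>A promoter polymorphism
(target sensitivity), body weight, age and interacting drugs such as
amiodarone. `warfinr` implements a nonlinear mixed-effects PK/PD model of
this system — the Hamberg-type transit-compartment INR model re-estimated
for a Han population — together with everything needed to exercise it at
desk scale: a synthetic-cohort generator, Laplace population estimation,
MAP Bayesian individual estimation, stepwise covariate selection, bootstrap
validation, and maintenance-dose prediction compared against published
regression dosing algorithms (IWPC, Gage, the FDA label genotype table).

## Model

One-compartment oral PK with additive per-allele clearance and a linear age
effect, sigmoid-Emax inhibition of clotting-factor synthesis, and two
parallel transit chains whose combined deficit maps linearly to INR:

```
CL       = (CL_a1 + CL_a2) · (1 + θ_age·(AGE − 60))          [L/h]
EC50     = TVEC50 · (WT/60)^θwt + CM1·θcm1                   [mg/L]
EC50_i   = EC50 · exp(η),      η ~ N(0, ω²)
EFF(t)   = Emax·C(t)^γ / (EC50_i^γ + C(t)^γ)
dA_j1/dt = ktr_j·(1 − EFF) − ktr_j·A_j1,   ktr_j = n_j/MTT_j
dA_jk/dt = ktr_j·(A_j,k−1 − A_jk)
INR(t)   = INR_base + INR_max · (1 − (A_1,n1 + A_2,n2)/2)
obs      = INR(t) · (1 + ε),   ε ~ N(0, σ²)
```

TVEC50 is the mean of the two VKORC1 allele EC50 values; clearance is the
sum of the two CYP2C9 allele values. Defaults (in
`warfinr/data/model_default.yaml`) are the published final estimates: CL per
*1/*2/*3 allele 0.174/0.0879/0.0422 L/h, −0.571 %/yr age effect, V/F 14.3 L,
Emax 0.174, γ 1.39, EC50 per G/A allele 4.3/1.14 mg/L, weight exponent 1.34,
amiodarone shift −0.602 mg/L, MTT 27.2/110.9 h, INRmax 20, ω 55.8 %,
σ 36.5 %.

The transit chains are linear in the forcing 1−EFF(t), so trajectories are
computed by exact first-order-hold discretization of each stage instead of a
generic ODE solver; a full-cohort likelihood evaluation is a few vectorized
array passes, which keeps population fits, bootstrap and stepwise selection
fast enough for a laptop.

## Worked example

```python
import numpy as np
from warfinr import (CohortSpec, sample_cohort, simulate_observations,
                     fit_population, find_maintenance_dose, DEFAULT_THETA)

patients = sample_cohort(CohortSpec(n_subjects=200, seed=1))
sim = simulate_observations(patients, DEFAULT_THETA, omega=0.558,
                            sigma=0.365, seed=2)
fit = fit_population(sim.patients, DEFAULT_THETA)
print({k: round(v, 3) for k, v in fit.params.items()})
```

Running the same experiment through the analysis drivers
(`python analysis/01_simulate_cohort.py && python analysis/02_fit_population.py`)
prints, for the default seed:

```
converged=True  OFV=3494.32
  parameter  estimate  rse_percent  ci95_lo  ci95_hi  published
     ec50_g     4.154       10.800    3.275    5.033      4.300
     ec50_a     1.209        5.563    1.077    1.340      1.140
beta_weight     1.335       11.018    1.046    1.623      1.340
   beta_cm1    -0.699       10.368   -0.841   -0.557     -0.602
      omega     0.514        7.767    0.435    0.592      0.558
      sigma     0.360        2.051    0.346    0.375      0.365
CWRES: mean -0.010, sd 1.000, |CWRES|>6 outliers: 0/1613
```

i.e. the Laplace fit recovers the generating (published) values of the
estimable PD parameters from 200 virtual subjects, with conditional weighted
residuals that are standardized (mean ≈ 0, sd ≈ 1) and free of |CWRES| > 6
outliers. Dose individualization then inverts the model:

```python
p = sim.patients[0]
print(find_maintenance_dose(p, target_inr=2.5).dose)   # mg/day, eta = 0
```

`analysis/03…05` reproduce the remaining stages: covariate screening picks
weight/BMI/amiodarone (and stepwise selection lands on exactly
{weight, amiodarone}, ΔOFV −25.5 and −28.5 on the example cohort), the
bootstrap (200 resamples) returns medians within a few percent of the
original estimates with an amiodarone interval excluding zero, and the dose
comparison shows the MAP-updated mechanistic predictor beating the external
regression models on cohorts generated by the model itself (MPE 1.85 mg/day
vs 4.7–5.3 mg/day).

A thin CLI mirrors these stages:
`warfinr simulate|map|fit|select|bootstrap|dose|compare --help`.

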