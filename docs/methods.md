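# Methods

## Structural model

The model is a Hamberg-type warfarin PK/PD model with parameters
re-estimated for a Han population. PK is a one-compartment model with
first-order absorption and oral clearance composed additively from the two
CYP2C9 alleles, scaled by a linear age effect centered at 60 yr
(−0.571 %/yr). Concentrations are evaluated by exact superposition of the
analytic single-dose solution (the ka = ke limit uses the analytic limiting
form), so PK involves no numerical integration. Racemic dose in mg is used
throughout; no enantiomer splitting.

PD: warfarin concentration inhibits clotting-factor synthesis through a
sigmoid-Emax function; the inhibition drives two parallel transit chains
(n = 2 compartments each by default, ktr = n/MTT, MTT 27.2 h and 110.9 h)
whose combined deficit maps linearly onto INR with scale INRmax = 20 above
the patient's pre-treatment baseline. A single lognormal random effect acts
on EC50; residual error is proportional, y = f·(1+ε).

The genotype composition rules are: clearance = sum of allele values (this
reproduces the six-genotype clearance ordering *1/*1 > *1/*2 > *1/*3 >
*2/*2 > *2/*3 > *3/*3); typical EC50 = mean of the two VKORC1 allele values
(so homozygotes equal the per-allele estimates and GA lies midway). The
covariate model on EC50 is `TVEC50·(WT/60)^1.34 + CM1·(−0.602)` — the
additive amiodarone shift in mg/L matches the published statements "decrease
by 0.602 mg/L" and "+22.9 % per 10 kg". EC50 and CL are floored at 1e−6 of
their units to preserve positivity.

Two published values deserve note. Emax is fixed at the printed 0.174 even
though the reference model family usually fixes Emax = 1 and the value
coincides suspiciously with the CL-per-*1-allele estimate; all recovery
experiments avoid depending on Emax. The reference age of the CL age effect
is not printed; 60 yr (the analogue of the 60 kg weight centering) is used
and exposed as `age_ref`. Absorption ka is not printed; 2 h⁻¹ is
conventional for this model family and PK is fixed during estimation anyway.

## Trajectory computation

The transit ODEs are linear and time-invariant in the forcing u(t) =
1−EFF(t). Each first-order stage is advanced on a uniform grid by exact
first-order-hold (FOH) discretization (piecewise-linear input), which is
exact for constant forcing — hence the analytic fixed point INR = base +
INRmax·EFF is reproduced to ~1e−14 — and O(dt³) accurate otherwise.
Against a tightly-toleranced `solve_ivp` oracle the dense INR trajectory
agrees to ≤7e−4 INR at dt = 0.5 h (≤3e−3 at dt = 1 h), far below the 36.5 %
residual noise. Single-patient trajectories default to dt = 0.5 h;
cohort-level estimation uses dt = 1 h (fits at dt = 0.5 were checked to give
identical estimates to three decimals). When numba is present the default
two-stage chains run in a single fused kernel; the scipy `lfilter` path is
the reference implementation and the two agree to machine precision.

## Estimation

The individual objective is the exact −2 log of (Gaussian proportional-error
likelihood × lognormal prior), with the error variance evaluated at the
individual prediction f(η). Note a consequence: for data equal to the
typical prediction the MAP η is only ≈ 0 up to O(σ²), because the
ln (σf(η))² term rewards lower predictions; the identity becomes exact as
σ → 0.

Population estimation follows the Laplace approximation of the marginal
likelihood: per subject, −2 log L ≈ obj(η̂) + ln(obj″(η̂)/2) − ln 2π, with
the inner MAP problem solved for all subjects simultaneously (coarse scan
over ±max(4ω, 2.5), golden-section refinement; the absolute floor on the
scan half-width prevents trial values of ω well below the data-generating
scale from clamping outlying subjects). The curvature uses a central
difference; a non-positive curvature falls back to the prior curvature with
a warning. A subject without observations contributes exactly zero. OFVs
are therefore comparable only as differences (Δ-OFV), matching standard
pharmacometric practice; no absolute OFV is compared against published
tables.

The outer fit moves {EC50_G, EC50_A, covariate coefficients, ω, σ} —
everything else fixed — by Nelder–Mead on log scale for positive
parameters, clipped to e^±5 with boundary events flagged. Two effort
levels: "full" (two chained simplex runs, tight tolerances; used for
headline fits) and "fast" (single warm-started run; used inside bootstrap
and stepwise where thousands of refits are needed). Standard errors come
from the central-difference OFV Hessian on the transformed scale
(Cov = 2H⁻¹, delta method back), with eigenvalue clipping for near-flat
directions (conservative SEs, flagged). CWRES uses the standard
linearization in η at η̂: residual y − (f − gη̂) whitened by
(ω²ggᵀ + σ²diag f²)^{1/2}; the outlier convention is |CWRES| > 6.

Known estimator behavior at the study conditions (200 subjects, ~8
observations each, σ = 36.5 %): ω is recovered with ≈ −5 % bias (present
also under adaptive quadrature of the marginal, so a finite-sample property
rather than a Laplace artifact) and σ tracks the *realized* residual CV of
the data within ~1 %. Coverage and recovery tests therefore target the
realized residual scale for σ (see below) and use medians over replicate
cohorts for headline comparisons.

## Synthetic cohorts

The generator emulates the study population: age 54.7 ± 12.5 yr (truncated
1–82), weight 59.7 ± 11.6 kg (7–106), height 161.9 ± 9.3 cm, CYP2C9 *1/*1
94.3 % / *1/*3 5.7 % (no *2 in this population; a frequency override exists),
VKORC1 AA/GA/GG 80.3/18.7/0.9 %, amiodarone 25.7 %, statins 37.3 %, azoles
2.6 %, antibiotics 0.6 %, baseline INR 1.13 (truncated normal, sd 0.15,
min 0.82 — the reported baseline range is right-skewed; a truncated normal
is an approximation). Truncated normals are sampled by rejection; genotypes
by inverse CDF.

Dosing is once daily on the 0.625–6.25 mg grid for 15 days (no titration).
Each subject's dose is chosen clinically plausibly but deterministically:
the grid dose whose typical-patient (η = 0) steady-state average
concentration D/(CL·24) meets a target INR of 2.2 via the closed-form Emax
inversion, plus one random grid step of jitter, clipped to the grid. INR
observation times: one pre-dose baseline row at t = 0 plus 7–9 post-dose
measurements on uniformly drawn dosing days, with time-after-dose drawn 70 %
from the 7–10 h window and 30 % uniformly in 0–24 h (the study sampled
mostly 7–10 h post-dose; total measurements per subject ≈ the study's 8.5
mean). The t = 0 row defines BASE and is excluded from all likelihoods —
including it would produce exact-zero residuals and bias σ̂ downward.

Observations get proportional noise; a draw below INR 0.3 is redrawn once
and then clipped (logged). With σ = 36.5 % and typical INR 1.2–2.4 this
guard fires on ~1.4 % of draws and truncates the lower noise tail, so the
*realized* residual CV of generated data is ≈ 34–35.5 %, slightly below the
nominal σ. This is a property of the generated conditions, not of the
estimator; tests that check σ recovery in the confidence-interval sense
target the realized CV, while band checks against the published bootstrap
interval use the estimates as-is.

What passing tests show — and do not show. The generator draws covariates
independently (no weight–height–age correlation beyond BMI's definition),
uses fixed regimens without clinician titration or compliance gaps, Gaussian
noise instead of the heavy-tailed errors of real INR data, and no
inter-occasion variability. Recovery of the generating parameters therefore
demonstrates the estimation machinery is correct and well calibrated at the
study's design, not that the model fits any particular real cohort.

## Covariate selection and bootstrap

Screening associates empirical-Bayes η̂ from the covariate-free model with
candidates: Spearman rank correlation for continuous covariates, Wilcoxon
rank-sum for binary flags, α = 0.05; constant covariates are excluded with
a note, and when weight and BMI both pass, weight is preferred (the
clinically simpler measure). Stepwise selection is greedy forward inclusion
at ΔOFV > 3.84 (χ²₁, α = 0.05) then backward elimination at ΔOFV > 6.63
(α = 0.01). Continuous candidates enter as power terms on EC50,
binary ones as additive shifts, mirroring the final model's two forms. The
source study reports its OFV ledger but not its inclusion thresholds; the
standard ones are used. At
desk scale the candidate refits use the fast effort level, which makes the
forward test slightly conservative (empirical null inclusion below the
nominal 5 %).

The bootstrap resamples subjects with replacement to the original cohort
size and refits warm-started from the original estimates; "minimization
success" is optimizer convergence with finite OFV and no parameter-bound
hits (the per-replicate Hessian is not computed, on cost grounds).
Percentile 2.5–97.5 % intervals and medians are reported next to the
original estimates.

## Dose engine

The maintenance dose is found by `brentq` root bracketing on the monotone
map dose → steady-state INR, where steady state is the average INR over the
final 24 h of a ≥10×MTT₂ horizon of constant daily dosing; inversion error
is < 2e−3 INR. A-priori dosing uses η = 0, a-posteriori dosing the MAP η
from available INRs. "Ideal prediction percentage" (not defined in the
source literature) is the fraction of subjects predicted within ±20 % of the
actual dose, exposed as a configurable band. The external comparator models
(IWPC, Gage, FDA label table) ship as editable YAML with provenance notes;
coefficients constant in a Han cohort are folded into their intercepts, and
none of their outputs is used as a reference value anywhere in the tests.

## Problem sizes

Desk-scale experiment sizes, chosen to exercise every stage with useful
statistical power: parameter recovery uses ten (tests) or three (acceptance
script) replicate 200-subject cohorts with ~8 observations each over 15
days, summarized by medians; stepwise-selection power uses twenty
150-subject cohorts (10-day horizon) plus twenty-five 40-subject null
cohorts; the bootstrap demonstration uses 200 resamples of an 80-subject
cohort. The modelling/validation ID split utility reproduces the study's
83/17 split.

## Known limitations

Laplace (not FOCE-I or exact quadrature) is the marginal-likelihood
approximation; its small variance-component bias at high residual noise is
documented above. PK parameters are fixed by design and never estimated.
The CLI covers the common paths only. Comparator coefficients are
transcriptions and should be re-verified against the original publications
before any applied use. This package is a research tool for methodology;
it must not be used to dose patients.
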