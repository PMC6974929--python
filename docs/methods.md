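# Methods

## The model

`arspk` implements a simultaneous drug–metabolite population pharmacokinetic
model for oral artesunate (ARS) and its active metabolite dihydroartemisinin
(DHA) in adult women with uncomplicated falciparum malaria, and the full
analysis workflow around it: synthetic-trial generation, nonlinear
mixed-effects estimation with censored observations, covariate selection,
bootstrap and visual-predictive-check diagnostics, and pregnancy-impact
exposure simulation.

### Structural model

Absorption is a chain of three hypothetical transit compartments with a
common rate constant, producing an Erlang-shaped absorption delay:

    depot →kTR→ T1 →kTR→ T2 →kTR→ T3 →kTR→ ARS →k23→ DHA →k30→ out

with `kTR = (NN+1)/MTT`, `NN = 3`. Artesunate is eliminated from a single
central compartment by first-order hydrolysis assumed to convert *entirely*
into DHA (`k23 = CL_ARS/V_ARS`); DHA follows one-compartment disposition
with first-order elimination (`k30 = CL_DHA/V_DHA`). A dose deposits
`F1 × AMT` mg in the depot, where F1 is the subject's relative oral
bioavailability (population value fixed at 1). No molar-mass correction is
applied in the ARS→DHA transfer: amounts move compartment-to-compartment
directly, so DHA parameters are interpreted in artesunate-mass equivalents.

Units: doses mg, volumes L, clearances L/h. Predicted concentrations are
converted to ng/mL (×1000 from mg/L) before comparison with the assay
LLOQs, which are quoted in ng/mL (1.2 ARS, 2.0 DHA).

### Parameter model

Individual parameters are log-normal around covariate-adjusted typical
values (η ~ N(0, ω²), diagonal):

- `CL_ARS,i = θ_CL_ARS (WT/52)^0.75 e^η1`
- `V_ARS,i  = θ_V_ARS (WT/52)`
- `CL_DHA,i = θ_CL_DHA (WT/52)^0.75 (1 + θ_PREG·PREG) e^η2`
- `V_DHA,i  = θ_V_DHA (WT/52)`
- `MTT_i    = θ_MTT e^η3`
- `F1_i     = (1 + θ_ALT (ALT − 20.75)) (1 + θ_BIO (LNPC − 5.88)) e^η4`

Weight enters allometrically (exponent 0.75 on clearances, 1 on volumes),
centered at the 52 kg cohort median; ALT and log parasite count enter
linearly on bioavailability, centered at their cohort medians. IIV is
carried on the two clearances, MTT and F; the volumes carry none (their
variances are structurally fixed at 0). Residual error is additive on the
natural-log concentration scale, with a separate variance per analyte —
equivalent to an exponential error on the arithmetic scale.

Final (published) values used as the generating model and default start:
CL_ARS/F 3570 L/h, V_ARS/F 1700 L, CL_DHA/F 190 L/h, V_DHA/F 267 L, MTT
0.832 h, pregnancy +21.4% on CL_DHA, +2.15%/IU ALT and +13.8%/log-unit
parasite biomass on F; ω² = 0.0672 / 0.00810 / 0.320 / 0.0887 (CL_ARS,
CL_DHA, MTT, F); σ² = 0.892 (ARS), 0.660 (DHA).

## Solving the linear system

The cascade is linear with rate constants `(kTR×4, k23, k30)`. The bolus
response has a closed form from partial fractions of
`k⁴ / ((s+k)⁴ (s+a)(s+b))` — a fourth-order pole at the transit rate and
two simple poles. The partial-fraction coefficients scale as inverse powers
of the pairwise rate gaps, so the expression cancels catastrophically when
rates cluster (the transit rate crossing the ARS elimination rate is common
once random effects are drawn). Rather than guessing a safe pairwise-gap
threshold, the implementation computes an explicit roundoff bound alongside
each value (machine epsilon × the sum of term magnitudes, including the
cancelling parts inside each coefficient) and re-evaluates any parameter
set whose bound exceeds `1e-7·|value| + 1e-12` per unit dose by one of two
robust routes:

- a confluent series in `d = kTR − k23` (exact through the degeneracy,
  ~1e-13 relative) when the other rate pairs are separated and `|d·t| ≤ 5`;
  its inner moment integrals `∫ s^m e^{-cs} ds` use the incomplete-gamma
  form for `c > 0` and an all-positive power series for `c ≤ 0`;
- the matrix exponential of the conservation-augmented 7×7 rate matrix
  (exact for repeated eigenvalues) otherwise.

The closed form is evaluated vectorized across subjects, finite-difference
perturbations and time points at once; this is what makes the inner
optimization of the marginal likelihood affordable. Validation: profiles
agree with an independent adaptive ODE integration (`solve_ivp`, DOP853,
rtol 1e-12) to rtol 1e-6 with an absolute floor of 1e-9 of the dose, over
randomized draws including forced degeneracies; mass balance (all
compartments plus cumulatively eliminated mass) holds to 1e-9 relative.

Multiple doses superpose; the headline analysis uses the first dose only,
because sampling spans 0–12 h after it.

## Likelihood and estimation

Quantified observations contribute a Gaussian density on the log scale.
Samples below the LLOQ contribute their censoring probability
`Φ((log LLOQ − IPRED)/σ) + 1e-6` (the M3 method); the `1e-6` floor is kept
from the published model code as a fidelity choice (it bounds the log away
from −∞) and can be disabled. M1 (discard) and M5 (impute LLOQ/2) are
available for comparison; M3 requires the Laplacian.

The marginal likelihood integrates over each subject's η by Laplace's
method with the observed (finite-difference) Hessian at the posterior mode.
The inner mode search is a damped Newton iteration vectorized across all
subjects: one broadcast evaluation per iteration supplies the full
finite-difference gradient/Hessian stencil (step 5e-4), steps are clipped
to 3 in η-norm and backtracked; the gradient tolerance is 1e-5 with
convergence reported at 1e-3 (the finite-difference noise floor makes
tighter targets illusory; the OFV error from a mode located to 1e-4 is
O(1e-8)). During an outer fit the modes are warm-started from a per-subject
cache. A FOCE-style variant replaces the Hessian with the expected
(score-outer-product) information; because the residual variance here does
not depend on the prediction, the two differ only in that Hessian
treatment.

The OFV is −2× the approximate marginal log-likelihood *including* all
Gaussian constants; `include_constant=False` drops the `n·log 2π` data
constant (the convention of common estimation software). ΔOFV-based
likelihood-ratio tests are identical under either convention (3.84 ≈
p 0.05, 6.63 ≈ p 0.01 at one degree of freedom).

The outer problem minimizes the OFV with L-BFGS-B on a transformed scale:
log for positive typical values and variances, raw within box bounds for
the signed covariate effects (bounds mirror the published model's coded
bounds, e.g. (−0.024, 0.057) for the ALT effect, chosen to keep F positive
over the covariate range). Convergence: optimizer success plus inner-mode
convergence for every subject; the returned OFV never exceeds the OFV at
the start values. Laplace agrees with direct numerical integration
(adaptive quadrature / 64-node adaptive Gauss–Hermite) to <0.01 OFV units
on one- and two-η subjects.

### Covariate machinery

Stepwise selection adds the best-improving candidate effect while the OFV
drop exceeds the χ²(1) threshold at α=0.05, then removes effects whose
deletion costs less than the α=0.01 threshold; ties break toward the
lexicographically first parameter:covariate label. The full covariate
approach places a categorical pregnancy effect simultaneously on F, CL_ARS,
CL_DHA and MTT and bootstraps it (default 500 replicates, stratified on
pregnancy) to give the effect-distribution box plots, with a ±20% band
marking assumed clinical relevance.

## Diagnostics

- **CV%** of a log-normal random effect: `100·sqrt(exp(ω²) − 1)`. This is
  the square-root form; it reproduces the published CV% for three of the
  four variances exactly to three significant figures, and gives 9.02% for
  ω² = 0.00810 where 9.00% is printed — the difference is the rounding of
  the printed variance itself.
- **CWRES** by first-order linearization about the conditional modes:
  `Cov ≈ G Ω Gᵀ + Σ` with G the finite-difference sensitivity of the
  log-scale predictions to η; censored records are excluded from residuals
  and contribute only to the BLQ panels.
- **Shrinkage**: η-shrinkage `1 − SD(EBE)/ω` per dimension, ε-shrinkage
  `1 − SD(IWRES)` per analyte.
- **pcVPC**: prediction correction on the arithmetic concentration scale by
  the bin-median population prediction over the individual population
  prediction; one bin per nominal sampling time (the design is fixed-time);
  default 2000 simulation replicates give 95% bands for the 5th/50th/95th
  percentiles and for the BLQ fraction per bin.
- **Bootstrap**: subjects resampled with replacement within pregnancy
  strata preserving stratum sizes (default 1000 replicates), refits
  warm-started from the original estimates; summaries (mean, SD,
  RSE% = 100·SD/mean, percentile CIs) over successful fits only, with the
  success count reported.

## Synthetic-trial generator

The generator emulates the trial the model was built on: 24 pregnant and 24
non-pregnant women; a single weight-banded oral dose (1.5 / 2 / 2.5 tablets
of 100 mg artesunate for <50 / 50–60 / >60 kg — band edges: 50 and 60 kg
take 2 tablets); venous samples at 0.25, 0.5, 1, 2, 3, 4, 5, 6, 8, 10 and
12 h post-dose; log-normal IIV; additive log-scale residual noise applied
before censoring; raw concentrations below the analyte LLOQ flagged BQL=1
with the DV masked. Pre-dose screening records are emitted with MDV=1 and
never enter the likelihood (how the original analysis handled them is not
stated; the reported BLQ fractions here use post-dose samples only).

Covariates are drawn from truncated normal (weight, haemoglobin) and
truncated log-normal (parasite density, AST, ALT, bilirubin) distributions
whose supports are the published admission ranges and whose location is
calibrated (by root finding) so the *truncated* median equals the published
group median; the spread parameters were chosen once so the ranges are
plausibly covered. Gestational age is uniform on 4–8 months for pregnant
women and 0 otherwise. The distribution families are a modelling choice:
only medians and ranges are published. What the generator does **not**
emulate: assay error structure beyond the fitted residual model, dropout or
missed samples, actual enrolment correlation between covariates (they are
drawn independently), or day-2/3 dosing (supported by superposition but
unused). Passing recovery tests therefore demonstrate estimator
correctness under the stated design, not robustness to real-data
pathologies.

Under the published model and design, the simulated censored fractions come
out near 62% (ARS) and 21% (DHA) with no tuning — they are a consequence of
the profile shape, the sampling times and the LLOQs.

The paired exposure simulation gives each simulated pregnant woman a
non-pregnant twin with identical weight, covariates *and random effects*,
isolating the covariate effect; sharing the random effects makes the DHA
AUC ratio analytically exact at 1/(1+θ_PREG), a useful invariant (whether
to share them is a design choice — only "identical except pregnancy" is
specified for the original comparison). AUC uses the closed form `F·Dose/CL`; CMAX/TMAX are read off
the analytic profile on a 0.01 h grid over 0–12 h refined by bounded local
maximization (no tmax procedure is published).

## Problem sizes used in the checks

The acceptance computations use 10 simulate-and-refit replicates at the
full 48-subject design, 20 seeds for the censored-fraction summary, 200
simulation replicates for the pcVPC self-consistency check, and half-size
(24-subject) cohorts for the M3-vs-M5 bias comparison — sizes chosen so the
whole suite runs on a laptop-class single core in minutes while the Monte
Carlo error stays well inside the tolerances being checked. Library
defaults keep the published sizes (1000 bootstrap, 2000 VPC simulations,
500 full-covariate bootstrap, 1000 per group in exposure simulation).

## Known limitations

- The Laplacian with heavy censoring carries finite-sample bias; the
  simulate-and-refit means sit within the published bootstrap CIs but
  individual replicates scatter (that scatter is the sampling distribution
  at n=48, not a defect).
- Omega is diagonal throughout (as in the final published model);
  correlated random effects are out of scope.
- No saturable elimination, enterohepatic recirculation, or
  pharmacodynamics; the rejected two-compartment DHA structure exists only
  as a comparator in model-selection tests, not as a supported analysis
  path.
- Standard errors come from the bootstrap, not from an asymptotic
  covariance matrix of the Laplacian objective.
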