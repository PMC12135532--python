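# Methods

## Structural model

Fosfomycin disposition is modeled with two compartments in *amounts*
(central A_c, peripheral A_p), zero-order infusion input, and two parallel
first-order elimination pathways acting on the central compartment:

    dA_c/dt = rate(t) − [(CL_body + CL_KRT(t)) / V_C]·A_c − (Q/V_C)·A_c + (Q/V_P(t))·A_p
    dA_p/dt = (Q/V_C)·A_c − (Q/V_P(t))·A_p

Concentration is A_c/V_C. Working in amounts matters because the
peripheral volume of anuric subjects grows with time: volume growth then
dilutes the peripheral concentration without creating or destroying drug.
The intercompartmental flux uses the instantaneous V_P(t); the alternative
(baseline V_P in the flux) was considered and rejected because it breaks
the interpretation of Q as a flow between well-stirred spaces.

### Covariate model

* Body clearance: `CL_body = θ_CL (eGFR/48.4)^θ_KF exp(η_CL)`, set to
  exactly 0 for anuric subjects (24-h urine output < 100 mL) and for the
  study-B cohort, whose patients showed no measurable elimination between
  dialysis sessions. eGFR is the 4-variable IDMS-traceable MDRD estimate
  (coefficient 175, no race term — the cohort emulated is European /
  Australian ICU); the CKD-EPI 2009 and Cockcroft–Gault equations are
  implemented for covariate screening parity but do not enter the final
  model.
* Dialysis clearance: `CL_KRT = θ_DIAL (Q_D/42)^θ_QD` during a dialysis
  session, 0 otherwise. Sessions are half-open intervals `[start, end)`.
  No inter-individual variability is placed on this pathway. A mass
  transfer–area (K_oA/Michaels) dialyzer model is deliberately out of
  scope: it requires dialyzer-specific coefficients that would not
  generalize across modalities, whereas the Q_D power law does.
* Peripheral volume: `V_P = θ_VP (1 + TSFD·θ_T) exp(η_VP)` with TSFD in
  minutes; the time slope is active only for anuric subjects (fluid
  retention under severely reduced kidney function). η_VP multiplies the
  whole time-varying volume, so slope and intercept scale together.

### Variability

η_CL, η_VC, η_VP are independent normal (diagonal Ω — no correlations are
estimated), applied exponentially. The `%CV` reporting convention is
`100·sqrt(exp(ω²)−1)`. Residual error is combined
proportional + additive on the concentration scale,
`Var = (σ_prop·pred)² + σ_add²`, with σ_prop a fractional SD (0.147 at the
default estimates) and σ_add in mg/L (21.9). Default parameter values are
the published full-data-set estimates; the reduced-data-set column (the
study-B-excluded sensitivity fit) ships as an alternative preset.

## Simulation engine

Dosing and dialysis schedules are compiled into maximal segments on which
the infusion rate and CL_KRT are both constant. Three solution paths share
this segmentation:

* `simulate_profile` — reference single-subject integrator
  (scipy `solve_ivp`, LSODA, rtol = atol = 1e−9) restarted at every
  breakpoint so discontinuities are never integrated across.
* `analytic_twocpt` — exact piecewise solution for constant V_P via the
  spectral form of the 2×2 matrix exponential (with `expm1` so the
  zero-clearance eigenvalue limit is exact); the in-package oracle.
* `simulate_population` — the same closed-form propagation vectorized over
  subjects. The growing V_P is handled by freezing it at the midpoint of
  sub-steps of ≤ 0.1 h; V_P changes 0.42 % per 0.1 h at the default slope,
  and the midpoint rule leaves a relative concentration error of ~1e−5
  (verified against `simulate_profile` in the tests).

Numerical conventions: internal time unit is hours (θ_T, printed per
minute, is converted once at the model boundary); output grid default
0.1 h; concentrations are clipped at 0 only to absorb −1e−9-scale
integrator noise.

## PK/PD evaluation

AUC₂₄₋₄₈ is the trapezoidal integral on the simulation grid with
interpolated window endpoints; %T₂₄₋₄₈>MIC treats the profile as piecewise
linear and locates threshold crossings exactly within grid intervals (a
0.1 h grid is converged to well under 0.5 percentage points). A target is
attained when the index is **≥** the threshold; under continuous
variability ties have probability zero, so the choice of ≥ over > is a
documented convention, not a results driver. PTA uses
individual-predicted concentrations — inter-individual variability only,
no residual error — the standard pharmacometric practice, since residual
error represents assay noise rather than true exposure. MIC grid:
doublings 4–512 mg/L.

## Scenario grid and recommendation rule

Per scenario, 2,000 virtual subjects are simulated over 48 h. Regimens:
4/5/8 g q8h, 8 g q12h, 4 g q6h, all starting at t = 0 with 60-min
infusions (the source studies infused over 30–120 min; the simulated
duration is configurable and a sensitivity switch, because the published
simulation settings do not pin it down). CKRT runs 0–48 h at
Q_D = 42 mL/min; PIKRT is one 8-h session on day 2 (24–32 h, start time
configurable) at Q_D = 250 mL/min, with no session on day 1. eGFR is
drawn uniformly within the stratum interval (0–30, 31–60, 61–90,
91–120 mL/min/1.73 m²) and held constant over the 48 h; this within-stratum
sampling scheme is the main reproduction uncertainty of the scenario grid,
as only band-level results are published. The anuria stratum (simulated
with KRT only) sets CL_body = 0 and activates the V_P time slope
regardless of the nominal eGFR.

The recommendation rule picks, per (KRT type, stratum, MIC, activity), the
lowest-daily-dose regimen reaching PTA ≥ 90 %, falling back to ≥ 80 %
(flagged), else "N/A". Daily-dose order: 12 (4 g TID) < 15 (5 g TID) <
16 g — tie between 8 g BID and 4 g QID broken toward fewer administrations
— < 24 g (8 g TID).

A note on an intuitive invariant: the recommended dose is monotone in
kidney function *across the eGFR strata*, but the anuria stratum is not
ordered against the 0–30 stratum at borderline targets. Anuric subjects
have zero body clearance (more exposure) yet a growing peripheral volume
(slower accumulation into the 24–48 h window), and at marginal AUC targets
the second effect can dominate. The property tests therefore assert
monotonicity over the four eGFR strata only.

## Estimation

The marginal likelihood integrates the conditional data likelihood over
each subject's η. We use the Laplace approximation: the conditional
−2 log-likelihood is minimized over η (damped Newton with
finite-difference derivatives, warm-started from the previous outer
iteration's empirical Bayes estimate, step capped at 4 SD), and

    −2 log L_i ≈ m2ll(η̂) − d·log 2π + log det(½ H)

with H the Hessian at the mode. This replaces NONMEM's FOCE-I, whose
interaction terms are implementation-internal; an adaptive-quadrature
oracle in the test suite bounds the approximation error at ≤ 0.5 OFV units
on one-η problems, and the linear-Gaussian case (where Laplace is exact)
is checked in closed form.

The outer problem maximizes the summed marginal likelihood over the fixed
effects, Ω diagonal and residual parameters with L-BFGS-B; positive
parameters are estimated on the log scale, the two covariate exponents
unbounded. For likelihood evaluation the two-compartment system is solved
with the exact piecewise propagator (pure-Python inner loop, ~0.1 ms per
subject); for anuric subjects V_P is frozen within 0.5-h chunks, accurate
to ~0.1 % in concentration — far below the residual noise. Relative
standard errors come from the inverse central-difference Hessian of the
OFV (covariance = 2 H⁻¹) and are computed on request only, since a
13-parameter Hessian costs ~2·13² objective evaluations. Observation rows
enter the likelihood only when `EVID = 0, MDV = 0`; there is no
below-quantification handling (none is needed for the emulated designs).
Default initial estimates are deliberately generic (e.g. CL 1 L/h,
V_C 30 L, exponents 1 and 0.5) rather than the published values.

Covariate search: candidate effects are multiplicative terms (linear in
the centered covariate, power around the cohort median, or Emax) on
CL_body, V_C, V_P or Q. Forward inclusion accepts the largest OFV drop
exceeding the χ² critical value at α = 0.05 (3.84 for one parameter);
backward elimination removes effects whose deletion costs less than the
α = 0.01 value (6.63). Conditional weighted residuals decorrelate the
observations by the first-order covariance G Ω Gᵀ + diag(residual
variance) evaluated at the empirical Bayes estimates.

## Synthetic cohort generator

The generator emulates the four source studies' *designs*: 45 subjects
(10/8/15/12), 5 g q8h under KRT and 4 g q6h (one subject 6 g q8h) without,
infusion durations 0.5–1 h (2 h in the CKRT study), PIKRT sessions of 8 h
(study A, day 2) and 6 h (study B, day 2), continuous CKRT over the first
24 h (study C) so that the published "with and without CKRT" sampling
series both exist, and the printed minute-level sampling schedules per
study. Study A's sampling is anchored at the dialysis-session start; the
dose-to-session offset is not published and defaults to 0 h
(configurable). Observation times are jittered ±2 min (switchable off)
because real sampling is never exact.

Covariates are sampled lognormally, parameterized by each study's
published median and interquartile range via the method of quantiles;
correlations are ignored except that body-mass index is clamped to 15–50
kg/m² by resampling weight. Serum creatinine, age and sex generate eGFR
through the same MDRD code used by the model. Anuric counts per study
(3/0/7/0) follow the published per-category tallies; anuric subjects draw
a 24-h urine output uniformly below 100 mL. Study B carries no height or
laboratory values (left empty for the imputation machinery) and zero true
body clearance. Observations are the model's true concentrations plus
combined residual error, redrawn on the rare negative.

Under the default schedules the cohort yields ~620 observations versus the
727 of the source pool — the real studies collected a variable number of
sampling series per patient (up to six in study D), which we fix at one or
two. What passing tests on these cohorts show is that the estimation
machinery recovers the generating model under realistic designs and noise;
they cannot show robustness to features the generator omits — covariate
correlations, time-varying kidney function (available as an optional
random-walk stress mode), irregular dialysis scheduling, or assay
quantification limits.

## Problem sizes and tolerances

Monte Carlo scenarios use 2,000 subjects (binomial SE ≤ ~1.1 percentage
points); PTA checks against published attainment levels allow 2 percentage
points. Parameter-recovery checks allow twice the published relative
standard error of each parameter — the sampling spread of an estimate from
a single 45-subject cohort. The engine oracle battery demands < 1e−3
relative agreement between the ODE and closed-form paths, and mass balance
closes within 0.5 %.

## Known limitations

* Laplace ≠ FOCE-I: small systematic OFV offsets are expected; model
  *comparisons* (dOFV) are affected far less than absolute values.
* The dialysis model predicts serum concentrations only; dialysate-side or
  post-filter concentrations are out of scope (insufficient information
  for a mechanistic CL_KRT).
* No fecal/non-renal elimination pathway; CL_body aggregates whatever
  elimination remains without KRT.
* ω² values are not published (only derived %CV), so recovery checks on
  variance components are necessarily loose.
* The pcVPC uses its own simulated replicates; with small `n_rep` the
  envelope is noisy (the default is 1,000 replicates).
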