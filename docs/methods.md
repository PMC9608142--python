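# Methods

This note records the modelling assumptions, numerical choices and the
design decisions behind `pmbpk`, in the spirit of a statistical software
methods appendix.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Structural and stochastic model

Concentration–time profiles are closed-form superpositions of
single-infusion solutions (linear kinetics), for one- and two-compartment
disposition with first-order elimination.  For a zero-order infusion of
rate `R0` starting at `t0` with duration `D` and elimination rate
`k = CL/V`, the one-compartment concentration is
`(R0/CL)(1 − e^{−k(t−t0)})` during the infusion and decays
mono-exponentially afterwards; the two-compartment solution is the
standard bi-exponential form in the macro constants α, β.  Using closed
forms rather than an ODE integrator makes a 100,000-subject Monte Carlo
run a vectorised array operation and removes integrator tolerance as a
source of error.  `expm1` is used for the infusion-rise term so the
two-compartment solution degenerates cleanly to the one-compartment one
as the inter-compartmental clearance vanishes.

Between-subject variability is exponential (log-normal parameters):
`P_i = θ_P · Π(cov/ref)^β · exp(η_P)`, covariate factors applied before
the random effect.  Continuous covariates enter as power functions
centred at a study reference (the median); binary covariates as
multiplicative factors `θ^indicator`.  The clearance–renal-function
relation is implemented multiplicatively,
`CL = θ_CL (CrCL/78.49)^θ1`: this is the standard centred power form, and
it is the only reading under which the typical clearance at the median
covariate equals θ_CL, consistent with the reported estimate table.
Residual error is additive, proportional or combined; the residual model
is selected by refitting all three and comparing OFV with a 3.84-point
penalty per extra parameter.

Internal units are fixed (mg, L, h, mg/L).  Serum creatinine is accepted
in µmol/L and converted by 88.4 µmol/L per mg/dl inside the
Cockcroft–Gault function, which includes the 0.85 female factor and
rejects ages ≥ 140 (non-positive numerator).

## Data model

Event records follow the NONMEM convention: one CSV row per dose
(`EVID 1`, `AMT`, `DUR` or `RATE`) or observation (`EVID 0`, `DV`), with
per-subject-constant covariate columns; times are normalised to hours
since each subject's first dose.  Observations below the assay's lower
limit of quantification (0.1 mg/L) must be flagged; they are retained in
the table but excluded from all likelihoods.  No BLQ likelihood method
(M3 etc.) is implemented — the clinical data this design emulates lies
well above the limit, so flag-and-exclude is adequate and simpler.
Inter-occasion variability and off-diagonal ω covariances are out of
scope (the estimate table this package mirrors reports diagonal BSV
only).

## FOCE-I estimation

For each subject the conditional objective
`Σ_j [log v_j(η) + (y_j − f_j(η))²/v_j(η)] + η'Ω⁻¹η` (with
`v = σ_add² + σ_pro² f²` evaluated at the conditional prediction — the
"interaction") is minimised over η by a batched damped Newton iteration:
finite-difference gradient and Hessian in the (at most two-dimensional)
η space, eigenvalue-floored to positive definite, a trust-region cap of
2.0 on the step (η is a unit-scale log deviation), per-subject
backtracking, convergence at 1e-8.  Each search starts from the better of
zero and the subject's previous mode.  All subjects are advanced
simultaneously as numpy array operations, which is what makes the outer
optimisation affordable in pure Python.

The population objective is the linearised marginal −2 log likelihood at
the mode: `OFV_i = log|C_i| + r_i' C_i⁻¹ r_i` with
`C_i = diag(v(f(η̂))) + GΩG'`, `G = ∂f/∂η` at the mode, and
`r_i = y_i − f(η̂) + Gη̂`; the additive `n log 2π` is excluded, so only
OFV differences are comparable across implementations (the tests compare
differences against an adaptive-quadrature evaluation of the exact
marginal likelihood).  With all ω² = 0 this reduces exactly to the
extended-least-squares deviance.

The outer search runs on transformed parameters (log for positive
quantities, identity for power exponents): first L-BFGS-B with a coarse
finite-difference step (1e-4) matched to the inner-loop noise, then
Nelder-Mead polish with restarts, stopping when a restart improves the
OFV by under 0.01 and the simplex spread is below 1e-4.  The quasi-Newton
stage is the workhorse; the restart loop guards against the occasional
simplex collapse far from the optimum.  Default initial estimates are
order-of-magnitude values (θ_CL = 1 L/h, θ_V = 10 L, ω = 0.3,
σ_pro = 0.3, exponents 0) — deliberately away from the packaged final
model so that recovery tests are honest.  Warm-started refits (bootstrap
replicates) skip the polish stage.

Standard errors come from the central finite-difference Hessian of the
OFV in the natural parameters (relative step 1e-3): covariance
`2 H⁻¹`, RSE% = 100·SE/estimate; the condition number is the eigenvalue
ratio of the correlation-scaled Hessian, and a non-positive-definite
Hessian reports SEs as unavailable rather than failing.  ω is reported
externally as `100·√ω²` (%) and σ_pro as a percentage, the conventional
scale for BSV and proportional-error rows.

FOCE-I is an approximation: with a proportional-error SD near 40 % its
conditional mode is deliberately not the residual-zero point even on
noise-free data (the log-variance term rewards smaller predictions), and
sparse 4-point designs leave a few percent of bias in the typical values.
The parameter-recovery tests therefore check tolerances (15 % fixed
effects, 30 % variability terms), not equality, and average over five
independent synthetic studies.

## Covariate search

Candidates are (covariate, parameter) pairs.  The Pearson screen
(threshold |r| ≥ 0.5, configurable; a conventional collinearity cut since
no threshold is standard) removes, within each correlated pair, the
member whose univariate addition to the base model lowers the OFV less.
Forward selection repeatedly adds the candidate with the largest drop
while it exceeds 3.84 (χ², p < 0.05); backward elimination removes, one
at a time, any link whose single removal costs ≤ 6.63 (p < 0.01).
Non-convergent candidate fits are skipped and logged.  Qualitative
retention criteria (precision gain, unexplained-BSV drop) are recorded in
the step log as metrics but never applied automatically — they are
judgment calls, not rules.

## Model evaluation

*Bootstrap.* Subjects are the resampling unit, drawn with replacement to
the original count; each replicate refits the final model initialised at
the final estimates (common pharmacometric practice; it speeds
convergence without changing the optimum).  Failed replicates are
excluded and counted, with a warning above 5 %.  Bias is
`(replicate median − estimate)/estimate × 100`, computed on the reporting
scale (ω %, σ %) because that is the scale on which estimates are
reported and compared.

*pvcVPC.* Observations are binned by time after the last dose into
quantile bins (default 6; bins under 5 observations are merged with a
neighbour).  Each observed and simulated value is location/scale
standardised to its bin's typical subject:
`y* = PRED_bin + (y − PRED_ij) · sd_bin/sd_ij`, where PRED is the
population prediction, `sd_ij` the model-simulated SD of that
observation, and bin values are medians — a Bergstrand-style prediction
and variability correction that reduces to the plain VPC when the design
is homogeneous.  Observed 5th/50th/95th percentiles are compared with
the 2.5–97.5 % band of the same percentile across simulated replicates.

*NPDE.* Each subject's observation vector is simulated `K` times; the
empirical simulation mean and covariance define a Cholesky decorrelation
applied to both observed and simulated vectors; the decorrelated
observation's rank among its decorrelated simulations (ties smoothed
with seeded uniform jitter, probabilities clamped to
`[1/2K, 1 − 1/2K]`) maps through the standard-normal quantile.  The three
reported tests are the one-sample t-test (mean 0), a two-sided χ² test of
unit variance (the variance test named in the NPDE methodology is
implemented as this χ² form, since no formula is standardised), and
Shapiro–Wilk for normality.  A singular simulation covariance is
ridge-regularised with an escalating diagonal.

## Monte Carlo dose optimization

Virtual subjects share a scenario's creatinine clearance and draw
`η_CL, η_V` from the final model's log-normal BSV (sd 0.326 and 0.406).
Fixed-effect (estimation) uncertainty is *not* propagated by default: the
simulation exercise is defined as simulation from the final model, and
mid-grid PTA values are sensitive to exactly which extra variance sources
are included — only variance-convention-robust extreme cells are treated
as reproduction anchors.  Doses are a loading dose at time 0 and
maintenance doses every 12 h as 1-h infusions; "day 3" exposure is the
48–72 h window, integrated by the linear-up/log-down trapezoid on a
10-minute grid (log-trapezoid on strictly descending positive segments,
linear otherwise).  PTA is the fraction of subjects with
`0.42·AUC/MIC ≥ 20`, reported to 3 decimals; at the default 100,000
subjects the Monte Carlo SE is ≤ 0.0016.  Per-subject steady-state daily
exposure uses the closed form `daily dose / CL_i` directly — the
simulator knows each subject's true parameters, so re-estimating them
Bayesianly would only add noise; this is a deliberate simplification.

One set of random-effect draws is shared across every cell of a grid
(common random numbers), so PTA is exactly monotone in dose, MIC and
renal function rather than merely monotone up to Monte Carlo error, and
the AUC distribution for each (CrCL, regimen) pair is reused across
MICs.

## Synthetic studies

The generator emulates the emulated trial's design: covariates from
truncated normals (CrCL 80.81 ± 29.97 ml/min on [20, 160]; weight
52.15 ± 10.00 kg on [35, 80]; age 56 ± 12.76 y on [18, 85]; albumin
33.15 ± 5.16 g/L; 25/34 male), truncation bounds being a plausibility
choice since only means and SDs are reported.  Serum creatinine is
derived by inverting Cockcroft–Gault from the sampled CrCL, age, weight
and sex, which reproduces the strong SCr–CrCL anticollinearity the
covariate screen must handle.  Dosing draws uniformly from the guideline
bands (loading 2.0–2.5 mg/kg, maintenance 1.25–1.5 mg/kg q12h, 1-h
infusions), rounded to 5 mg.  The four samples per subject bracket the
first maintenance dose at or after 48 h: 0.5 h before the infusion and
1, 2, 6 h after its end (47.5, 50, 51, 55 h).  Exactly four samples per
subject are generated.  Observations below 0.1 mg/L are flagged as
below-LOQ.  The same seed reproduces a table bit for bit.

What the generator does *not* emulate: occasional extra samples per
patient, assay error structure beyond the fitted residual model,
extracorporeal support subpopulations (none were modelled), inhalation
co-therapy (not a covariate in the final model), or time-varying renal
function.  Passing recovery tests therefore demonstrate internal
consistency of estimator and simulator under the stated design, not
robustness to those real-data features.

## Problem sizes used in the test suite

Chosen as the package's own scaled study sizes: parameter recovery uses
five 200-subject studies (seeds 101…505); the bootstrap check runs 100
replicates of a 200-subject fit; the PTA table checks run the two extreme
cells at 100,000 subjects and the full 9 × 3 × 4 grid at 20,000; NPDE
calibration uses 100 34-subject studies with 500 simulations each; VPC
self-consistency pools three 34-subject runs.  The pipeline integration
test runs a deliberately tiny configuration (12 subjects, 3 bootstrap
replicates) to exercise plumbing, not estimation quality.

## Known limitations

* FOCE-I only; no SAEM or importance sampling, no Laplacian-with-η²
  refinement, and small-sample bias in sparse designs is inherited.
* Diagonal Ω; no inter-occasion variability; no BLQ likelihood.
* The two-compartment model is available for base-model comparison but
  the dose simulator is one-compartment (matching the final model).
* Verbal risk-cutoff statements about nephrotoxicity thresholds across
  renal-function bands are qualitative narrative over the safety grid
  and are intentionally not encoded as logic.
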