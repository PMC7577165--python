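# Methods

## Structural model and parameterization

Disposition is a one-compartment model with first-order absorption and
linear elimination, parameterized as apparent oral clearance CL/F (L/h),
apparent volume V/F (L) and absorption rate ka (1/h); bioavailability F is
not separately identifiable from oral data alone and is absorbed into CL/F
and V/F throughout. Doses are stored in nmol (100 mg of doravirine,
molecular weight 425.75 g/mol, is 234,880 nmol) and concentrations in nM,
so AUC over a dosing interval emerges in nM·h and is reported in μM·h.

All concentration computations reduce to geometric partial sums of the
single-dose exponentials, written as `e^(−k·u)·(1−r^n)/(1−r)` with
`r = e^(−k·τ) ≤ 1` so that arbitrarily long dosing histories cannot
overflow. Steady state is the n → ∞ limit of the same expression. The
removable singularity at ka = ke uses the exact limit formulas (both the
concentration and tmax), triggered when |ka − ke| < 10⁻⁸·ke; continuity at
the switch is covered by tests. Dose amounts and times of prior doses are
reconstructed from the dataset's EVID=1 rows in file order, which encodes
the predose-versus-postdose distinction for same-time rows.

Covariate submodel (all coefficients configuration-visible, reference
weight 70 kg, reference age 45 years):

    CL/F = TVCL · (age/45)^beta_age_cl
    V/F  = TVV  · (weight/70)^beta_wt_v · beta_hiv_v^[status = HIV]
    ka   = TVKA

Weight and infection status deliberately do not touch CL/F, and age does
not touch V/F. Between-subject variability is log-normal,
parameter_i = typical_i · e^η, η ~ N(0, diag(ω²_CL, ω²_V, ω²_ka)); Ω is
diagonal (no correlations). The residual model is proportional with an
optional additive floor: var = (σ_prop·f)² + σ_add², evaluated at the
individual prediction.

## Likelihood and estimation

The marginal likelihood integrates each subject's η out with a Laplace
approximation at the conditional mode: with g_i(η) the negative log joint
density of subject i's data and η,

    −2 log L_i ≈ 2·g_i(η*_i) + log det H_i − d·log 2π ,

η*_i the minimizer and H_i the Hessian of g_i there. The inner minimization
runs for all subjects simultaneously: damped Newton with an eigenvalue-
clamped Hessian, a trust-region cap of 3 on the η-step norm (BSV standard
deviations are O(0.1–0.5), so a step of 3 is already far outside the
plausible region), and a backtracking line search that accepts steps to
within a 10⁻¹⁰ relative slack so floating-point rounding near the mode
cannot stall quadratic convergence; NaN objective values count as
rejections. Gradients of g use complex-step differentiation (exact to
machine precision for this closed-form model); Hessians are central
differences of that gradient with step 10⁻⁴. Subjects without usable
observations sit at the prior mode and contribute exactly zero to −2 log L.
A 9-node-per-dimension adaptive Gauss–Hermite quadrature implemented
independently in the test suite agrees with the Laplace objective to well
under 1% on small instances.

The outer problem minimizes −2 log L over (log TVCL, log TVV, log TVKA,
beta_wt_v, log beta_hiv_v, beta_age_cl, log ω², log σ) — positives on the
log scale, exponents unconstrained — with L-BFGS-B (finite-difference
gradients, step 10⁻⁵) followed by a short Nelder–Mead polish (at most
min(300, 40·p) iterations) that cleans up the stall finite-difference noise
can cause near the optimum. Per-subject modes are warm-started between
objective calls, making an evaluation a few milliseconds for hundreds of
subjects. Parameters fixed by the caller, any ω² starting at zero, σ_add
starting at zero, and — when the dataset contains a single infection
status — the structurally unidentifiable beta_hiv_v are all held at their
initial values automatically.

Standard errors are delta-method transforms of the inverse central
finite-difference Hessian (step 10⁻³) of −log L at the optimum. When a
variance component is estimated at or near its boundary the Hessian can
fail positive definiteness; SEs are then reported as unavailable together
with the condition number rather than silently regularized.

Empirical-Bayes (post hoc) parameters are the per-subject MAP η under the
final model, typical values times e^η. η-shrinkage is reported as
(1 − SD(η_k)/ω_k)·100; it is a property of design informativeness, and the
sparse trial schedule yields low shrinkage for η_CL (troughs pin clearance)
but substantial shrinkage for η_ka (few absorption-phase samples), which in
turn biases post hoc exposure dispersion slightly downward — visible as
geometric %CVs of EBE-derived metrics a few points below the generative
totals.

## Synthetic trial generator

The generator emulates the immediate-switch arm of a switch study: 443
HIV-1-positive subjects by default, once-daily 100 mg, and the sparse
schedule day-1 predose (no drug on board, recorded DV=0/MDV=1), week-4
trough, week-12 sample at a uniform time within the dosing interval, and
weeks 24/48 trough plus a Uniform(0.5, 2) h post-dose sample. Troughs are
simulated at exactly τ after the previous dose. Covariates are log-normal
weight (median 70 kg, CV 15%) and truncated-normal age (45 ± 11 years,
18–78) — generic adult values, not any trial's empirical distribution. An
optional healthy cohort (off by default) exercises the status covariate;
the mixed-cohort mode is what makes beta_hiv_v identifiable in recovery
tests.

The default truth is this package's own calibration, chosen once so that
simulated steady-state exposures match published summary exposures for
doravirine 100 mg once daily: TVCL 5.66 L/h, TVV 130.4 L with a 1.15 HIV
factor (≈150 L for the simulated population), TVKA 1 h⁻¹, weight exponent
0.5 on V/F, age exponent −0.2 on CL/F, ω = (0.22, 0.12, 0.40), σ_prop
0.20. The variance split is deliberate: covariate contributions plus BSV
reproduce total geometric CVs of ≈23% (AUC), ≈36% (C₂₄) and ≈16.5% (Cmax).
These are not estimates from any clinical dataset.

The week-48 endpoint truth is a logistic exposure-efficacy model on a
chosen metric (C₂₄ by default) with baseline responder probability 0.90
and slope 0 — a flat exposure–response. Responders receive an RNA value
below threshold, non-responders a log-uniform value above it. A
configurable 8% of subjects have a missing week-48 value, split 40/60
between lack-of-efficacy and other discontinuations, applied independently
of responder status (the generator does not model the correlation between
dropout and failure that real trials show — passing recovery tests
therefore says nothing about informative missingness). Other real-data
features intentionally not emulated: below-quantitation censoring,
enzyme-induction washout after an efavirenz switch, adherence variation,
and dropout over time.

## Exposure–response analysis

Snapshot classification: response = 1 iff a measured week-48 RNA is below
threshold; any missing value is failure; nobody is excluded.
Observed-failure classification: measured values are compared with the
threshold; missing after an efficacy-related discontinuation is failure;
missing for other reasons is excluded; missing with no discontinuation
reason (intermittent missingness, for which the rule is silent) is excluded
with a warning.

The "linear exposure-effect model" is taken as a logistic model linear in
exposure on the logit scale, its comparator linear in log exposure — the
standard binary E–R pair; exposures enter in their natural units. Slope
inference is Wald (CI = β ± 1.96·SE, two-sided p), with a likelihood-ratio
p available as an option; AIC = 4 − 2 log L compares the two forms and ties
select the linear form. Complete separation (e.g. all responders) is
detected and flagged; no Wald inference is reported then. Quartile
boundaries use linear-interpolation percentiles with ties assigned to the
lower bin; observed proportions carry exact Clopper–Pearson 95% intervals.
The prediction band is the delta-method 95% CI of the linear predictor
pushed through the inverse logit, so it always contains the point curve and
stays in [0, 1]; a parametric-bootstrap check in the tests agrees with the
delta half-width to within 10% at the exposure mean.

## Problem sizes used in the test suite

Simulation studies are sized for a single CPU while keeping their
statistical conclusions meaningful, as the package's own choices: parameter
recovery uses one 300-subject rich-sampling cohort (8 samples per subject,
mixed healthy/HIV) for the 10%/40% fixed-effect/variance checks and one
150-subject sparse-schedule cohort for the typical-clearance check; the
replicate study of typical-clearance error and Wald coverage runs 12 seeded
replicates of a 60-subject rich design with interior variance components
(ω = 0.30/0.25/0.40) so the covariance step stays well-conditioned at that
sample size; the type-I-error study of the E–R slope test runs 500 seeded
replicates at the full trial size (n = 443) through the generator's fast
truth-only path.

## Known limitations

Diagonal Ω only; no SAEM or importance-sampling estimation; no covariate
selection (the covariate structure is fixed); no BLQ handling (records
flagged MDV=1 are excluded from fitting); the equal-dose, equal-interval
regimen is assumed when reconstructing dosing history; exposure–response
offers only the linear/log logistic pair (a linear-probability variant
exists behind a flag but is not part of the default sweep); Wald inference
is first-order and the variance-component SEs inherit the usual boundary
pathologies.
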