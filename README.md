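# dorpk

Population pharmacokinetics and exposure–response analysis of once-daily
oral doravirine (100 mg), built as a tested, reusable pipeline around a
synthetic immediate-switch trial generator.

Doravirine is a non-nucleoside reverse transcriptase inhibitor used in
switch regimens for virologically suppressed people living with HIV-1. The
clinical question this analysis addresses is whether steady-state drug
exposure in a switch population is consistent with the treatment-naive
population, and whether week-48 virologic response depends on exposure over
the range achieved by the 100-mg dose. The clinical datasets behind that
question are access-restricted, so this package pairs the full analysis
machinery with a seeded generator of trial-like data carrying its own
generative truth — every estimation step can be checked by parameter
recovery.

## The model

**Structural PK.** One-compartment disposition with first-order absorption,
apparent clearance CL/F and volume V/F (ke = CL/V). At steady state under a
dose D every τ hours,

    C_ss(t) = D·ka / (V·(ka − ke)) · [ e^(−ke·t)/(1 − e^(−ke·τ))
                                      − e^(−ka·t)/(1 − e^(−ka·τ)) ]

with the exact L'Hôpital limit at ka = ke. Before steady state the finite
superposition over administered doses is used. Exposure metrics follow in
closed form: AUC₀₋₂₄ = D/CL, tmax = ln[ka(1−e^(−ke·τ))/(ke(1−e^(−ka·τ)))]/(ka−ke),
Cmax = C_ss(tmax), C₂₄ = C_ss(τ).

**Covariates and variability.** Weight (power) and HIV-1 infection status
(multiplicative factor) act on V/F; age (power) acts on CL/F. Each subject's
parameters are the covariate-typical values times e^η with
η ~ N(0, diag(ω²)); the residual error is proportional (plus optional
additive).

**Estimation.** The marginal likelihood integrates η out per subject by a
Laplace approximation at the conditional mode (a batched damped-Newton inner
loop with complex-step derivatives); −2 log L is minimized over
(log θ, covariate coefficients, log ω², log σ) by quasi-Newton with a short
simplex polish. Standard errors come from the inverse finite-difference
Hessian; individual (post hoc) parameters are the per-subject MAP η given
the final model.

**Exposure–response.** Week-48 binary endpoints (<50 or <40 copies/ml)
under the regulatory snapshot rule (missing ⇒ failure) or the
observed-failure rule (efficacy-related monotone missingness ⇒ failure,
other missingness excluded), then maximum-likelihood logistic models
logit P(response) = α + β·g(exposure) with g = identity or log, compared by
AIC, with Wald slope inference, exposure-quartile summaries with exact
Clopper–Pearson intervals, and a delta-method 95% prediction band.

## Worked example

The numbered scripts under `analysis/` run the study end to end on the
default synthetic trial (443 subjects, sparse sampling, flat
exposure–response truth):

```sh
python analysis/01_simulate_trial.py      # dataset under results/trial/
python analysis/02_fit_population.py      # population fit
python analysis/03_posthoc_exposures.py   # post hoc parameters + exposures
python analysis/04_exposure_response.py   # endpoints + logistic E-R sweep
```

With the default seed (20240) the fit prints

```
fit on 443 subjects / 2658 observations (-2LL = 39018.3, converged=True)
  tvcl        = 5.636 (SE 0.07301)
  tvv         = 144.1 (SE 4.457)
  tvka        = 0.9863 (SE 0.05798)
```

— the typical CL/F of 5.64 L/h (truth 5.66) is recovered to ~0.4% from
sparse data. The post hoc exposure summaries,

```
  auc24  geometric mean    41.14 uM*h  geometric CV 20.9%
  cmax   geometric mean     2398 nM    geometric CV 14.3%
  c24    geometric mean     1041 nM    geometric CV 35.0%
```

are steady-state exposures of the magnitude reported for doravirine 100 mg
once daily (geometric %CVs sit slightly below the generative totals because
MAP estimates shrink toward typical values under sparse sampling). The
exposure–response sweep ends with

```
slope p-values below 0.05: 0 of 24
headline (C24, snapshot, <50): slope 0.000496 [-0.000233, 0.00123], p = 0.182 -> flat exposure-response
```

no slope reaches significance in any metric × endpoint × threshold
combination, i.e. the analysis correctly finds the flat exposure–response
relationship built into the generator.

The same pipeline is scriptable in one call (`dorpk report`, or
`dorpk --config configs/default.yaml --seed 7 report`), and the individual
stages are exposed as `dorpk simulate | fit | posthoc | exposures | er`.

## Dataset dialect

PK datasets are long-format CSVs (`ID,TIME,AMT,TAD,DV,EVID,MDV,WT,AGE,STAT,GRP`)
with EVID/MDV codes as used by NONMEM-style tools: doses in nmol, plasma
concentrations in nM, times in hours since first dose; an observation row
written before a same-time dose row is a predose sample. See
`dorpk.trial_data` for the full contract and `configs/default.yaml` for all
tunable constants.
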