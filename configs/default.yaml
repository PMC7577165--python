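# Shared configuration for the doravirine switch-trial analysis.
# `analysis:` holds run-wide constants; `simulation:` the generative truth
# of the synthetic trial.  All values shown are the package defaults.

analysis:
  regimen:
    dose_mg: 100.0        # once-daily oral dose
    tau: 24.0             # dosing interval, h
    molecular_weight: 425.75   # g/mol -> 100 mg = 234,880 nmol
  weight_ref: 70.0        # kg, covariate reference
  age_ref: 45.0           # years, covariate reference
  thresholds: [50, 40]    # HIV-1 RNA endpoint cutoffs, copies/ml
  seed: 20240

simulation:
  n_subjects: 443         # immediate-switch-arm size
  seed: 20240
  schedule: sparse        # day-1 predose; wk4 trough; wk12 any time;
                          # wk24 + wk48 trough and 0.5-2 h postdose
  weight_median: 70.0     # kg, log-normal
  weight_cv: 0.15
  age_mean: 45.0          # years, normal truncated to bounds
  age_sd: 11.0
  age_bounds: [18.0, 78.0]
  p_response: 0.90        # baseline week-48 responder probability
  er_slope: 0.0           # flat exposure-response truth
  missing_frac: 0.08      # missing week-48 outcome
  missing_loe_frac: 0.40  # share of missingness from lack of efficacy
  true_model:
    theta:
      tvcl: 5.66          # L/h   typical CL/F
      tvv: 130.4          # L     typical V/F (healthy reference; x1.15 HIV)
      tvka: 1.0           # 1/h   typical ka
      beta_wt_v: 0.5      # power of (weight/70) on V/F
      beta_hiv_v: 1.15    # multiplicative HIV factor on V/F
      beta_age_cl: -0.2   # power of (age/45) on CL/F
    omega2: [0.0484, 0.0144, 0.16]   # BSV variances (CL, V, ka); SDs 0.22/0.12/0.40
    sigma_prop: 0.20      # proportional residual SD
    sigma_add: 0.0        # additive residual SD, nM
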