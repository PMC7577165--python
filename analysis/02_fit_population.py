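"""Fit the population PK model to the simulated trial dataset.

One-compartment oral model with log-normal between-subject variability on
CL/F, V/F and ka, proportional residual error, and power/indicator
covariates (weight and infection status on V/F, age on CL/F).  Estimation
maximizes the Laplace-approximated marginal likelihood from generic
starting values; the infection-status factor is fixed automatically because
the immediate-switch arm contains a single status level.  Writes fit.json
(estimates, SEs, objective) and the residual table under results/fit/.

Run:  python analysis/02_fit_population.py   (after 01_simulate_trial.py)
"""

import argparse
import json
from pathlib import Path

from dorpk import nlme
from dorpk.pipeline import default_init_model
from dorpk.trial_data import AnalysisConfig, read_pk_dataset

ap = argparse.ArgumentParser()
ap.add_argument("--dataset", type=Path, default=Path("results/trial/dataset.csv"))
ap.add_argument("--outdir", type=Path, default=Path("results/fit"))
args = ap.parse_args()

ana = AnalysisConfig()
records, subjects = read_pk_dataset(args.dataset, ana)
fit = nlme.fit_population(default_init_model(), records, subjects, ana)
fit.se = nlme.standard_errors(fit, records, subjects, ana)

args.outdir.mkdir(parents=True, exist_ok=True)
(args.outdir / "fit.json").write_text(
    json.dumps(
        {
            "estimates": nlme.model_to_dict(fit.model),
            "se": fit.se,
            "neg2ll": fit.neg2ll,
            "converged": fit.converged,
            "n_subjects": fit.n_subjects,
            "n_obs": fit.n_obs,
            "message": fit.message,
        },
        indent=2,
    )
)
nlme.residual_table(fit.model, records, subjects, ana).to_csv(
    args.outdir / "residuals.csv", index=False
)

print(f"fit on {fit.n_subjects} subjects / {fit.n_obs} observations "
      f"(-2LL = {fit.neg2ll:.1f}, converged={fit.converged})")
est = nlme.model_to_dict(fit.model)
for name in ("tvcl", "tvv", "tvka", "omega2_cl", "omega2_v", "omega2_ka", "sigma_prop"):
    se = (fit.se or {}).get(name)
    se_s = f" (SE {se:.4g})" if se is not None else ""
    print(f"  {name:11s} = {est[name]:.4g}{se_s}")
print(f"wrote fit.json and residuals.csv under {args.outdir}/")
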