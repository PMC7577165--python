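"""Empirical-Bayes individual parameters and steady-state exposure metrics.

Takes the fitted population model, computes each subject's MAP (post hoc)
CL/F, V/F and ka given their sparse concentrations, derives steady-state
AUC0-24 (uM*h), Cmax and C24 (nM) and tmax, and summarizes them as
geometric mean, geometric %CV and 5th/25th/50th/75th/95th percentiles.
Writes ebe.csv, exposures.csv and exposure_summary.csv under
results/exposures/.

Run:  python analysis/03_posthoc_exposures.py   (after 02_fit_population.py)
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from dorpk import nlme, reporting
from dorpk.structural import exposure_table
from dorpk.trial_data import AnalysisConfig, read_pk_dataset

ap = argparse.ArgumentParser()
ap.add_argument("--dataset", type=Path, default=Path("results/trial/dataset.csv"))
ap.add_argument("--fit", type=Path, default=Path("results/fit/fit.json"))
ap.add_argument("--outdir", type=Path, default=Path("results/exposures"))
args = ap.parse_args()

ana = AnalysisConfig()
records, subjects = read_pk_dataset(args.dataset, ana)
model = nlme.model_from_dict(json.loads(args.fit.read_text())["estimates"])

ebes = nlme.empirical_bayes(model, records, subjects, ana)
expo = exposure_table(ebes.subject_ids, ebes.cl, ebes.v, ebes.ka, ana.regimen)

args.outdir.mkdir(parents=True, exist_ok=True)
pd.DataFrame(
    {
        "subject_id": ebes.subject_ids,
        "eta_cl": ebes.eta[:, 0], "eta_v": ebes.eta[:, 1], "eta_ka": ebes.eta[:, 2],
        "cl": ebes.cl, "v": ebes.v, "ka": ebes.ka,
    }
).to_csv(args.outdir / "ebe.csv", index=False)
expo.to_csv(args.outdir / "exposures.csv", index=False)

rows = []
print(f"post hoc parameters for {len(ebes.subject_ids)} subjects")
print("  eta shrinkage:", {k: None if v is None else round(v, 1) for k, v in ebes.shrinkage.items()})
for metric, unit in (("auc24", "uM*h"), ("cmax", "nM"), ("c24", "nM")):
    s = reporting.exposure_summary(expo[metric], metric)
    rows.append(
        {"metric": metric, "n": s.n, "geometric_mean": s.geometric_mean,
         "geometric_cv_pct": s.geometric_cv_pct,
         **{f"p{int(k)}": v for k, v in s.percentiles.items()}}
    )
    print(f"  {metric:6s} geometric mean {s.geometric_mean:8.4g} {unit:5s} "
          f"geometric CV {s.geometric_cv_pct:.1f}%")
pd.DataFrame(rows).to_csv(args.outdir / "exposure_summary.csv", index=False)
print(f"wrote ebe.csv, exposures.csv, exposure_summary.csv under {args.outdir}/")
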