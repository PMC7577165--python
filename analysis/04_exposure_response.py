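"""Week-48 exposure-response analysis across endpoints and metrics.

Builds the binary week-48 endpoints under the snapshot and observed-failure
rules at the <50 and <40 copies/ml thresholds, fits the logistic
exposure-effect model (linear and log exposure) for AUC0-24, Cmax and C24,
compares forms by AIC, and exports the quartile summary and delta-method
prediction band for the headline C24/snapshot/<50 analysis.  Everything
lands under results/er/.

Run:  python analysis/04_exposure_response.py   (after 03_posthoc_exposures.py)
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from dorpk import exposure_response as er
from dorpk.trial_data import AnalysisConfig, read_efficacy

ap = argparse.ArgumentParser()
ap.add_argument("--exposures", type=Path, default=Path("results/exposures/exposures.csv"))
ap.add_argument("--efficacy", type=Path, default=Path("results/trial/efficacy.csv"))
ap.add_argument("--outdir", type=Path, default=Path("results/er"))
args = ap.parse_args()

ana = AnalysisConfig()
expo = pd.read_csv(args.exposures)
efficacy = read_efficacy(args.efficacy)

rows = []
fits = {}
for thr in ana.thresholds:
    for approach, classify in (
        ("snapshot", er.classify_snapshot),
        ("observed_failure", er.classify_observed_failure),
    ):
        endpoints = [classify(r, thr) for r in efficacy]
        for metric in ("auc24", "cmax", "c24"):
            emap = dict(zip(expo["subject_id"], expo[metric]))
            for form in ("linear", "log"):
                f = er.fit_er_model(endpoints, emap, metric=metric, form=form)
                fits[(thr, approach, metric, form)] = f
                rows.append(
                    {"threshold": thr, "approach": approach, "metric": metric,
                     "form": form, "n": f.n, "slope": f.slope,
                     "ci_low": f.slope_ci95[0], "ci_high": f.slope_ci95[1],
                     "p": f.slope_p, "aic": f.aic}
                )
            sel = er.compare_models_aic(
                fits[(thr, approach, metric, "linear")], fits[(thr, approach, metric, "log")]
            )
            rows[-1]["selected"] = rows[-2]["selected"] = sel["selected"]

tab = pd.DataFrame(rows)
args.outdir.mkdir(parents=True, exist_ok=True)
tab.to_csv(args.outdir / "er_fits.csv", index=False)

thr0 = ana.thresholds[0]
endpoints = [er.classify_snapshot(r, thr0) for r in efficacy]
emap = dict(zip(expo["subject_id"], expo["c24"]))
head = fits[(thr0, "snapshot", "c24", "linear")]
quart = er.quartile_summary(endpoints, emap, metric="c24")
quart.table.to_csv(args.outdir / "quartiles_c24_snapshot.csv", index=False)
x = expo["c24"].to_numpy()
band = er.prediction_band(
    head, np.linspace(*np.percentile(x, [5, 95]), 100), data_range=(x.min(), x.max())
)
band.to_csv(args.outdir / "band_c24_snapshot.csv", index=False)

print(tab[["threshold", "approach", "metric", "form", "slope", "p", "selected"]]
      .to_string(index=False, float_format=lambda v: f"{v:.3g}"))
n_sig = int((tab["p"] < 0.05).sum())
print(f"\nslope p-values below 0.05: {n_sig} of {len(tab)}")
print(f"headline (C24, snapshot, <{thr0}): slope {head.slope:.3g} "
      f"[{head.slope_ci95[0]:.3g}, {head.slope_ci95[1]:.3g}], p = {head.slope_p:.3f}"
      + (" -> flat exposure-response" if head.slope_p > 0.05 else ""))
print("observed responder proportion by C24 quartile:")
print(quart.table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(f"wrote er_fits.csv, quartiles and prediction band under {args.outdir}/")
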