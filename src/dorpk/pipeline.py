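"""End-to-end analysis pipeline: simulate -> fit -> post hoc -> exposures ->
endpoint classification -> exposure-response.

Every stage is a library call from the sibling modules; this module owns the
orchestration, the on-disk artifact layout and a structured run log (one
JSON line per stage with input/output hashes) so a run can be audited and
reproduced from its seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import exposure_response as er
from . import nlme, reporting, synthetic
from .structural import ThetaVector, exposure_table
from .trial_data import (
    AnalysisConfig,
    DosingRegimen,
    read_efficacy,
    read_pk_dataset,
    validate_dataset,
    write_efficacy,
    write_pk_dataset,
)

__all__ = ["load_config", "default_init_model", "run_pipeline", "PipelineError"]

ER_METRICS = ("auc24", "cmax", "c24")
ER_APPROACHES = ("snapshot", "observed_failure")
ER_FORMS = ("linear", "log")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def load_config(path: str) -> tuple[synthetic.SimulationConfig, AnalysisConfig]:
    """Read the shared YAML config (sections `analysis:` and `simulation:`)."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    raw = yaml.safe_load(p.read_text()) or {}
    ana_raw = dict(raw.get("analysis", {}))
    regimen = DosingRegimen(**ana_raw.pop("regimen", {}))
    if "thresholds" in ana_raw:
        ana_raw["thresholds"] = tuple(ana_raw["thresholds"])
    analysis = AnalysisConfig(regimen=regimen, **ana_raw)

    sim_raw = dict(raw.get("simulation", {}))
    tm_raw = sim_raw.pop("true_model", None)
    if tm_raw is not None:
        theta = ThetaVector(**tm_raw.get("theta", {}))
        true_model = nlme.PopulationModel(
            theta=theta,
            omega2=tuple(tm_raw.get("omega2", (0.0484, 0.0144, 0.16))),
            sigma_prop=tm_raw.get("sigma_prop", 0.2),
            sigma_add=tm_raw.get("sigma_add", 0.0),
        )
        sim_raw["true_model"] = true_model
    for tup in ("age_bounds", "postdose_window", "rich_tads"):
        if tup in sim_raw:
            sim_raw[tup] = tuple(sim_raw[tup])
    sim = synthetic.SimulationConfig(regimen=regimen, **sim_raw)
    return sim, analysis


def default_init_model() -> nlme.PopulationModel:
    """Generic starting values for estimation (deliberately off the
    generator's truth): mid-range typicals, null covariate effects,
    moderate variability."""
    return nlme.PopulationModel(
        theta=ThetaVector(tvcl=4.0, tvv=100.0, tvka=1.5),
        omega2=(0.1, 0.1, 0.1),
        sigma_prop=0.3,
        sigma_add=0.0,
    )


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class _Log:
    def __init__(self, path: Path):
        self.path = path
        path.write_text("")

    def stage(self, name: str, **info):
        rec = {"stage": name, "time": round(time.time(), 3), **info}
        with open(self.path, "a") as fh:
            fh.write(json.dumps(rec) + "\n")


def run_pipeline(
    config_path: str | None = None,
    outdir: str = "results/pipeline",
    seed: int | None = None,
    sim_config: synthetic.SimulationConfig | None = None,
    analysis: AnalysisConfig | None = None,
    dataset_path: str | None = None,
    efficacy_path: str | None = None,
    compute_se: bool = True,
    fit_max_iter: int = 400,
) -> dict:
    """Run the full analysis and write its artifact bundle under `outdir`.

    Either simulate a trial (default) or analyze existing dataset/efficacy
    CSVs.  `seed` overrides the config seed for every random draw.  Returns
    a dict of the key results (fit, exposures, ER sweep); raises
    PipelineError naming the failing stage, leaving partial artifacts.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log = _Log(out / "run_log.jsonl")

    if config_path is not None:
        sim_config, analysis = load_config(config_path)
    sim_config = sim_config or synthetic.SimulationConfig()
    analysis = analysis or AnalysisConfig(regimen=sim_config.regimen)
    if seed is not None:
        sim_config = replace(sim_config, seed=int(seed))
    log.stage("config", seed=sim_config.seed, n_subjects=sim_config.n_subjects)

    bundle: dict = {"seed": sim_config.seed, "outdir": str(out)}

    # -- data -------------------------------------------------------------
    try:
        if dataset_path is None:
            records, subjects, efficacy, truth = synthetic.simulate_trial(sim_config, analysis)
            write_pk_dataset(records, subjects, out / "dataset.csv")
            write_efficacy(efficacy, out / "efficacy.csv")
            truth_tab = truth.exposures.assign(p_response=truth.p_response, responder=truth.responder)
            truth_tab.to_csv(out / "truth.csv", index=False)
            bundle["truth"] = truth
        else:
            if not Path(dataset_path).exists():
                raise FileNotFoundError(f"dataset file not found: {dataset_path}")
            records, subjects = read_pk_dataset(dataset_path, analysis)
            efficacy = read_efficacy(efficacy_path) if efficacy_path else []
        report = validate_dataset(records, subjects)
        if not report.ok:
            raise ValueError(f"dataset invalid: {report.violations[:3]}")
    except Exception as e:  # noqa: BLE001
        raise PipelineError("data", str(e)) from e
    ds_hash = _sha(out / "dataset.csv") if (out / "dataset.csv").exists() else None
    log.stage("data", n_records=len(records), n_subjects=len(subjects), dataset_hash=ds_hash)

    # -- population fit ----------------------------------------------------
    try:
        fit = nlme.fit_population(
            default_init_model(), records, subjects, analysis, max_iter=fit_max_iter
        )
        if compute_se:
            fit.se = nlme.standard_errors(fit, records, subjects, analysis)
        fit_json = {
            "estimates": nlme.model_to_dict(fit.model),
            "se": fit.se,
            "neg2ll": fit.neg2ll,
            "converged": fit.converged,
            "n_subjects": fit.n_subjects,
            "n_obs": fit.n_obs,
            "message": fit.message,
            "seed": sim_config.seed,
            "dataset_hash": ds_hash,
        }
        (out / "fit.json").write_text(json.dumps(fit_json, indent=2))
        bundle["fit"] = fit
    except Exception as e:  # noqa: BLE001
        raise PipelineError("fit", str(e)) from e
    log.stage("fit", neg2ll=fit.neg2ll, converged=fit.converged)

    # -- post hoc + exposures ---------------------------------------------
    try:
        ebes = nlme.empirical_bayes(fit.model, records, subjects, analysis)
        nlme.residual_table(fit.model, records, subjects, analysis, ebes).to_csv(
            out / "residuals.csv", index=False
        )
        expo = exposure_table(ebes.subject_ids, ebes.cl, ebes.v, ebes.ka, analysis.regimen)
        expo.to_csv(out / "exposures.csv", index=False)
        summaries = {
            m: reporting.exposure_summary(expo[m], m) for m in ER_METRICS
        }
        pd.DataFrame(
            [
                {
                    "metric": s.metric,
                    "n": s.n,
                    "geometric_mean": s.geometric_mean,
                    "geometric_cv_pct": s.geometric_cv_pct,
                    **{f"p{int(k)}": v for k, v in s.percentiles.items()},
                }
                for s in summaries.values()
            ]
        ).to_csv(out / "exposure_summary.csv", index=False)
        bundle["ebes"] = ebes
        bundle["exposures"] = expo
        bundle["summaries"] = summaries
    except Exception as e:  # noqa: BLE001
        raise PipelineError("exposures", str(e)) from e
    log.stage("exposures", shrinkage=ebes.shrinkage)

    # -- exposure-response sweep ------------------------------------------
    try:
        expo_map = dict(zip(expo["subject_id"], expo["c24"]))
        er_rows = []
        er_fits: dict[tuple, er.ERFit] = {}
        endpoint_rows = []
        for thr in analysis.thresholds:
            for approach in ER_APPROACHES:
                classify = (
                    er.classify_snapshot if approach == "snapshot" else er.classify_observed_failure
                )
                endpoints = [classify(r, thr) for r in efficacy]
                endpoint_rows += [
                    {
                        "subject_id": e.subject_id,
                        "approach": e.approach,
                        "threshold": e.threshold,
                        "response": "" if e.excluded else e.response,
                    }
                    for e in endpoints
                ]
                for metric in ER_METRICS:
                    emap = dict(zip(expo["subject_id"], expo[metric]))
                    for form in ER_FORMS:
                        fit_er = er.fit_er_model(endpoints, emap, metric=metric, form=form)
                        er_fits[(thr, approach, metric, form)] = fit_er
                        er_rows.append(
                            {
                                "threshold": thr,
                                "approach": approach,
                                "metric": metric,
                                "form": form,
                                "n": fit_er.n,
                                "intercept": fit_er.intercept,
                                "slope": fit_er.slope,
                                "slope_ci_low": fit_er.slope_ci95[0],
                                "slope_ci_high": fit_er.slope_ci95[1],
                                "slope_p": fit_er.slope_p,
                                "aic": fit_er.aic,
                                "converged": fit_er.converged,
                            }
                        )
                    cmp_rec = er.compare_models_aic(
                        er_fits[(thr, approach, metric, "linear")],
                        er_fits[(thr, approach, metric, "log")],
                    )
                    er_rows[-2]["selected_form"] = cmp_rec["selected"]
                    er_rows[-1]["selected_form"] = cmp_rec["selected"]
        er_table = pd.DataFrame(er_rows)
        er_table.to_csv(out / "er_fits.csv", index=False)
        pd.DataFrame(endpoint_rows).to_csv(out / "endpoints.csv", index=False)
        bundle["er_table"] = er_table
        bundle["er_fits"] = er_fits

        # headline analysis: C24, snapshot, <50, linear form (plot data)
        thr0 = analysis.thresholds[0]
        endpoints = [er.classify_snapshot(r, thr0) for r in efficacy]
        headline = er_fits[(thr0, "snapshot", "c24", "linear")]
        quart = er.quartile_summary(endpoints, expo_map, metric="c24")
        quart.table.to_csv(out / "quartiles_c24_snapshot.csv", index=False)
        x = expo["c24"].to_numpy()
        lo, hi = np.percentile(x, [5, 95])
        band = er.prediction_band(headline, np.linspace(lo, hi, 100), data_range=(x.min(), x.max()))
        band.to_csv(out / "band_c24_snapshot.csv", index=False)
        bundle["headline"] = headline
        bundle["quartiles"] = quart
        bundle["band"] = band
    except Exception as e:  # noqa: BLE001
        raise PipelineError("exposure_response", str(e)) from e
    log.stage(
        "exposure_response",
        headline_slope=bundle["headline"].slope,
        headline_p=bundle["headline"].slope_p,
    )
    log.stage("done")
    return bundle
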