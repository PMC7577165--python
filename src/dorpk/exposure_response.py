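"""Week-48 binary endpoint construction and exposure-response analysis.

Two endpoint rules are implemented for the week-48 HIV-1 RNA threshold
endpoints (<50 or <40 copies/ml):

* snapshot: any missing week-48 value counts as failure; nobody is excluded.
* observed failure: subjects with a measured value are classified against
  the threshold; monotone missingness from efficacy-related discontinuation
  counts as failure; missingness for other reasons excludes the subject.

Exposure-response is a maximum-likelihood logistic model
logit P(response) = alpha + beta * g(x) with g the identity ("linear") or
the natural log ("log") of the steady-state exposure metric.  Inference on
the slope is Wald by default (CI = beta +/- 1.96*SE, two-sided p), with a
likelihood-ratio p available; models are compared by AIC with ties going to
the linear form.  Observed responder proportions by exposure quartile carry
exact Clopper-Pearson 95% intervals, and the model prediction band is the
delta-method 95% CI of the linear predictor pushed through the inverse
logit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .structural import ExposureMetrics
from .trial_data import EfficacyRecord

__all__ = [
    "BinaryEndpoint",
    "ERFit",
    "QuartileSummary",
    "classify_snapshot",
    "classify_observed_failure",
    "fit_er_model",
    "compare_models_aic",
    "quartile_summary",
    "prediction_band",
]

Z95 = 1.96


@dataclass(frozen=True)
class BinaryEndpoint:
    subject_id: str
    response: int | None  # None = excluded (observed-failure only)
    approach: str  # "snapshot" | "observed_failure"
    threshold: float

    @property
    def excluded(self) -> bool:
        return self.response is None


@dataclass
class ERFit:
    intercept: float
    slope: float
    vcov: np.ndarray
    aic: float
    loglik: float
    slope_ci95: tuple[float, float]
    slope_p: float
    exposure_metric: str
    form: str
    n: int
    subject_ids: tuple[str, ...]
    converged: bool = True
    separation: bool = False


@dataclass
class QuartileSummary:
    metric: str
    table: pd.DataFrame  # quartile, exposure_median, n, responders, proportion, ci_low, ci_high
    n_total: int


def _check_threshold(threshold: float) -> None:
    if threshold <= 0:
        raise ValueError("threshold must be positive")


def classify_snapshot(record: EfficacyRecord, threshold: float) -> BinaryEndpoint:
    """Regulatory snapshot rule: missing week-48 value = failure."""
    _check_threshold(threshold)
    resp = int(record.week48_rna is not None and record.week48_rna < threshold)
    return BinaryEndpoint(record.subject_id, resp, "snapshot", threshold)


def classify_observed_failure(record: EfficacyRecord, threshold: float) -> BinaryEndpoint:
    """Observed-failure rule.

    Measured value -> compare with threshold; missing after an
    efficacy-related discontinuation -> failure; missing for other reasons
    -> excluded.  Missing with no discontinuation reason (intermittent
    missingness) is excluded with a warning: the rule defines only monotone
    missingness.
    """
    _check_threshold(threshold)
    if record.week48_rna is not None:
        resp: int | None = int(record.week48_rna < threshold)
    elif record.disc_reason == "lack_of_efficacy":
        resp = 0
    else:
        if record.disc_reason == "none":
            warnings.warn(
                f"subject {record.subject_id}: missing week-48 value without a "
                "discontinuation reason; excluded from observed-failure analysis"
            )
        resp = None
    return BinaryEndpoint(record.subject_id, resp, "observed_failure", threshold)


def _analysis_arrays(
    endpoints: Sequence[BinaryEndpoint],
    exposures: Mapping[str, "ExposureMetrics | float"],
    metric: str,
):
    ids, y, x = [], [], []
    for e in endpoints:
        if e.excluded:
            continue
        ex = exposures[e.subject_id]
        val = getattr(ex, metric) if isinstance(ex, ExposureMetrics) else float(ex)
        ids.append(e.subject_id)
        y.append(e.response)
        x.append(val)
    return ids, np.asarray(y, float), np.asarray(x, float)


def fit_er_model(
    endpoints: Sequence[BinaryEndpoint],
    exposures: Mapping[str, "ExposureMetrics | float"],
    metric: str = "c24",
    form: str = "linear",
    pvalue: str = "wald",
) -> ERFit:
    """ML logistic fit of response on g(exposure).

    `exposures` maps subject_id to an ExposureMetrics (the `metric` field is
    used) or directly to a float.  form="linear" uses the exposure itself on
    the logit scale, form="log" its natural log.  AIC = 2*2 - 2*logL.
    """
    if form not in ("linear", "log"):
        raise ValueError("form must be 'linear' or 'log'")
    ids, y, x = _analysis_arrays(endpoints, exposures, metric)
    if len(np.unique(x)) < 2:
        raise ValueError("need >= 2 distinct exposure values among analysis subjects")
    if form == "log":
        if np.any(x <= 0):
            raise ValueError("log form requires positive exposures")
        g = np.log(x)
    else:
        g = x

    X = sm.add_constant(g)
    separation = len(np.unique(y)) < 2
    converged = False
    params = np.array([np.nan, np.nan])
    vcov = np.full((2, 2), np.nan)
    llf = np.nan
    if not separation:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(y, X).fit(disp=0, maxiter=200)
                params = np.asarray(res.params, float)
                vcov = np.asarray(res.cov_params(), float)
                llf = float(res.llf)
                converged = bool(res.mle_retvals.get("converged", True))
                # runaway estimates on the working scale indicate separation
                if not np.all(np.isfinite(vcov)) or np.abs(params).max() > 1e3 * max(
                    1.0, 1.0 / (np.abs(g).max() + 1e-12)
                ):
                    separation = True
            except Exception:
                separation = True
    if separation:
        converged = False

    if converged:
        se = float(np.sqrt(vcov[1, 1]))
        ci = (params[1] - Z95 * se, params[1] + Z95 * se)
        if pvalue == "wald":
            p = float(2.0 * stats.norm.sf(abs(params[1] / se)))
        elif pvalue == "lr":
            p_null = y.mean()
            ll0 = float(np.sum(y * np.log(p_null) + (1 - y) * np.log1p(-p_null)))
            p = float(stats.chi2.sf(2.0 * (llf - ll0), df=1))
        else:
            raise ValueError("pvalue must be 'wald' or 'lr'")
        aic = 2.0 * 2 - 2.0 * llf
    else:
        ci, p, aic = (np.nan, np.nan), np.nan, np.nan

    return ERFit(
        intercept=float(params[0]),
        slope=float(params[1]),
        vcov=vcov,
        aic=float(aic),
        loglik=float(llf),
        slope_ci95=ci,
        slope_p=p,
        exposure_metric=metric,
        form=form,
        n=len(y),
        subject_ids=tuple(ids),
        converged=converged,
        separation=separation,
    )


def compare_models_aic(fit_linear: ERFit, fit_log: ERFit) -> dict:
    """Delta AIC (linear - log) and the selected form; ties pick linear."""
    if set(fit_linear.subject_ids) != set(fit_log.subject_ids):
        raise ValueError("fits use different analysis sets; AIC not comparable")
    if not (fit_linear.converged and fit_log.converged):
        raise ValueError("both fits must have converged")
    delta = fit_linear.aic - fit_log.aic
    return {
        "delta_aic": float(delta),
        "selected": "linear" if delta <= 0 else "log",
        "aic_linear": fit_linear.aic,
        "aic_log": fit_log.aic,
    }


def quartile_summary(
    endpoints: Sequence[BinaryEndpoint],
    exposures: Mapping[str, "ExposureMetrics | float"],
    metric: str = "c24",
) -> QuartileSummary:
    """Observed responder proportion per exposure quartile with exact
    (Clopper-Pearson) 95% CIs.  Values tied with a quartile boundary go to
    the lower bin."""
    ids, y, x = _analysis_arrays(endpoints, exposures, metric)
    if len(y) < 8:
        raise ValueError("quartile summary needs >= 8 analysis subjects")
    cuts = np.percentile(x, [25, 50, 75], method="linear")
    bins = (x[:, None] > cuts[None, :]).sum(axis=1)
    rows = []
    for q in range(4):
        mask = bins == q
        n = int(mask.sum())
        if n == 0:
            rows.append((q + 1, np.nan, 0, 0, np.nan, np.nan, np.nan))
            continue
        r = int(y[mask].sum())
        lo, hi = proportion_confint(r, n, alpha=0.05, method="beta")
        rows.append((q + 1, float(np.median(x[mask])), n, r, r / n, float(lo), float(hi)))
    table = pd.DataFrame(
        rows,
        columns=["quartile", "exposure_median", "n", "responders", "proportion", "ci_low", "ci_high"],
    )
    return QuartileSummary(metric=metric, table=table, n_total=len(y))


def prediction_band(
    fit: ERFit,
    exposure_grid: Sequence[float],
    data_range: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Mean model prediction with a delta-method 95% band on a grid.

    The band is inverse-logit of (linear predictor +/- 1.96 * SE), so it
    always contains the point prediction and stays inside [0, 1].  Grid
    points outside `data_range` (if given) are flagged as extrapolation.
    """
    if not fit.converged:
        raise ValueError("prediction band requires a converged fit")
    x = np.asarray(exposure_grid, float)
    g = np.log(x) if fit.form == "log" else x
    X = np.column_stack([np.ones_like(g), g])
    lp = X @ np.array([fit.intercept, fit.slope])
    se = np.sqrt(np.einsum("ij,jk,ik->i", X, fit.vcov, X))
    out = pd.DataFrame(
        {
            "exposure": x,
            "prediction": stats.logistic.cdf(lp),
            "ci_low": stats.logistic.cdf(lp - Z95 * se),
            "ci_high": stats.logistic.cdf(lp + Z95 * se),
        }
    )
    if data_range is not None:
        out["extrapolation"] = (x < data_range[0]) | (x > data_range[1])
    return out
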