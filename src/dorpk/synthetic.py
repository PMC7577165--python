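"""Seeded generator of switch-trial-like PK/PD datasets.

Emulates the immediate-switch arm of a 2:1 switch study: ~443 virologically
suppressed adults on once-daily 100 mg oral dosing, sparse PK sampling
(day-1 predose; week-4 trough; week-12 sample at an arbitrary time after
dose; weeks 24 and 48 trough plus a 0.5-2 h post-dose sample), log-normal
between-subject variability on CL/F, V/F and ka, proportional residual
error, and a week-48 binary virologic endpoint generated from a logistic
exposure-efficacy model that is flat (slope 0) by default with ~90%
responders.  A configurable fraction of subjects has a missing week-48
measurement, split between efficacy-related and other discontinuations.

The full generative truth (individual parameters, exposures, response
probabilities) is returned alongside the dataset so estimation code can be
tested by parameter recovery.

The default truth parameters are this package's own calibration: they are
chosen so the simulated steady-state exposure distributions match published
summary exposures for doravirine 100 mg once daily; they are not estimates
from any clinical dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from scipy import stats
from scipy.special import expit, logit

from .nlme import PopulationModel
from .structural import ThetaVector, _conc_kernel, exposure_table
from .trial_data import (
    AnalysisConfig,
    DosingRegimen,
    EfficacyRecord,
    PKRecord,
    Subject,
)

__all__ = [
    "SimulationConfig",
    "TrialTruth",
    "default_true_model",
    "sampling_schedule",
    "simulate_truth",
    "simulate_trial",
]


def default_true_model() -> PopulationModel:
    """Generator truth calibrated to published 100-mg exposure summaries.

    Typical CL/F 5.66 L/h and (HIV) V/F ~150 L with ka 1/h give geometric
    mean AUC0-24 ~41.5 uM*h, C24 ~1.09 uM and Cmax ~2.4 uM; the variance
    components are chosen so TOTAL variability (covariates + BSV) matches
    geometric CVs of roughly 23% (AUC), 36% (C24) and 16.5% (Cmax).
    """
    return PopulationModel(
        theta=ThetaVector(
            tvcl=5.66,
            tvv=130.4,  # healthy reference; x1.15 for HIV -> ~150 L
            tvka=1.0,
            beta_wt_v=0.5,
            beta_hiv_v=1.15,
            beta_age_cl=-0.2,
        ),
        omega2=(0.22**2, 0.12**2, 0.40**2),
        sigma_prop=0.20,
        sigma_add=0.0,
    )


@dataclass
class SimulationConfig:
    """Full generative truth plus trial-design constants."""

    n_subjects: int = 443
    seed: int = 20240
    regimen: DosingRegimen = field(default_factory=DosingRegimen)
    true_model: PopulationModel = field(default_factory=default_true_model)
    # covariates
    weight_median: float = 70.0
    weight_cv: float = 0.15
    age_mean: float = 45.0
    age_sd: float = 11.0
    age_bounds: tuple[float, float] = (18.0, 78.0)
    healthy_frac: float = 0.0  # optional mixed healthy cohort (off by default)
    # sampling design: "sparse" (switch-trial schedule) or "rich"
    schedule: str = "sparse"
    rich_tads: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0, 6.0, 10.0, 16.0, 24.0)
    postdose_window: tuple[float, float] = (0.5, 2.0)
    # efficacy model: P(response) = expit(logit(p_response) + er_slope*(x - er_center))
    p_response: float = 0.90
    er_slope: float = 0.0
    er_metric: str = "c24"
    er_center: float = 0.0
    rna_threshold: float = 50.0
    missing_frac: float = 0.08
    missing_loe_frac: float = 0.40

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for p in (self.p_response, self.missing_frac, self.missing_loe_frac):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if not 0.0 < self.p_response < 1.0:
            raise ValueError("p_response must lie in (0, 1)")
        lo, hi = self.postdose_window
        if not (0 <= lo < hi <= self.regimen.tau):
            raise ValueError("postdose window bounds inverted or outside [0, tau]")
        if self.schedule not in ("sparse", "rich"):
            raise ValueError("schedule must be 'sparse' or 'rich'")
        if self.er_metric not in ("auc24", "cmax", "c24"):
            raise ValueError("er_metric must be auc24, cmax or c24")


@dataclass
class TrialTruth:
    subject_ids: list[str]
    eta: np.ndarray
    cl: np.ndarray
    v: np.ndarray
    ka: np.ndarray
    exposures: "object"  # DataFrame from exposure_table
    p_response: np.ndarray
    responder: np.ndarray


# dose-number / time-after-dose pairs per visit; trough sampled at TAD=tau
def sampling_schedule(
    config: SimulationConfig, rng: np.random.Generator
) -> list[list[tuple[str, int, float]]]:
    """Per-subject list of (label, n_doses_given, time_after_dose) samples.

    Sparse default: week-4 trough; week-12 TAD ~ U(0, tau); weeks 24 and 48
    trough + post-dose TAD ~ U(postdose_window).  The day-1 predose sample
    (before any drug) is handled by `simulate_trial`, not listed here.
    """
    tau = config.regimen.tau
    lo, hi = config.postdose_window
    out = []
    for _ in range(config.n_subjects):
        if config.schedule == "rich":
            out.append([("wk4_rich", 28, float(t)) for t in config.rich_tads])
            continue
        out.append(
            [
                ("wk4_trough", 28, tau),
                ("wk12_any", 85, float(rng.uniform(0.0, tau))),
                ("wk24_trough", 168, tau),
                ("wk24_post", 169, float(rng.uniform(lo, hi))),
                ("wk48_trough", 336, tau),
                ("wk48_post", 337, float(rng.uniform(lo, hi))),
            ]
        )
    return out


def _draw_covariates(config: SimulationConfig, rng: np.random.Generator):
    n = config.n_subjects
    sdlog = np.sqrt(np.log1p(config.weight_cv**2))
    weight = config.weight_median * np.exp(rng.normal(0.0, sdlog, n))
    a, b = (
        (config.age_bounds[0] - config.age_mean) / config.age_sd,
        (config.age_bounds[1] - config.age_mean) / config.age_sd,
    )
    age = stats.truncnorm.rvs(
        a, b, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng
    )
    healthy = rng.random(n) < config.healthy_frac
    subjects = [
        Subject(
            subject_id=f"S{i + 1:04d}",
            weight=float(weight[i]),
            age=float(age[i]),
            status="healthy" if healthy[i] else "hiv",
            group="naive" if healthy[i] else "ISG",
        )
        for i in range(n)
    ]
    return subjects


def simulate_truth(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    analysis: AnalysisConfig | None = None,
) -> tuple[list[Subject], TrialTruth, list[EfficacyRecord]]:
    """Draw subjects, individual parameters, true exposures and the binary
    endpoint — everything except the PK samples (fast path for endpoint
    replicate studies)."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    analysis = analysis or AnalysisConfig(regimen=config.regimen)
    subjects = _draw_covariates(config, rng)
    m = config.true_model
    om = np.sqrt(np.asarray(m.omega2))
    eta = rng.normal(0.0, 1.0, (config.n_subjects, 3)) * om

    th = m.theta
    weight = np.array([s.weight for s in subjects])
    age = np.array([s.age for s in subjects])
    is_hiv = np.array([s.status == "hiv" for s in subjects])
    cl = th.tvcl * (age / analysis.age_ref) ** th.beta_age_cl * np.exp(eta[:, 0])
    v = th.tvv * (weight / analysis.weight_ref) ** th.beta_wt_v
    v = np.where(is_hiv, v * th.beta_hiv_v, v) * np.exp(eta[:, 1])
    ka = th.tvka * np.exp(eta[:, 2])

    exp_tab = exposure_table([s.subject_id for s in subjects], cl, v, ka, config.regimen)
    x = exp_tab[config.er_metric].to_numpy()
    p = expit(logit(config.p_response) + config.er_slope * (x - config.er_center))
    responder = rng.random(config.n_subjects) < p

    missing = rng.random(config.n_subjects) < config.missing_frac
    loe = rng.random(config.n_subjects) < config.missing_loe_frac
    disc_week = rng.integers(4, 48, config.n_subjects)
    rna_resp = rng.uniform(0.0, 0.9 * config.rna_threshold, config.n_subjects)
    rna_fail = 10 ** rng.uniform(np.log10(1.2 * config.rna_threshold), 4.0, config.n_subjects)

    efficacy = []
    for i, s in enumerate(subjects):
        if missing[i]:
            efficacy.append(
                EfficacyRecord(
                    subject_id=s.subject_id,
                    week48_rna=None,
                    disc_reason="lack_of_efficacy" if loe[i] else "other",
                    disc_week=float(disc_week[i]),
                )
            )
        else:
            rna = rna_resp[i] if responder[i] else rna_fail[i]
            efficacy.append(EfficacyRecord(subject_id=s.subject_id, week48_rna=float(rna)))

    truth = TrialTruth(
        subject_ids=[s.subject_id for s in subjects],
        eta=eta,
        cl=cl,
        v=v,
        ka=ka,
        exposures=exp_tab,
        p_response=p,
        responder=responder.astype(int),
    )
    return subjects, truth, efficacy


def simulate_trial(
    config: SimulationConfig, analysis: AnalysisConfig | None = None
) -> tuple[list[PKRecord], list[Subject], list[EfficacyRecord], TrialTruth]:
    """Generate a complete trial dataset plus its generative truth.

    Concentrations are f*(1 + sigma_prop*eps) + sigma_add*eps', truncated at
    zero; the day-1 predose sample is recorded as DV=0 with MDV=1 (no drug
    on board, not usable for fitting).  Identical seeds give identical
    output, row for row.
    """
    rng = np.random.default_rng(config.seed)
    analysis = analysis or AnalysisConfig(regimen=config.regimen)
    subjects, truth, efficacy = simulate_truth(config, rng, analysis)
    schedule = sampling_schedule(config, rng)
    tau = config.regimen.tau
    amt = config.regimen.amount_nmol
    m = config.true_model

    records: list[PKRecord] = []
    for i, subj in enumerate(subjects):
        visits = schedule[i]
        n_days = max(nd for _, nd, _ in visits)
        rows: list[tuple[float, int, PKRecord]] = []
        # day-1 predose (before the first dose): no doravirine on board
        rows.append(
            (0.0, 0, PKRecord(subj.subject_id, 0.0, dv=0.0, evid=0, mdv=1, time_after_dose=None))
        )
        for d in range(n_days):
            t = d * tau
            rows.append(
                (t, 1, PKRecord(subj.subject_id, t, amt=amt, evid=1, mdv=1))
            )
        u = np.array([tad for _, _, tad in visits])
        nd = np.array([n for _, n, _ in visits], float)
        f = _conc_kernel(u, nd, truth.cl[i], truth.v[i], truth.ka[i], amt, tau)
        eps = rng.normal(0.0, 1.0, len(visits))
        eps2 = rng.normal(0.0, 1.0, len(visits))
        dv = np.maximum(f * (1.0 + m.sigma_prop * eps) + m.sigma_add * eps2, 0.0)
        for k, (_, n, tad) in enumerate(visits):
            t = (n - 1) * tau + tad
            rows.append(
                (t, 0, PKRecord(subj.subject_id, t, dv=float(dv[k]), evid=0, mdv=0, time_after_dose=tad))
            )
        rows.sort(key=lambda r: (r[0], r[1]))  # observations precede same-time doses
        records.extend(r for _, _, r in rows)
    return records, subjects, efficacy, truth
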