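"""One-compartment oral PK model with first-order absorption.

Everything downstream (likelihood, post hoc parameters, exposure metrics)
rests on the closed-form concentration of a one-compartment model with
first-order absorption, linear apparent clearance CL/F and apparent volume
V/F (bioavailability F is not separately identifiable and is absorbed into
both).  With ke = CL/V, dose D (nmol) every tau hours, the steady-state
concentration t hours after a dose is

    C_ss(t) = D*ka / (V*(ka-ke)) * [ exp(-ke*t)/(1-exp(-ke*tau))
                                    - exp(-ka*t)/(1-exp(-ka*tau)) ]

in nM.  Before steady state the finite superposition over the doses actually
given is used; both reduce to the same geometric partial sums, evaluated in a
form that cannot overflow.  The removable singularity at ka = ke is handled
with the exact L'Hopital limit, triggered at relative rate difference 1e-8.

Covariates enter through the typical parameters only: a power of body weight
and a multiplicative infection-status factor on V/F, a power of age on CL/F.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trial_data import AnalysisConfig, DosingRegimen, Subject

__all__ = [
    "ThetaVector",
    "IndividualParams",
    "ExposureMetrics",
    "typical_params",
    "conc_ss",
    "conc_profile_n_doses",
    "steady_state_metrics",
    "exposure_table",
]

#: relative |ka - ke| below which the equal-rate limit formula is used
EQUAL_RATE_RTOL = 1e-8


@dataclass(frozen=True)
class ThetaVector:
    """Fixed effects: typical parameter values plus covariate coefficients.

    tvcl (L/h), tvv (L) and tvka (1/h) are the typical apparent clearance,
    volume and absorption rate for a reference subject (weight = weight_ref,
    age = age_ref, healthy).  beta_wt_v and beta_age_cl are power-model
    exponents; beta_hiv_v multiplies V/F for HIV-1-infected subjects.
    """

    tvcl: float
    tvv: float
    tvka: float
    beta_wt_v: float = 0.0
    beta_hiv_v: float = 1.0
    beta_age_cl: float = 0.0

    def __post_init__(self) -> None:
        if not (self.tvcl > 0 and self.tvv > 0 and self.tvka > 0):
            raise ValueError("typical CL/F, V/F and ka must be positive")
        if not self.beta_hiv_v > 0:
            raise ValueError("beta_hiv_v must be positive (multiplicative factor)")


@dataclass(frozen=True)
class IndividualParams:
    cl: float
    v: float
    ka: float

    def __post_init__(self) -> None:
        if not (self.cl > 0 and self.v > 0 and self.ka > 0):
            raise ValueError("individual CL/F, V/F and ka must be positive")

    @property
    def ke(self) -> float:
        return self.cl / self.v


@dataclass(frozen=True)
class ExposureMetrics:
    """Steady-state exposure over one dosing interval.

    auc24 in uM*h (AUC over the interval = D/CL at steady state), cmax and
    c24 (trough) in nM, tmax in hours after dose.
    """

    auc24: float
    cmax: float
    c24: float
    tmax: float


def typical_params(
    theta: ThetaVector, subject: Subject, config: AnalysisConfig
) -> IndividualParams:
    """Typical CL/F, V/F, ka for a subject's covariates.

    Weight and infection status act on V/F only; age acts on CL/F only.
    """
    if subject.weight <= 0 or subject.age <= 0:
        raise ValueError("subject weight and age must be positive")
    cl = theta.tvcl * (subject.age / config.age_ref) ** theta.beta_age_cl
    v = theta.tvv * (subject.weight / config.weight_ref) ** theta.beta_wt_v
    if subject.status == "hiv":
        v *= theta.beta_hiv_v
    return IndividualParams(cl=cl, v=v, ka=theta.tvka)


# ---------------------------------------------------------------------------
# Array kernels (complex-step safe; used by the likelihood machinery too)
# ---------------------------------------------------------------------------


def _real(x):
    return x.real if np.iscomplexobj(x) else x


def _conc_kernel(u, n_dose, cl, v, ka, dose, tau):
    """Concentration u hours after the n_dose-th of equally spaced doses.

    n_dose = inf gives the steady-state profile.  All array arguments
    broadcast; complex dtypes propagate (for complex-step derivatives).
    Partial geometric sums are written as exp(-k*u)*(1-r^n)/(1-r) with
    r = exp(-k*tau) <= 1, so nothing overflows for large n.
    """
    ke = cl / v
    at_ss = np.isinf(n_dose)

    def gsum(k):
        r = np.exp(-k * tau)
        num = np.where(at_ss, 1.0, 1.0 - r ** np.where(at_ss, 1.0, n_dose))
        return np.exp(-k * u) * num / (1.0 - r)

    diff = ka - ke
    equal = np.abs(diff) <= EQUAL_RATE_RTOL * np.abs(ke)
    safe_diff = np.where(equal, 1.0, diff)

    general = dose * ka / (v * safe_diff) * (gsum(ke) - gsum(ka))

    # equal-rate limit: single dose C(s) = (D/V) k s exp(-k s); superpose
    k = ke
    r = np.exp(-k * tau)
    n_eff = np.where(at_ss, 1.0, n_dose)
    rn = r**n_eff
    A = np.where(at_ss, 1.0 / (1.0 - r), (1.0 - rn) / (1.0 - r))
    B_fin = r * (1.0 - n_eff * r ** np.maximum(_real(n_eff) - 1, 0) + (n_eff - 1.0) * rn)
    B = np.where(at_ss, r / (1.0 - r) ** 2, B_fin / (1.0 - r) ** 2)
    limit = dose * k / v * np.exp(-k * u) * (u * A + tau * B)

    out = np.where(equal, limit, general)
    zero = _real(np.asarray(n_dose)) == 0
    return np.where(zero, 0.0 * out, out)


def conc_ss(t_after_dose, params: IndividualParams, regimen: DosingRegimen):
    """Steady-state concentration (nM) at t hours after a dose, t in [0, tau]."""
    t = np.asarray(t_after_dose, dtype=float)
    if np.any(t < 0) or np.any(t > regimen.tau):
        raise ValueError(f"t_after_dose must lie in [0, {regimen.tau}]")
    out = _conc_kernel(
        t, np.inf, params.cl, params.v, params.ka, regimen.amount_nmol, regimen.tau
    )
    return float(out) if np.isscalar(t_after_dose) else out


def conc_profile_n_doses(t, n_doses: int, params: IndividualParams, regimen: DosingRegimen):
    """Concentration at t hours since the first dose, doses at 0, tau, ...,
    (n_doses-1)*tau.  Doses scheduled after t do not contribute.

    Converges to conc_ss(t mod tau) as n_doses grows.
    """
    tt = np.asarray(t, dtype=float)
    if np.any(tt < 0):
        raise ValueError("t must be >= 0")
    if n_doses < 0:
        raise ValueError("n_doses must be >= 0")
    n_given = np.minimum(n_doses, np.floor(tt / regimen.tau) + 1)
    u = tt - (n_given - 1) * regimen.tau
    u = np.where(n_given > 0, u, 0.0)
    out = _conc_kernel(
        u, n_given, params.cl, params.v, params.ka, regimen.amount_nmol, regimen.tau
    )
    return float(out) if np.isscalar(t) else out


def _tmax_ss(cl, v, ka, tau):
    ke = cl / v
    diff = ka - ke
    equal = np.abs(diff) <= EQUAL_RATE_RTOL * np.abs(ke)
    safe = np.where(equal, 1.0, diff)
    gen = np.log(ka * (1.0 - np.exp(-ke * tau)) / (ke * (1.0 - np.exp(-ka * tau)))) / safe
    r = np.exp(-ke * tau)
    lim = 1.0 / ke - tau * r / (1.0 - r)  # stationarity of the equal-rate profile
    return np.where(equal, lim, gen)


def steady_state_metrics(params: IndividualParams, regimen: DosingRegimen) -> ExposureMetrics:
    """AUC0-tau (uM*h), Cmax, Ctrough and tmax at steady state.

    AUC over a dosing interval at steady state is exactly D/CL; tmax has the
    closed form ln[ka(1-e^{-ke tau}) / (ke(1-e^{-ka tau}))] / (ka - ke).
    """
    D = regimen.amount_nmol
    auc_nMh = D / params.cl
    tmax = float(_tmax_ss(params.cl, params.v, params.ka, regimen.tau))
    tmax = min(max(tmax, 0.0), regimen.tau)
    cmax = float(conc_ss(tmax, params, regimen))
    c24 = float(conc_ss(regimen.tau, params, regimen))
    return ExposureMetrics(auc24=auc_nMh / 1000.0, cmax=cmax, c24=c24, tmax=tmax)


def exposure_table(
    subject_ids, cl, v, ka, regimen: DosingRegimen
) -> pd.DataFrame:
    """Vectorized steady-state metrics for arrays of individual parameters.

    Returns a DataFrame with columns subject_id, cl, v, ka, auc24, cmax,
    c24, tmax (units as in ExposureMetrics).
    """
    cl = np.asarray(cl, float)
    v = np.asarray(v, float)
    ka = np.asarray(ka, float)
    D = regimen.amount_nmol
    tmax = np.clip(_tmax_ss(cl, v, ka, regimen.tau), 0.0, regimen.tau)
    cmax = _conc_kernel(tmax, np.inf, cl, v, ka, D, regimen.tau)
    c24 = _conc_kernel(regimen.tau, np.inf, cl, v, ka, D, regimen.tau)
    return pd.DataFrame(
        {
            "subject_id": list(subject_ids),
            "cl": cl,
            "v": v,
            "ka": ka,
            "auc24": D / cl / 1000.0,
            "cmax": cmax,
            "c24": c24,
            "tmax": tmax,
        }
    )
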