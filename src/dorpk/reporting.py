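"""Exposure summary statistics (geometric mean / %CV, percentiles)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ExposureSummary", "exposure_summary", "percentile_summary"]

DEFAULT_PROBS = (5.0, 25.0, 50.0, 75.0, 95.0)


@dataclass
class ExposureSummary:
    metric: str
    n: int
    geometric_mean: float
    geometric_cv_pct: float
    percentiles: dict[float, float]


def exposure_summary(values, metric: str = "") -> ExposureSummary:
    """Geometric mean exp(mean(ln x)) and geometric %CV
    100*sqrt(exp(sd_ln^2) - 1) with the n-1 sample SD of ln x."""
    x = np.asarray(values, float)
    if x.size < 1:
        raise ValueError("need at least one value")
    bad = np.where(~(x > 0))[0]
    if bad.size:
        raise ValueError(f"non-positive value at position {bad[0]}")
    lx = np.log(x)
    sd = np.std(lx, ddof=1) if x.size > 1 else 0.0
    return ExposureSummary(
        metric=metric,
        n=int(x.size),
        geometric_mean=float(np.exp(lx.mean())),
        geometric_cv_pct=float(100.0 * np.sqrt(np.expm1(sd**2))),
        percentiles=dict(zip(DEFAULT_PROBS, percentile_summary(x))) if x.size > 1 else {},
    )


def percentile_summary(values, probs=DEFAULT_PROBS, method: str = "linear"):
    """Percentiles by linear interpolation (config-switchable method)."""
    x = np.asarray(values, float)
    if x.size < 2:
        raise ValueError("need at least two values")
    return np.percentile(x, list(probs), method=method)
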