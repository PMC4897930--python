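"""Exceedance flagging, precision classification and trend testing.

An area is flagged as elevated when at least 95% of its posterior prevalence
draws exceed the regional average prevalence *of the same draw* (a joint
posterior comparison, so regional uncertainty propagates into the flag).
Estimate precision is graded by the coefficient of variation with the
standard survey-release bands: acceptable below 16.6%, marginal from 16.6 to
33.3% (boundaries inclusive), low above 33.3%.  The two are related: areas
estimated more precisely tend to reach high exceedance probabilities, which
the Pearson correlation between CVs and exceedance probabilities quantifies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bym import PosteriorDraws

__all__ = [
    "ExceedanceReport",
    "exceedance_probabilities",
    "cv_classify",
    "classify_precision",
    "precision_exceedance_correlation",
    "trend_test",
    "surveillance_report",
]

FLAG_THRESHOLD = 0.95
CV_ACCEPTABLE_MAX = 16.6
CV_MARGINAL_MAX = 33.3


@dataclass
class ExceedanceReport:
    per_area: pd.DataFrame  # exceedance_prob, flagged, cv_percent, cv_class
    region_draws: np.ndarray
    correlation_r: float
    correlation_p: float


def exceedance_probabilities(
    area_draws: pd.DataFrame,
    region_draws: np.ndarray,
) -> pd.DataFrame:
    """Fraction of draws in which each area exceeds the regional average.

    ``area_draws`` has one column per area and one row per draw, aligned
    with ``region_draws`` (same draw indices).  The comparison is strict;
    flagging uses the >= 0.95 rule.
    """
    region_draws = np.asarray(region_draws, dtype=float)
    if len(area_draws) != len(region_draws):
        raise ValueError("area and regional draws are misaligned")
    probs = (area_draws.to_numpy() > region_draws[:, None]).mean(axis=0)
    return pd.DataFrame({
        "exceedance_prob": probs,
        "flagged": probs >= FLAG_THRESHOLD,
    }, index=area_draws.columns).rename_axis("area_id")


def cv_classify(posterior_mean: float, posterior_sd: float) -> tuple[float, str]:
    """Coefficient of variation (percent) and its precision class.

    CV = 100 * sd / mean; < 16.6 acceptable, 16.6-33.3 marginal (inclusive
    at both boundaries), > 33.3 low.
    """
    if posterior_mean <= 0:
        raise ValueError("CV undefined for non-positive mean")
    cv = 100.0 * posterior_sd / posterior_mean
    cv_cmp = round(cv, 9)  # make the inclusive band edges float-robust
    if cv_cmp < CV_ACCEPTABLE_MAX:
        cls = "acceptable"
    elif cv_cmp <= CV_MARGINAL_MAX:
        cls = "marginal"
    else:
        cls = "low"
    return cv, cls


def classify_precision(summary: pd.DataFrame) -> pd.DataFrame:
    """Vectorised ``cv_classify`` over an area summary frame
    (``posterior_mean``/``posterior_sd`` columns)."""
    pairs = [
        cv_classify(m, s)
        for m, s in zip(summary["posterior_mean"], summary["posterior_sd"])
    ]
    out = summary.copy()
    out["cv_percent"] = [p[0] for p in pairs]
    out["cv_class"] = [p[1] for p in pairs]
    return out


def precision_exceedance_correlation(
    exceedance_probs: np.ndarray,
    cvs: np.ndarray,
) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between exceedance and CV."""
    exceedance_probs = np.asarray(exceedance_probs, dtype=float)
    cvs = np.asarray(cvs, dtype=float)
    if len(exceedance_probs) != len(cvs) or len(cvs) < 3:
        raise ValueError("need >= 3 paired values")
    if np.var(exceedance_probs) == 0 or np.var(cvs) == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = stats.pearsonr(exceedance_probs, cvs)
    return float(r), float(p)


def trend_test(draws: PosteriorDraws) -> dict:
    """Posterior summary of the integer-cycle slope.

    Significant iff the central 95% credible interval strictly excludes 0.
    Requires a fit with ``cycle_coding='integer_trend'``.
    """
    if draws.trend_slope is None:
        raise ValueError("trend test requires an integer-trend fit "
                         "(categorical-cycle draws supplied)")
    slope = draws.trend_slope
    lo, hi = np.quantile(slope, [0.025, 0.975])
    return {
        "slope_mean": float(slope.mean()),
        "ci95": (float(lo), float(hi)),
        "significant": bool(lo > 0 or hi < 0),
    }


def surveillance_report(
    area_draws: pd.DataFrame,
    region_draws: np.ndarray,
) -> ExceedanceReport:
    """Full per-area report: exceedance, flags, CV class, and the
    exceedance-precision correlation."""
    exc = exceedance_probabilities(area_draws, region_draws)
    summary = pd.DataFrame({
        "posterior_mean": area_draws.mean(),
        "posterior_sd": area_draws.std(ddof=1),
    })
    summary = classify_precision(summary)
    per_area = exc.join(summary)
    r, p = precision_exceedance_correlation(
        per_area["exceedance_prob"].to_numpy(), per_area["cv_percent"].to_numpy()
    )
    return ExceedanceReport(
        per_area=per_area,
        region_draws=np.asarray(region_draws, dtype=float),
        correlation_r=r,
        correlation_p=p,
    )
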