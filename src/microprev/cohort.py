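"""Risk-factor classification and pooled-cycle weight rescaling.

Respondents are classified as current smokers if they report smoking daily or
occasionally; excess bodyweight is BMI >= 25 kg/m^2 for adults and the IOTF
age- and sex-specific equivalent threshold for ages 12-17, with pregnant or
lactating respondents excluded.  Classification is pure and never drops
records silently: "missing" and "excluded" are explicit states.

For pooled multi-cycle analysis, design weights (and the bootstrap replicate
weights used for variance estimation) are rescaled so the pooled weighted
population matches a single-cycle scale rather than summing K cycles.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "EXCLUDED",
    "classify_current_smoker",
    "classify_excess_bodyweight",
    "overweight_cutoff",
    "add_risk_factor_columns",
    "rescale_pooled_weights",
    "mean_respondents_per_area",
]

MISSING = "missing"
EXCLUDED = "excluded"

_SMOKER_MAP = {"daily": 1, "occasional": 1, "former": 0, "never": 0}


def _load_iotf_table() -> pd.DataFrame:
    path = resources.files("microprev.data") / "iotf_overweight_cutoffs.csv"
    with resources.as_file(path) as p:
        return pd.read_csv(p, comment="#")


_IOTF = _load_iotf_table()
_IOTF_AGES = _IOTF["age_years"].to_numpy()
_IOTF_CUTS = {"M": _IOTF["male"].to_numpy(), "F": _IOTF["female"].to_numpy()}


def classify_current_smoker(smoking_response: str):
    """``daily``/``occasional`` -> 1; ``former``/``never`` -> 0; else missing."""
    if smoking_response == MISSING or pd.isna(smoking_response):
        return MISSING
    try:
        return _SMOKER_MAP[smoking_response]
    except KeyError:
        raise ValueError(f"unrecognised smoking response {smoking_response!r}")


def overweight_cutoff(age_years: float, sex: str) -> float:
    """BMI threshold for overweight at a given age and sex.

    Adults (18+) use 25 kg/m^2; ages 12-17.5 use the IOTF table at the
    nearest half-year of age (the table passes through 25 at age 18 by
    construction).
    """
    if sex not in ("M", "F"):
        raise ValueError(f"sex must be 'M' or 'F', got {sex!r}")
    if age_years >= 18:
        return 25.0
    if age_years < 12:
        raise ValueError("no overweight threshold below age 12")
    half = round(float(age_years) * 2) / 2
    half = min(half, 18.0)
    idx = int(np.argmin(np.abs(_IOTF_AGES - half)))
    return float(_IOTF_CUTS[sex][idx])


def classify_excess_bodyweight(
    height_m: float | None,
    weight_kg: float | None,
    age_years: float,
    sex: str,
    pregnant_or_lactating: bool = False,
):
    """Dichotomise excess bodyweight (overweight or obese) from BMI.

    Returns 1/0, or ``"excluded"`` (pregnant/lactating, or below the 12+
    classifiable range), or ``"missing"`` (height or weight unavailable).
    Heights above 3 m are rejected as a unit error (centimetres suspected).
    """
    if pregnant_or_lactating:
        return EXCLUDED
    if age_years < 12:
        return EXCLUDED
    if height_m is None or weight_kg is None or pd.isna(height_m) or pd.isna(weight_kg):
        return MISSING
    if height_m <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    if height_m > 3:
        raise ValueError(f"implausible height {height_m} m (centimetres?)")
    bmi = weight_kg / height_m**2
    return int(bmi >= overweight_cutoff(age_years, sex))


def add_risk_factor_columns(respondents: pd.DataFrame) -> pd.DataFrame:
    """Attach ``smoker`` and ``excess_bodyweight`` classification columns."""
    out = respondents.copy()
    out["smoker"] = [
        classify_current_smoker(r) for r in respondents["smoking_response"]
    ]
    out["excess_bodyweight"] = [
        classify_excess_bodyweight(h, w, a, s, p)
        for h, w, a, s, p in zip(
            respondents["height_m"], respondents["weight_kg"],
            respondents["age_years"], respondents["sex"],
            respondents["pregnant_or_lactating"],
        )
    ]
    return out


def rescale_pooled_weights(
    respondents: pd.DataFrame,
    n_cycles: int,
    method: str = "divide_k",
) -> pd.DataFrame:
    """Rescale design and bootstrap weights for a pooled K-cycle sample.

    ``divide_k`` (default) divides every weight by K, so the pooled weighted
    total equals the mean of the per-cycle weighted totals and cycle-relative
    population sizes are preserved.  ``population_share`` instead multiplies
    each cycle's weights by that cycle's share of the total weighted
    population.  Bootstrap replicate weight columns (``bsw_*``) are rescaled
    identically.
    """
    if n_cycles <= 0:
        raise ValueError("number of cycles must be positive")
    cycles = respondents["cycle"].to_numpy()
    if cycles.min() < 1 or cycles.max() > n_cycles:
        raise ValueError("respondent cycle outside 1..K")
    out = respondents.copy()
    wcols = ["design_weight"] + [c for c in out.columns if c.startswith("bsw_")]
    if method == "divide_k":
        factor = np.full(len(out), 1.0 / n_cycles)
    elif method == "population_share":
        totals = out.groupby("cycle")["design_weight"].sum()
        shares = totals / totals.sum()
        factor = shares.reindex(cycles).to_numpy()
    else:
        raise ValueError(f"unknown rescaling method {method!r}")
    for c in wcols:
        out[c] = out[c].to_numpy() * factor
    return out


def mean_respondents_per_area(n_respondents: int, n_areas: int) -> float:
    """Average respondents per unit area of analysis (pooling arithmetic)."""
    if n_areas <= 0:
        raise ValueError("n_areas must be positive")
    return n_respondents / n_areas
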