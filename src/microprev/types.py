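"""Shared domain types and categorical conventions.

The unit of geography is a "micro area": a census dissemination-area-like unit
of roughly 400-700 residents.  Survey respondents are aged 12+ and carry design
weights plus bootstrap replicate weights for variance estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Sexes used throughout (models are fitted separately per stratum).
SEXES: tuple[str, str] = ("M", "F")

#: Eight age bands covering the 12+ survey population.
AGE_GROUPS: tuple[str, ...] = (
    "12-19", "20-29", "30-39", "40-49", "50-59", "60-69", "70-79", "80+",
)

#: Reference age band for model fixed effects.
REFERENCE_AGE_GROUP = "50-59"
REFERENCE_AGE_INDEX = AGE_GROUPS.index(REFERENCE_AGE_GROUP)

#: Smoking questionnaire response categories.
SMOKING_CATEGORIES = ("daily", "occasional", "former", "never", "missing")


def age_group_of(age_years: float) -> str:
    """Map an age in years (>= 12) to its age band."""
    if age_years < 12:
        raise ValueError(f"age {age_years} below survey coverage (12+)")
    if age_years >= 80:
        return "80+"
    if age_years < 20:
        return "12-19"
    lo = int(age_years // 10) * 10
    return f"{lo}-{lo + 9}"


@dataclass
class MicroArea:
    """One geographic unit with adjacency, census structure and covariate.

    ``median_income`` is the *observed* census median household income and may
    be ``None`` (suppressed / unavailable).  ``income_true`` always holds the
    latent value used when generating synthetic outcomes, so that masking
    income does not change the generating process.
    """

    area_id: str
    centroid: tuple[float, float]
    neighbour_ids: set[str] = field(default_factory=set)
    census_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    median_income: float | None = None
    income_true: float | None = None
    county_id: str = ""

    def population(self, sex: str | None = None) -> int:
        """Total census population (optionally one sex)."""
        return sum(
            n for (s, _), n in self.census_counts.items()
            if sex is None or s == sex
        )

    def validate(self) -> None:
        if any(n < 0 for n in self.census_counts.values()):
            raise ValueError(f"negative census count in area {self.area_id}")
        if self.median_income is not None and self.median_income <= 0:
            raise ValueError(f"non-positive income in area {self.area_id}")
        if self.area_id in self.neighbour_ids:
            raise ValueError(f"area {self.area_id} is its own neighbour")


@dataclass
class GroundTruth:
    """Generating parameters for the synthetic survey (log-odds scale).

    ``cycle_effects`` has one entry per cycle with the first fixed at 0
    (reference cycle 1); ``age_effects`` has one entry per age band with the
    50-59 band fixed at 0.  ``income_coef`` is per $10,000 of median household
    income, centred at the study mean.  ``u`` (ICAR, sums to zero) and ``v``
    (iid) are per-area random effects.
    """

    intercept: float
    cycle_effects: np.ndarray
    age_effects: np.ndarray
    income_coef: float
    sigma_u: float
    sigma_v: float
    u: np.ndarray
    v: np.ndarray

    def validate(self, n_areas: int) -> None:
        if self.sigma_u < 0 or self.sigma_v < 0:
            raise ValueError("random-effect scales must be non-negative")
        if len(self.u) != n_areas or len(self.v) != n_areas:
            raise ValueError("random-effect vectors must have one entry per area")
        if abs(float(np.sum(self.u))) > 1e-8 * max(1.0, float(np.abs(self.u).max())):
            raise ValueError("spatial effects u must sum to zero")
        if self.age_effects[REFERENCE_AGE_INDEX] != 0.0:
            raise ValueError("reference age band effect must be zero")
        if self.cycle_effects[0] != 0.0:
            raise ValueError("reference cycle effect must be zero")
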