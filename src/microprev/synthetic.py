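"""Synthetic geography, census and pooled-survey generator.

Every downstream stage (adjacency building, spatial autocorrelation testing,
hierarchical model fitting, post-stratification, surveillance, scan
statistics) is exercised against data produced here with *known* generating
parameters, standing in for confidential survey microdata and census tables.

The generator emulates:

* an irregular-lattice micro-area geography (dissemination-area-like units of
  ~400-700 residents) with rook or queen adjacency and jittered centroids;
* per-area census counts over sex x eight age bands with a non-uniform age
  pyramid, and median household income with optional suppression;
* pooled survey respondents over several cycles, sampled with *unequal*
  age-specific inclusion probabilities (design weight = inverse inclusion
  probability), with-replacement bootstrap replicate weights within cycle,
  and a binary risk-factor outcome drawn from a logistic model with both
  spatially structured (ICAR) and unstructured area effects.

Raw questionnaire fields (smoking response, self-reported height and weight,
pregnancy/lactation) are synthesised consistently with the generated binary
outcome so that the classification stage can be tested end to end.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .types import AGE_GROUPS, GroundTruth, MicroArea, REFERENCE_AGE_INDEX, SEXES

__all__ = [
    "make_geography",
    "simulate_census",
    "simulate_income",
    "make_ground_truth",
    "sample_icar",
    "simulate_survey",
    "implant_cluster",
    "write_geojson",
    "write_adjacency_list",
    "write_respondents_csv",
    "write_census_csv",
    "write_params_json",
]

#: Share of the 12+ population in each age band (heavier 40-69 mass, matching
#: the pooled-cycle respondent age pattern of a mid-2000s Ontario region).
AGE_PYRAMID = np.array([0.125, 0.115, 0.150, 0.140, 0.155, 0.140, 0.110, 0.065])

#: P(male) for census cell splitting.
MALE_SHARE = 0.49

#: Relative survey inclusion rates by age band (older respondents are easier
#: to reach); design weights invert these, so uniform weighting is wrong by
#: construction and weighting bugs surface in the unbiasedness checks.
AGE_INCLUSION_FACTORS = np.array([0.60, 0.70, 0.85, 1.00, 1.10, 1.25, 1.35, 1.40])

_AGE_BOUNDS = {
    "12-19": (12, 19), "20-29": (20, 29), "30-39": (30, 39), "40-49": (40, 49),
    "50-59": (50, 59), "60-69": (60, 69), "70-79": (70, 79), "80+": (80, 94),
}


def _county_of(row: int, col: int, n_rows: int, n_cols: int) -> str:
    return f"C{int(row >= n_rows / 2)}{int(col >= n_cols / 2)}"


def make_geography(
    n_rows: int,
    n_cols: int,
    adjacency_rule: str = "queen",
    seed: int = 0,
) -> dict[str, MicroArea]:
    """Build an ``n_rows x n_cols`` lattice of micro areas.

    Centroids sit on the integer lattice with a small uniform jitter; adjacency
    follows the lattice (rook: shared edges; queen: edges + diagonals), so the
    jitter never changes neighbour structure.  Areas are partitioned into four
    quadrant "counties" to support county-level aggregation and validation.

    Returns an insertion-ordered mapping ``area_id -> MicroArea``.
    """
    if n_rows < 1 or n_cols < 1 or n_rows * n_cols < 2:
        raise ValueError("geography needs at least 2 areas (no neighbours possible)")
    if adjacency_rule not in ("rook", "queen"):
        raise ValueError(f"unknown adjacency rule {adjacency_rule!r}")
    rng = np.random.default_rng(seed)
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if adjacency_rule == "queen":
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    areas: dict[str, MicroArea] = {}
    for r in range(n_rows):
        for c in range(n_cols):
            aid = f"A{r:03d}_{c:03d}"
            jx, jy = rng.uniform(-0.2, 0.2, size=2)
            neigh = {
                f"A{r + dr:03d}_{c + dc:03d}"
                for dr, dc in offsets
                if 0 <= r + dr < n_rows and 0 <= c + dc < n_cols
            }
            areas[aid] = MicroArea(
                area_id=aid,
                centroid=(c + jx, r + jy),
                neighbour_ids=neigh,
                county_id=_county_of(r, c, n_rows, n_cols),
            )
    return areas


def simulate_census(
    areas: dict[str, MicroArea],
    mean_pop: float = 550.0,
    seed: int = 0,
) -> dict[str, MicroArea]:
    """Fill per-area census counts (sex x age band), totals around ``mean_pop``.

    Area totals are normal around ``mean_pop`` (sd 12% of the mean, floored at
    50) and split multinomially over the 16 sex x age cells using the fixed age
    pyramid.  Counts refer to the 12+ population (survey coverage).
    """
    if mean_pop <= 0:
        raise ValueError("mean_pop must be positive")
    rng = np.random.default_rng(seed)
    cell_p = np.concatenate([MALE_SHARE * AGE_PYRAMID, (1 - MALE_SHARE) * AGE_PYRAMID])
    for area in areas.values():
        total = max(50, int(round(rng.normal(mean_pop, 0.12 * mean_pop))))
        cells = rng.multinomial(total, cell_p)
        area.census_counts = {
            (sex, ag): int(cells[i * len(AGE_GROUPS) + j])
            for i, sex in enumerate(SEXES)
            for j, ag in enumerate(AGE_GROUPS)
        }
    return areas


def simulate_income(
    areas: dict[str, MicroArea],
    missing_fraction: float = 0.0,
    spatial_gradient: float = 0.0,
    seed: int = 0,
    base: float = 60_000.0,
    noise_sd: float = 8_000.0,
    floor: float = 10_000.0,
) -> dict[str, MicroArea]:
    """Assign median household income: base + gradient * y-coordinate + noise.

    Exactly ``floor(missing_fraction * n_areas)`` areas have their *observed*
    income suppressed (``median_income = None``); the latent value is kept in
    ``income_true`` so outcome generation is unaffected by suppression.
    """
    if not 0 <= missing_fraction < 1:
        raise ValueError("missing_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    ids = list(areas)
    for aid in ids:
        area = areas[aid]
        inc = base + spatial_gradient * area.centroid[1] + rng.normal(0.0, noise_sd)
        inc = max(floor, inc)
        area.income_true = inc
        area.median_income = inc
    n_missing = int(np.floor(missing_fraction * len(ids)))
    for aid in rng.choice(ids, size=n_missing, replace=False):
        areas[aid].median_income = None
    return areas


def sample_icar(areas: dict[str, MicroArea], sigma_u: float, seed: int) -> np.ndarray:
    """Draw a sum-to-zero spatial effect vector from the intrinsic CAR prior.

    The improper ICAR density with precision ``1/sigma_u**2`` is sampled
    exactly on the subspace orthogonal to the null space of the graph
    Laplacian ``L = D - A``: each eigenvector with eigenvalue ``lam > 0``
    receives an independent N(0, sigma_u**2 / lam) coefficient, and the result
    is recentred to sum to zero.
    """
    ids = list(areas)
    index = {a: i for i, a in enumerate(ids)}
    n = len(ids)
    lap = np.zeros((n, n))
    for aid in ids:
        i = index[aid]
        for nb in areas[aid].neighbour_ids:
            if nb in index:
                lap[i, index[nb]] -= 1.0
                lap[i, i] += 1.0
    lam, vec = np.linalg.eigh(lap)
    rng = np.random.default_rng(seed)
    keep = lam > 1e-8 * max(1.0, lam.max())
    z = rng.standard_normal(keep.sum())
    u = vec[:, keep] @ (z * sigma_u / np.sqrt(lam[keep]))
    return u - u.mean()


def make_ground_truth(
    areas: dict[str, MicroArea],
    seed: int = 0,
    intercept: float = -1.0986,
    cycle_effects: np.ndarray | None = None,
    age_effects: np.ndarray | None = None,
    income_coef: float = np.log(0.88),
    sigma_u: float = 0.25,
    sigma_v: float = 0.10,
) -> GroundTruth:
    """Generating parameters for a smoking-like outcome.

    Defaults: baseline prevalence ~25% (intercept logit(0.25)); a gentle
    decline over cycles; an age profile peaking in mid adulthood and dropping
    steeply at older ages; income odds ratio 0.88 per $10,000; modest spatial
    (sigma_u = 0.25) and unstructured (sigma_v = 0.10) heterogeneity.
    """
    if cycle_effects is None:
        cycle_effects = np.array([0.0, -0.05, -0.02, -0.10, -0.13])
    if age_effects is None:
        age_effects = np.array([-1.00, 0.25, 0.15, 0.36, 0.0, -0.50, -1.40, -2.30])
    cycle_effects = np.asarray(cycle_effects, dtype=float)
    age_effects = np.asarray(age_effects, dtype=float)
    rng = np.random.default_rng(seed)
    u = sample_icar(areas, sigma_u, seed=int(rng.integers(2**31 - 1)))
    v = rng.normal(0.0, sigma_v, size=len(areas))
    truth = GroundTruth(
        intercept=intercept,
        cycle_effects=cycle_effects,
        age_effects=age_effects,
        income_coef=income_coef,
        sigma_u=sigma_u,
        sigma_v=sigma_v,
        u=u,
        v=v,
    )
    truth.validate(len(areas))
    return truth


def _income_z(areas: dict[str, MicroArea]) -> np.ndarray:
    """Latent income per area, centred at the study mean, per $10,000."""
    vals = np.array([
        a.income_true if a.income_true is not None else np.nan for a in areas.values()
    ])
    if np.isnan(vals).all():
        return np.zeros(len(vals))
    mean = np.nanmean(vals)
    z = (vals - mean) / 10_000.0
    return np.where(np.isnan(z), 0.0, z)


def _draw_ages(rng: np.random.Generator, age_group: str, size: int) -> np.ndarray:
    lo, hi = _AGE_BOUNDS[age_group]
    return rng.integers(lo, hi + 1, size=size)


def _raw_outcome_fields(
    df: pd.DataFrame, outcome_type: str, rng: np.random.Generator,
    raw_missing_rate: float,
) -> pd.DataFrame:
    """Synthesise questionnaire fields consistent with the binary outcome."""
    n = len(df)
    y = df["y"].to_numpy()
    out = df.copy()
    if outcome_type == "current_smoking":
        resp = np.where(
            y == 1,
            np.where(rng.random(n) < 0.8, "daily", "occasional"),
            np.where(rng.random(n) < 0.3, "former", "never"),
        )
        resp = np.where(rng.random(n) < raw_missing_rate, "missing", resp)
        out["smoking_response"] = resp
        out["height_m"] = np.nan
        out["weight_kg"] = np.nan
        out["pregnant_or_lactating"] = False
    elif outcome_type == "excess_bodyweight":
        from .cohort import overweight_cutoff  # deferred: avoids import cycle

        male = (df["sex"] == "M").to_numpy()
        height = np.where(male, rng.normal(1.76, 0.07, n), rng.normal(1.63, 0.065, n))
        height = np.clip(height, 1.40, 2.10)
        cut = np.array([
            overweight_cutoff(a, s)
            for a, s in zip(df["age_years"].to_numpy(), df["sex"].to_numpy())
        ])
        bmi = np.where(
            y == 1,
            cut + 0.5 + rng.exponential(3.0, n),
            np.clip(cut - 0.5 - rng.exponential(2.0, n), 16.0, None),
        )
        out["height_m"] = np.round(height, 3)
        out["weight_kg"] = np.round(bmi * height**2, 1)
        miss = rng.random(n) < raw_missing_rate
        out.loc[miss, ["height_m", "weight_kg"]] = np.nan
        preg = (
            (~male)
            & (df["age_years"].to_numpy() >= 18)
            & (df["age_years"].to_numpy() <= 49)
            & (rng.random(n) < 0.015)
        )
        out["pregnant_or_lactating"] = preg
        out["smoking_response"] = "missing"
    else:
        raise ValueError(f"unknown outcome_type {outcome_type!r}")
    return out


def simulate_survey(
    areas: dict[str, MicroArea],
    truth: GroundTruth,
    n_cycles: int = 5,
    sampling_rate: float = 0.055,
    n_bootstrap: int = 100,
    seed: int = 0,
    outcome_type: str = "current_smoking",
    raw_missing_rate: float = 0.02,
) -> pd.DataFrame:
    """Draw pooled survey respondents across ``n_cycles`` cycles.

    Within each area x cycle x sex x age cell of the census, each person is
    included with probability ``sampling_rate * age_factor`` (capped at 1);
    the design weight is the inverse inclusion probability.  The binary
    outcome is Bernoulli with logit equal to the generating linear predictor
    plus the area's spatial and unstructured effects.  ``n_bootstrap``
    with-replacement (Rao-Wu style) replicate weights are generated within
    each cycle for design-based variance estimation.

    The returned frame carries per-respondent ``p_true`` (generating
    probability) and ``y`` alongside raw questionnaire fields; the frame's
    ``attrs['outcome_type']`` records which risk factor the raw fields encode.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if not 0 < sampling_rate <= 1:
        raise ValueError("sampling_rate must be in (0, 1]")
    truth.validate(len(areas))
    if truth.income_coef != 0.0 and all(a.income_true is None for a in areas.values()):
        raise ValueError("income effect requested but areas have no income")
    if len(truth.cycle_effects) < n_cycles:
        raise ValueError("truth.cycle_effects shorter than n_cycles")
    rng = np.random.default_rng(seed)
    inc_z = _income_z(areas)
    ids = list(areas)
    n_areas, n_ages = len(ids), len(AGE_GROUPS)
    # census cell grid (area, sex, age) broadcast over cycles
    census = np.array([
        [[areas[a].census_counts.get((sex, ag), 0) for ag in AGE_GROUPS]
         for sex in SEXES]
        for a in ids
    ])  # (J, 2, A)
    p_incl = np.minimum(1.0, sampling_rate * AGE_INCLUSION_FACTORS)  # (A,)
    m = rng.binomial(
        census[:, None, :, :], p_incl[None, None, None, :],
        size=(n_areas, n_cycles, 2, n_ages),
    )
    if m.sum() == 0:
        raise ValueError("sampling_rate yielded zero respondents")
    j_grid, c_grid, s_grid, g_grid = np.indices(m.shape)
    counts = m.ravel()
    j_idx = np.repeat(j_grid.ravel(), counts)
    c_idx = np.repeat(c_grid.ravel(), counts)
    s_idx = np.repeat(s_grid.ravel(), counts)
    g_idx = np.repeat(g_grid.ravel(), counts)
    eta = (
        truth.intercept
        + truth.cycle_effects[c_idx]
        + truth.age_effects[g_idx]
        + truth.income_coef * inc_z[j_idx]
        + truth.u[j_idx]
        + truth.v[j_idx]
    )
    p = 1.0 / (1.0 + np.exp(-eta))
    bounds = np.array([_AGE_BOUNDS[ag] for ag in AGE_GROUPS])
    ages = rng.integers(bounds[g_idx, 0], bounds[g_idx, 1] + 1)
    n_resp = len(j_idx)
    df = pd.DataFrame({
        "respondent_id": [f"R{i:07d}" for i in range(n_resp)],
        "area_id": np.array(ids, dtype=object)[j_idx],
        "sex": np.array(SEXES, dtype=object)[s_idx],
        "age_years": ages,
        "age_group": np.array(AGE_GROUPS, dtype=object)[g_idx],
        "cycle": c_idx + 1,
        "design_weight": 1.0 / p_incl[g_idx],
        "p_true": p,
        "y": rng.binomial(1, p),
    })
    df = _raw_outcome_fields(df, outcome_type, rng, raw_missing_rate)
    if n_bootstrap > 0:
        bsw = np.empty((len(df), n_bootstrap))
        w = df["design_weight"].to_numpy()
        for cycle, idx in df.groupby("cycle").indices.items():
            n_c = len(idx)
            if n_c == 1:
                bsw[idx, :] = w[idx, None]
                continue
            counts = rng.multinomial(n_c - 1, np.full(n_c, 1.0 / n_c),
                                     size=n_bootstrap).T
            bsw[idx, :] = w[idx, None] * counts * (n_c / (n_c - 1))
        df = pd.concat(
            [df, pd.DataFrame(bsw, columns=[f"bsw_{b}" for b in range(n_bootstrap)],
                              index=df.index)],
            axis=1,
        )
    df.attrs["outcome_type"] = outcome_type
    return df


def implant_cluster(
    respondents: pd.DataFrame,
    target_area_ids: set[str] | list[str],
    odds_multiplier: float,
    seed: int = 0,
    outcome_type: str | None = None,
) -> pd.DataFrame:
    """Re-draw outcomes in the target areas with multiplied odds.

    Each target-area respondent's generating probability ``p`` becomes
    ``odds_multiplier * p / (1 - p + odds_multiplier * p)``; outcomes and the
    raw questionnaire fields are re-drawn there and all other rows are
    untouched.  Used to plant a known high-prevalence cluster for testing the
    exceedance flags and the spatial scan.
    """
    target_area_ids = set(target_area_ids)
    if not target_area_ids:
        raise ValueError("target area set must be non-empty")
    if odds_multiplier <= 1:
        raise ValueError("odds_multiplier must be > 1")
    known = set(respondents["area_id"].unique())
    unknown = target_area_ids - known
    if unknown:
        raise ValueError(f"unknown area ids: {sorted(unknown)}")
    if outcome_type is None:
        outcome_type = respondents.attrs.get("outcome_type", "current_smoking")
    rng = np.random.default_rng(seed)
    out = respondents.copy()
    mask = out["area_id"].isin(target_area_ids).to_numpy()
    p = out.loc[mask, "p_true"].to_numpy()
    p_new = odds_multiplier * p / (1.0 - p + odds_multiplier * p)
    out.loc[mask, "p_true"] = p_new
    out.loc[mask, "y"] = rng.binomial(1, p_new)
    redone = _raw_outcome_fields(out.loc[mask], outcome_type, rng, 0.0)
    out.loc[mask, redone.columns] = redone
    # classification columns derived from the raw fields are now stale
    if "smoker" in out.columns or "excess_bodyweight" in out.columns:
        from .cohort import add_risk_factor_columns

        refreshed = add_risk_factor_columns(
            out.loc[mask].drop(columns=["smoker", "excess_bodyweight"],
                               errors="ignore"))
        for col in ("smoker", "excess_bodyweight"):
            if col in out.columns:
                out.loc[mask, col] = refreshed[col]
    out.attrs["outcome_type"] = outcome_type
    return out


# ---------------------------------------------------------------------------
# File formats

def write_geojson(areas: dict[str, MicroArea], path: str) -> None:
    """Write areas as a GeoJSON FeatureCollection of centroid points."""
    features = []
    for a in areas.values():
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": list(a.centroid)},
            "properties": {
                "area_id": a.area_id,
                "county_id": a.county_id,
                "median_income": a.median_income,
                "centroid_x": a.centroid[0],
                "centroid_y": a.centroid[1],
            },
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def write_adjacency_list(areas: dict[str, MicroArea], path: str) -> None:
    """One line per area: ``area_id: neighbour_id,neighbour_id,...``"""
    with open(path, "w") as fh:
        for a in areas.values():
            fh.write(f"{a.area_id}: {','.join(sorted(a.neighbour_ids))}\n")


def write_respondents_csv(respondents: pd.DataFrame, path: str) -> None:
    respondents.to_csv(path, index=False)


def write_census_csv(areas: dict[str, MicroArea], path: str) -> None:
    rows = [
        {"area_id": a.area_id, "county_id": a.county_id, "sex": sex,
         "age_group": ag, "count": n, "median_income": a.median_income}
        for a in areas.values()
        for (sex, ag), n in sorted(a.census_counts.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_params_json(params: dict, path: str) -> None:
    """Echo generation parameters to a JSON sidecar."""
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return str(o)

    with open(path, "w") as fh:
        json.dump(params, fh, indent=2, default=_default)
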