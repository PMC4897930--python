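"""Post-stratification of posterior draws and design-based comparators.

Model-based prevalence: each posterior draw gives a probability for every
(area, sex, cycle, age-band) cell via the inverse-logit of the linear
predictor.  Cells are averaged over cycles (equal weight by default; the
pooled sample's cycle shares are available as an option) and then weighted by
the census age-band counts of the area, yielding a per-draw area prevalence
whose posterior mean, sd and percentile intervals summarise the estimate.
Areas aggregate to counties and the whole region by census population
weights.

Design-based prevalence: the classical weighted proportion within a group,
with variance from the empirical variance of the bootstrap replicate-weight
estimates and a normal-approximation 95% confidence interval.  Model-based
aggregates falling inside these intervals validate the model pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bym import PosteriorDraws
from .types import AGE_GROUPS, MicroArea

__all__ = [
    "CellDraws",
    "cell_prevalence_draws",
    "poststratify_area",
    "area_prevalence_draws",
    "summarise_area_prevalence",
    "aggregate_prevalence",
    "design_based_estimate",
    "validate_model_vs_design",
]


def _invlogit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class CellDraws:
    """Per-draw cell probabilities, shape (draws, areas, cycles, age bands).

    ``available`` marks areas for which the model provides estimates (model 2
    gives none for areas with suppressed income).
    """

    probs: np.ndarray
    area_ids: list[str]
    sex: str
    n_cycles: int
    available: np.ndarray  # bool per area

    def __post_init__(self) -> None:
        avail = self.probs[:, self.available, :, :]
        if avail.size and (avail.min() < 0 or avail.max() > 1):
            raise ValueError("cell probabilities must lie in [0, 1]")


def cell_prevalence_draws(
    draws: PosteriorDraws,
    all_area_ids: list[str] | None = None,
) -> CellDraws:
    """Expand posterior draws into per-cell probability draws.

    For each saved draw s, area j, cycle c and age band a:

        p = invlogit(beta0_s + cycle_s[c] + age_s[a] + gamma_s * income_j + u_sj + v_sj)

    The income term appears only for model-2 draws.  When ``all_area_ids``
    lists areas beyond those the model retained (e.g. income-suppressed areas
    dropped by model 2), those areas are marked unavailable (NaN cells)
    rather than silently filled.
    """
    cyc = draws.cycle_effects_full()  # (S, K)
    age = draws.age_effects_full()  # (S, 8)
    area_eff = draws.u + draws.v  # (S, J)
    if draws.gamma is not None:
        area_eff = area_eff + draws.gamma[:, None] * draws.income_z[None, :]
    eta = (
        draws.beta0[:, None, None, None]
        + area_eff[:, :, None, None]
        + cyc[:, None, :, None]
        + age[:, None, None, :]
    )
    probs = _invlogit(eta)
    area_ids = list(draws.area_ids)
    available = np.ones(len(area_ids), dtype=bool)
    if all_area_ids is not None:
        modelled = {a: i for i, a in enumerate(area_ids)}
        full = np.full((draws.n_draws, len(all_area_ids)) + probs.shape[2:], np.nan)
        available = np.zeros(len(all_area_ids), dtype=bool)
        for i, aid in enumerate(all_area_ids):
            if aid in modelled:
                full[:, i] = probs[:, modelled[aid]]
                available[i] = True
        probs, area_ids = full, list(all_area_ids)
    return CellDraws(
        probs=probs,
        area_ids=area_ids,
        sex=draws.spec.sex_stratum,
        n_cycles=draws.n_cycles,
        available=available,
    )


def poststratify_area(
    cell_probs: np.ndarray,
    census_counts: np.ndarray,
    cycle_weights: np.ndarray | None = None,
) -> np.ndarray:
    """Collapse one area's cell draws (draws, cycles, age bands) to per-draw
    prevalence.

    Cells are first averaged over cycles (equal weights unless
    ``cycle_weights`` is given), then weighted by the census age-band counts:
    ``prev = sum_a N_a p_a / sum_a N_a``.
    """
    census_counts = np.asarray(census_counts, dtype=float)
    if census_counts.sum() <= 0:
        raise ValueError("area has zero census population")
    if cell_probs.shape[-1] != len(census_counts):
        raise ValueError("census counts must cover every age band used")
    if cycle_weights is None:
        by_age = cell_probs.mean(axis=1)
    else:
        cw = np.asarray(cycle_weights, dtype=float)
        cw = cw / cw.sum()
        by_age = np.tensordot(cell_probs, cw, axes=([1], [0]))
    return by_age @ census_counts / census_counts.sum()


def area_prevalence_draws(
    cells: CellDraws,
    areas: dict[str, MicroArea],
    cycle_weights: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-draw post-stratified prevalence for every available area.

    Returns a frame indexed by draw with one column per area id.
    """
    cols = {}
    for i, aid in enumerate(cells.area_ids):
        if not cells.available[i]:
            continue
        counts = np.array([
            areas[aid].census_counts.get((cells.sex, ag), 0) for ag in AGE_GROUPS
        ], dtype=float)
        cols[aid] = poststratify_area(cells.probs[:, i], counts, cycle_weights)
    return pd.DataFrame(cols)


def summarise_area_prevalence(area_draws: pd.DataFrame) -> pd.DataFrame:
    """Posterior mean, sd and central 50%/95% intervals per area."""
    q = area_draws.quantile([0.025, 0.25, 0.75, 0.975])
    return pd.DataFrame({
        "posterior_mean": area_draws.mean(),
        "posterior_sd": area_draws.std(ddof=1),
        "ci95_low": q.loc[0.025],
        "ci25": q.loc[0.25],
        "ci75": q.loc[0.75],
        "ci95_high": q.loc[0.975],
    }).rename_axis("area_id")


def aggregate_prevalence(
    area_draws: pd.DataFrame,
    areas: dict[str, MicroArea],
    grouping: str = "county",
    sex: str | None = None,
) -> pd.DataFrame:
    """Population-weighted prevalence draws aggregated to counties or region.

    ``grouping`` is ``"county"`` (per county_id) or ``"region"`` (everything
    in one group).  Census populations (of the modelled sex when given) are
    the weights.  Returns mean and central 95% interval per group, plus the
    per-draw group prevalences in the ``draws`` column (arrays).
    """
    if grouping not in ("county", "region"):
        raise ValueError(f"unknown grouping {grouping!r}")
    groups: dict[str, list[str]] = {}
    for aid in area_draws.columns:
        key = areas[aid].county_id if grouping == "county" else "region"
        groups.setdefault(key, []).append(aid)
    rows = []
    for key, ids in sorted(groups.items()):
        if not ids:
            raise ValueError(f"empty group {key}")
        pops = np.array([areas[a].population(sex) for a in ids], dtype=float)
        if pops.sum() <= 0:
            raise ValueError(f"group {key} has zero population")
        gdraws = area_draws[ids].to_numpy() @ (pops / pops.sum())
        rows.append({
            "group": key,
            "mean": float(gdraws.mean()),
            "ci95_low": float(np.quantile(gdraws, 0.025)),
            "ci95_high": float(np.quantile(gdraws, 0.975)),
            "draws": gdraws,
        })
    return pd.DataFrame(rows).set_index("group")


def design_based_estimate(
    respondents: pd.DataFrame,
    outcome_col: str,
    grouping_col: str | None = None,
    weight_col: str = "design_weight",
) -> pd.DataFrame:
    """Survey-weighted prevalence with bootstrap replicate-weight variance.

    The point estimate within a group is ``sum(w y) / sum(w)`` over
    respondents with a 0/1 outcome; the variance is the mean squared
    deviation of the replicate-weight estimates around the point estimate,
    giving a normal-approximation 95% CI.  Weights are expected to be pooled
    (rescaled) when cycles are combined.
    """
    df = respondents[respondents[outcome_col].isin([0, 1])].copy()
    df["_y"] = df[outcome_col].astype(float)
    bsw_cols = [c for c in df.columns if c.startswith("bsw_")]
    if grouping_col is None:
        df["_grp"] = "all"
        grouping_col = "_grp"
    rows = []
    for key, sub in df.groupby(grouping_col):
        w = sub[weight_col].to_numpy()
        if w.sum() <= 0:
            raise ValueError(f"group {key} has zero weight")
        y = sub["_y"].to_numpy()
        est = float(w @ y / w.sum())
        if bsw_cols:
            bw = sub[bsw_cols].to_numpy()
            totals = bw.sum(axis=0)
            reps = np.where(totals > 0, (y @ bw) / np.where(totals > 0, totals, 1.0), est)
            var = float(np.mean((reps - est) ** 2))
        else:
            var = np.nan
        se = np.sqrt(var)
        rows.append({
            "group": key,
            "estimate": est,
            "se": se,
            "ci95_low": est - 1.96 * se,
            "ci95_high": est + 1.96 * se,
            "n": len(sub),
        })
    return pd.DataFrame(rows).set_index("group")


def validate_model_vs_design(
    model_summary: pd.DataFrame,
    design_summary: pd.DataFrame,
) -> pd.DataFrame:
    """Check whether model posterior means fall inside design-based 95% CIs.

    Both frames are indexed by group; the model frame needs a ``mean``
    column, the design frame ``ci95_low``/``ci95_high``.  Returns per-group
    booleans plus an ``overall_coverage`` attribute (fraction covered).
    """
    if set(model_summary.index) != set(design_summary.index):
        raise ValueError("model and design summaries cover different groups")
    rows = []
    for g in model_summary.index:
        m = float(model_summary.loc[g, "mean"])
        lo = float(design_summary.loc[g, "ci95_low"])
        hi = float(design_summary.loc[g, "ci95_high"])
        rows.append({"group": g, "model_mean": m, "design_ci95_low": lo,
                     "design_ci95_high": hi, "covered": lo <= m <= hi})
    out = pd.DataFrame(rows).set_index("group")
    out.attrs["overall_coverage"] = float(out["covered"].mean())
    return out
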