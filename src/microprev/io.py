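"""Readers for the package's plain-text interchange formats.

Counterparts to the writers in :mod:`microprev.synthetic`: census cell CSV,
adjacency-list file, GeoJSON centroid/polygon files and respondent CSV.
"""

from __future__ import annotations

import json

import pandas as pd

from .spatial import queen_contiguity_from_geojson, read_adjacency_list
from .types import MicroArea

__all__ = ["load_areas", "load_respondents", "load_draws"]


def load_areas(
    census_csv: str,
    adjacency_path: str | None = None,
    geojson_path: str | None = None,
) -> dict[str, MicroArea]:
    """Rebuild areas from a census CSV plus adjacency (list file or GeoJSON).

    The census CSV needs columns ``area_id, county_id, sex, age_group,
    count, median_income``.  Neighbours come from the adjacency-list file
    when given, otherwise from queen contiguity of GeoJSON polygons;
    centroids come from GeoJSON point coordinates or ``centroid_x``/``_y``
    properties when a GeoJSON file is supplied.
    """
    df = pd.read_csv(census_csv)
    areas: dict[str, MicroArea] = {}
    for aid, sub in df.groupby("area_id", sort=False):
        inc = sub["median_income"].iloc[0]
        areas[str(aid)] = MicroArea(
            area_id=str(aid),
            centroid=(0.0, 0.0),
            county_id=str(sub["county_id"].iloc[0]),
            median_income=None if pd.isna(inc) else float(inc),
            income_true=None if pd.isna(inc) else float(inc),
            census_counts={
                (r.sex, r.age_group): int(r.count_)
                for r in sub.rename(columns={"count": "count_"}).itertuples()
            },
        )
    if adjacency_path is not None:
        neigh = read_adjacency_list(adjacency_path)
    elif geojson_path is not None:
        neigh = queen_contiguity_from_geojson(geojson_path)
    else:
        neigh = {}
    for aid, nbs in neigh.items():
        if aid in areas:
            areas[aid].neighbour_ids = {n for n in nbs if n in areas}
    if geojson_path is not None:
        with open(geojson_path) as fh:
            gj = json.load(fh)
        for feat in gj["features"]:
            props = feat.get("properties", {})
            aid = str(props.get("area_id"))
            if aid not in areas:
                continue
            if feat["geometry"]["type"] == "Point":
                areas[aid].centroid = tuple(feat["geometry"]["coordinates"][:2])
            elif "centroid_x" in props:
                areas[aid].centroid = (props["centroid_x"], props["centroid_y"])
    return areas


def load_respondents(path: str, outcome_type: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    if outcome_type is not None:
        df.attrs["outcome_type"] = outcome_type
    return df


def load_draws(csv_path: str, meta_path: str):
    """Reload saved posterior draws (CSV + JSON metadata)."""
    import numpy as np

    from .bym import MCMCConfig, ModelSpec, PosteriorDraws
    from .types import AGE_GROUPS, REFERENCE_AGE_INDEX

    df = pd.read_csv(csv_path)
    with open(meta_path) as fh:
        meta = json.load(fh)
    spec = ModelSpec(**meta["spec"])
    config = MCMCConfig(**meta["config"])
    area_ids = meta["area_ids"]
    age_cols = [f"age_{AGE_GROUPS[i]}" for i in range(len(AGE_GROUPS))
                if i != REFERENCE_AGE_INDEX]
    cyc_cols = sorted(
        (c for c in df.columns if c.startswith("cycle_")),
        key=lambda c: int(c.split("_")[1]),
    )
    return PosteriorDraws(
        beta0=df["beta0"].to_numpy(),
        cycle=df[cyc_cols].to_numpy() if cyc_cols else None,
        trend_slope=df["trend_slope"].to_numpy() if "trend_slope" in df else None,
        age=df[age_cols].to_numpy(),
        gamma=df["gamma"].to_numpy() if "gamma" in df else None,
        u=df[[f"u_{a}" for a in area_ids]].to_numpy(),
        v=df[[f"v_{a}" for a in area_ids]].to_numpy(),
        sigma_u=df["sigma_u"].to_numpy(),
        sigma_v=df["sigma_v"].to_numpy(),
        deviance=df["deviance"].to_numpy(),
        chain=df["chain"].to_numpy(dtype=int),
        spec=spec,
        config=config,
        area_ids=area_ids,
        income_z=None if meta["income_z"] is None else np.asarray(meta["income_z"]),
        n_cycles=meta["n_cycles"],
        fingerprint=meta["fingerprint"],
    )
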