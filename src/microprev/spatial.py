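"""Adjacency graph construction and spatial-autocorrelation testing.

The neighbourhood structure drives the intrinsic CAR term of the hierarchical
model; isolated areas (islands) are removed up front because an area with no
neighbours cannot borrow strength and would receive an unsmoothed estimate.

A preliminary check for spatial clustering of the raw area-level counts uses
Moran's I on observed-minus-expected residuals with a parametric bootstrap
null: replicate count vectors are simulated from a negative binomial with the
areas' expected counts as means and a common dispersion fitted to the
observed counts by the method of moments (falling back to Poisson when the
observed counts are underdispersed), which avoids relying on the asymptotic
normal null distribution.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .types import MicroArea

__all__ = [
    "AdjacencyGraph",
    "MoranResult",
    "build_adjacency",
    "morans_i",
    "morans_i_bootstrap_test",
    "observed_expected_counts",
    "read_adjacency_list",
    "queen_contiguity_from_geojson",
]

logger = logging.getLogger(__name__)


@dataclass
class AdjacencyGraph:
    """Symmetric binary adjacency over an ordered list of retained areas."""

    area_ids: list[str]
    edges: set[frozenset] = field(default_factory=set)
    weights_style: str = "binary"
    removed_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.index = {a: i for i, a in enumerate(self.area_ids)}
        for e in self.edges:
            if len(e) != 2:
                raise ValueError(f"self-edge or malformed edge {set(e)}")

    @property
    def n(self) -> int:
        return len(self.area_ids)

    def degree(self) -> np.ndarray:
        d = np.zeros(self.n, dtype=int)
        for e in self.edges:
            i, j = (self.index[a] for a in e)
            d[i] += 1
            d[j] += 1
        return d

    def weight_matrix(self) -> sp.csr_matrix:
        """Sparse symmetric weight matrix (binary or row-standardised)."""
        rows, cols = [], []
        for e in self.edges:
            i, j = (self.index[a] for a in e)
            rows += [i, j]
            cols += [j, i]
        w = sp.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(self.n, self.n)
        )
        if self.weights_style == "row_standardized":
            deg = np.asarray(w.sum(axis=1)).ravel()
            deg[deg == 0] = 1.0
            w = sp.diags(1.0 / deg) @ w
        return w

    def neighbour_pairs(self) -> list[tuple[int, int]]:
        """Unique undirected edges as index pairs (i < j)."""
        return sorted(
            tuple(sorted((self.index[a], self.index[b])))
            for a, b in (tuple(e) for e in self.edges)
        )

    def is_connected(self) -> bool:
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(self.neighbour_pairs())
        return nx.is_connected(g) if self.n > 0 else False


@dataclass
class MoranResult:
    I: float
    p_value: float
    n_sim: int
    observed: np.ndarray
    expected: np.ndarray
    simulated_i: np.ndarray
    used_poisson_fallback: bool = False


def build_adjacency(
    areas: dict[str, MicroArea],
    weights_style: str = "binary",
) -> AdjacencyGraph:
    """Symmetrise the area neighbour lists and drop isolated areas.

    Islands (degree 0 after symmetrisation, e.g. a lone offshore area) are
    removed and recorded in ``removed_ids``; duplicate and one-directional
    neighbour declarations are cleaned up.  Raises if fewer than 2 areas
    remain or every area is isolated.
    """
    if len(areas) < 2:
        raise ValueError("need at least 2 areas")
    ids = list(areas)
    edges: set[frozenset] = set()
    for aid, area in areas.items():
        for nb in area.neighbour_ids:
            if nb == aid:
                continue
            if nb in areas:
                edges.add(frozenset((aid, nb)))
    touched = {a for e in edges for a in e}
    removed = [a for a in ids if a not in touched]
    if len(removed) == len(ids):
        raise ValueError("all areas are isolated; no adjacency structure")
    for aid in removed:
        logger.info("removing island area %s (no neighbours)", aid)
    kept = [a for a in ids if a in touched]
    return AdjacencyGraph(
        area_ids=kept, edges=edges, weights_style=weights_style,
        removed_ids=removed,
    )


def morans_i(
    values_obs: np.ndarray,
    values_exp: np.ndarray,
    graph: AdjacencyGraph,
) -> float:
    """Moran's I of the residuals ``z = obs - exp`` on the graph's weights.

    ``I = (n / S0) * (sum_ij w_ij z_i z_j) / (sum_i z_i**2)`` with S0 the sum
    of all weights.  Undefined (raises) when the residuals are constant.
    """
    z = np.asarray(values_obs, dtype=float) - np.asarray(values_exp, dtype=float)
    if len(z) != graph.n:
        raise ValueError("value vectors must match the graph's areas")
    if np.var(z) == 0:
        raise ValueError("Moran's I undefined: residuals have zero variance")
    w = graph.weight_matrix()
    s0 = w.sum()
    return float(graph.n / s0 * (z @ (w @ z)) / (z @ z))


def _moran_many(z_mat: np.ndarray, graph: AdjacencyGraph) -> np.ndarray:
    """Moran's I for each column of a residual matrix (vectorised)."""
    w = graph.weight_matrix()
    s0 = w.sum()
    num = np.einsum("is,is->s", z_mat, w @ z_mat)
    den = np.einsum("is,is->s", z_mat, z_mat)
    den = np.where(den == 0, np.nan, den)
    return graph.n / s0 * num / den


def morans_i_bootstrap_test(
    obs: np.ndarray,
    exp: np.ndarray,
    graph: AdjacencyGraph,
    n_sim: int = 999,
    seed: int = 0,
) -> MoranResult:
    """One-tailed parametric-bootstrap test for positive spatial clustering.

    Simulates ``n_sim`` replicate count vectors with the expected counts as
    means: negative binomial with a common method-of-moments dispersion from
    the observed counts, or Poisson when the observed counts show no
    overdispersion (logged).  ``p = (1 + #{I_sim >= I_obs}) / (n_sim + 1)``.
    """
    obs = np.asarray(obs, dtype=float)
    exp = np.asarray(exp, dtype=float)
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    if (obs < 0).any() or (exp < 0).any():
        raise ValueError("counts must be non-negative")
    i_obs = morans_i(obs, exp, graph)
    rng = np.random.default_rng(seed)
    m = obs.mean()
    s2 = obs.var(ddof=1)
    fallback = s2 <= m
    if fallback:
        logger.info(
            "observed counts underdispersed (var %.3g <= mean %.3g); "
            "simulating from Poisson", s2, m,
        )
        sims = rng.poisson(exp[:, None], size=(len(exp), n_sim)).astype(float)
    else:
        size = m**2 / (s2 - m)  # NB dispersion by method of moments
        p_nb = size / (size + exp)
        sims = rng.negative_binomial(
            size, p_nb[:, None], size=(len(exp), n_sim)
        ).astype(float)
    i_sim = _moran_many(sims - exp[:, None], graph)
    i_sim = i_sim[np.isfinite(i_sim)]
    p = (1 + int(np.sum(i_sim >= i_obs))) / (n_sim + 1)
    return MoranResult(
        I=i_obs, p_value=p, n_sim=n_sim, observed=obs, expected=exp,
        simulated_i=i_sim, used_poisson_fallback=bool(fallback),
    )


def observed_expected_counts(
    respondents, graph: AdjacencyGraph, outcome_col: str = "y",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-area observed case counts and expected counts.

    Expected counts are the overall study-area proportion of cases times each
    area's respondent total (unweighted), aligned to the graph's area order.
    """
    sub = respondents[respondents[outcome_col].isin([0, 1])]
    cases = sub.groupby("area_id")[outcome_col].sum()
    totals = sub.groupby("area_id")[outcome_col].count()
    obs = np.array([float(cases.get(a, 0)) for a in graph.area_ids])
    tot = np.array([float(totals.get(a, 0)) for a in graph.area_ids])
    overall = obs.sum() / tot.sum()
    return obs, overall * tot


def read_adjacency_list(path: str) -> dict[str, set[str]]:
    """Parse ``area_id: n1,n2,...`` lines into a neighbour mapping."""
    neigh: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            aid, _, rest = line.partition(":")
            neigh[aid.strip()] = {
                t.strip() for t in rest.split(",") if t.strip()
            }
    return neigh


def queen_contiguity_from_geojson(path: str) -> dict[str, set[str]]:
    """Queen contiguity (any shared boundary point) from GeoJSON polygons."""
    from shapely.geometry import shape

    with open(path) as fh:
        gj = json.load(fh)
    geoms = {}
    for feat in gj["features"]:
        if feat["geometry"]["type"] not in ("Polygon", "MultiPolygon"):
            continue
        geoms[feat["properties"]["area_id"]] = shape(feat["geometry"])
    ids = list(geoms)
    neigh = {a: set() for a in ids}
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if geoms[a].intersects(geoms[b]) and not geoms[a].equals(geoms[b]):
                neigh[a].add(b)
                neigh[b].add(a)
    return neigh
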