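"""Bernoulli spatial scan statistic with elliptical windows.

An independent corroboration of areas flagged by the model: candidate
elliptical windows are grown around each point over a grid of shapes (axis
ratios) and orientations, each window's excess of cases is scored by the
Bernoulli log-likelihood ratio (one-sided, high-rate), and significance
comes from Monte-Carlo replicates that redistribute the observed number of
cases at random over the population (the conditional Bernoulli null).
Window size is capped at a fraction (default 10%) of the population at risk.

Points may be individual respondents (one case/control each) or area
centroids carrying aggregated case and population counts; the two are
equivalent under the conditional null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import xlogy

__all__ = [
    "ScanCluster",
    "ScanResult",
    "enumerate_elliptic_windows",
    "bernoulli_llr",
    "scan_test",
    "DEFAULT_SHAPES",
    "DEFAULT_ANGLES",
]

DEFAULT_SHAPES: tuple[float, ...] = (1.0, 1.5, 2.0, 3.0, 4.0, 5.0)
#: 12 evenly spaced orientations over a half-turn (ellipses are symmetric).
DEFAULT_ANGLES: tuple[float, ...] = tuple(np.arange(12) * 15.0)


@dataclass
class ScanCluster:
    """One elliptical window and its evidence of elevated prevalence."""

    centre: tuple[float, float]
    semi_axes: tuple[float, float]  # (a, b), a >= b
    angle: float  # degrees, major axis orientation
    member_ids: tuple
    cases_in: float
    total_in: float
    llr: float
    rank: int
    p_value: float


@dataclass
class ScanResult:
    clusters: list[ScanCluster]
    max_llr: float
    n_mc: int
    replicate_max: np.ndarray

    @property
    def most_likely(self) -> ScanCluster | None:
        return self.clusters[0] if self.clusters else None


@dataclass
class _WindowSet:
    members: np.ndarray  # bool (n_windows, n_points)
    centre_idx: np.ndarray
    shape: np.ndarray
    angle: np.ndarray
    radius: np.ndarray  # covering elliptical distance


def _normalise_points(points: pd.DataFrame) -> pd.DataFrame:
    df = points.copy()
    if "cases" not in df.columns:
        if "outcome" not in df.columns:
            raise ValueError("points need an 'outcome' or 'cases' column")
        df["cases"] = df["outcome"].astype(float)
        df["total"] = 1.0
    if "total" not in df.columns:
        df["total"] = 1.0
    if "id" not in df.columns:
        df["id"] = np.arange(len(df))
    bad = (df["cases"] < 0) | (df["cases"] > df["total"])
    if bad.any():
        raise ValueError("cases must satisfy 0 <= cases <= total")
    return df


def enumerate_elliptic_windows(
    points: pd.DataFrame,
    max_pop_fraction: float = 0.10,
    shapes: tuple[float, ...] = DEFAULT_SHAPES,
    angles: tuple[float, ...] = DEFAULT_ANGLES,
) -> _WindowSet:
    """Candidate windows: nested elliptical neighbourhoods of every point.

    For each centre, axis ratio and orientation, points are absorbed one at a
    time in order of elliptical distance (major axis along the orientation;
    ratio 1 reduces to circles) until the next point would push the window's
    population beyond ``floor(max_pop_fraction * N)``.  Windows with
    identical member sets are deduplicated (first parameterisation kept).
    """
    if max_pop_fraction <= 0 or max_pop_fraction > 1:
        raise ValueError("max_pop_fraction must be in (0, 1]")
    df = _normalise_points(points)
    npts = len(df)
    if npts < 2:
        raise ValueError("need at least 2 points")
    if any(s < 1 for s in shapes):
        raise ValueError("axis ratios must be >= 1")
    x = df["x"].to_numpy(dtype=float)
    y = df["y"].to_numpy(dtype=float)
    totals = df["total"].to_numpy(dtype=float)
    cap = np.floor(max_pop_fraction * totals.sum())
    seen: dict[frozenset, int] = {}
    members_list: list[np.ndarray] = []
    meta: list[tuple[int, float, float, float]] = []
    for ci in range(npts):
        dx = x - x[ci]
        dy = y - y[ci]
        for ratio in shapes:
            n_angles = 1 if ratio == 1.0 else len(angles)
            for ang in angles[:n_angles]:
                th = np.deg2rad(ang)
                dxr = np.cos(th) * dx + np.sin(th) * dy
                dyr = -np.sin(th) * dx + np.cos(th) * dy
                dist = np.sqrt((dxr / ratio) ** 2 + dyr**2)
                order = np.argsort(dist, kind="stable")
                # points at exactly tied distance enter together: every
                # window must be realisable as an ellipse
                mask = np.zeros(npts, dtype=bool)
                cum = 0.0
                i = 0
                while i < npts:
                    d0 = dist[order[i]]
                    k = i
                    while k < npts and dist[order[k]] == d0:
                        k += 1
                    group = order[i:k]
                    cum += totals[group].sum()
                    if cum > cap:
                        break
                    mask[group] = True
                    i = k
                    key = frozenset(np.flatnonzero(mask))
                    if key in seen:
                        continue
                    seen[key] = len(members_list)
                    members_list.append(mask.copy())
                    meta.append((ci, ratio, ang, float(d0)))
    if not members_list:
        raise ValueError("population cap admits no windows")
    meta_arr = np.array(meta, dtype=float)
    return _WindowSet(
        members=np.array(members_list),
        centre_idx=meta_arr[:, 0].astype(int),
        shape=meta_arr[:, 1],
        angle=meta_arr[:, 2],
        radius=meta_arr[:, 3],
    )


def bernoulli_llr(c: float, n: float, C: float, N: float) -> float:
    """One-sided (high-rate) Bernoulli scan log-likelihood ratio.

    Zero when the in-window rate does not exceed the overall rate, and by
    convention when the window is the whole population.  Uses the 0*log(0)=0
    convention throughout.
    """
    if not (0 <= c <= n <= N and c <= C <= N):
        raise ValueError("need 0 <= c <= n <= N and c <= C <= N")
    return float(_llr_many(np.array([c]), np.array([n]), C, N)[0])


def _llr_many(c: np.ndarray, n: np.ndarray, C: float, N: float) -> np.ndarray:
    """Vectorised Bernoulli LLR; zero where c/n <= C/N or n == N."""
    with np.errstate(divide="ignore", invalid="ignore"):
        inside = (
            xlogy(c, c) - xlogy(c, n)
            + xlogy(n - c, n - c) - xlogy(n - c, n)
        )
        n_out = N - n
        c_out = C - c
        outside = (
            xlogy(c_out, c_out) - xlogy(c_out, n_out)
            + xlogy(n_out - c_out, n_out - c_out) - xlogy(n_out - c_out, n_out)
        )
        null = xlogy(C, C / N) + xlogy(N - C, (N - C) / N)
    llr = inside + outside - null
    high = (c * N > C * n) & (n < N)
    return np.where(high, np.maximum(llr, 0.0), 0.0)


def scan_test(
    points: pd.DataFrame,
    windows: _WindowSet | None = None,
    n_mc: int = 999,
    seed: int = 0,
    max_pop_fraction: float = 0.10,
    shapes: tuple[float, ...] = DEFAULT_SHAPES,
    angles: tuple[float, ...] = DEFAULT_ANGLES,
    max_clusters: int = 5,
    mc_batch: int = 64,
) -> ScanResult:
    """Scan for high-prevalence clusters with Monte-Carlo inference.

    The observed maximum LLR over all candidate windows is referred to the
    distribution of replicate maxima obtained by redistributing the C cases
    at random over the population (multivariate hypergeometric over point
    populations, i.e. a permutation of case labels for unit points);
    ``p = (1 + #{replicate max >= observed}) / (n_mc + 1)``.  Secondary
    clusters are reported greedily after removing overlaps with
    higher-ranked clusters, each scored against the same replicate-max
    distribution.
    """
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    df = _normalise_points(points)
    cases = df["cases"].to_numpy(dtype=float)
    totals = df["total"].to_numpy(dtype=float)
    C = float(cases.sum())
    N = float(totals.sum())
    if C == 0 or C == N:
        raise ValueError("scan undefined: no cases or no controls")
    if windows is None:
        windows = enumerate_elliptic_windows(
            df, max_pop_fraction=max_pop_fraction, shapes=shapes, angles=angles
        )
    w = windows.members.astype(float)
    n_in = w @ totals
    c_in = w @ cases
    llr_obs = _llr_many(c_in, n_in, C, N)

    rng = np.random.default_rng(seed)
    colors = totals.astype(int)
    if not np.allclose(colors, totals):
        raise ValueError("point populations must be integers")
    rep_max = np.empty(n_mc)
    done = 0
    while done < n_mc:
        b = min(mc_batch, n_mc - done)
        reps = np.stack([
            rng.multivariate_hypergeometric(colors, int(C)) for _ in range(b)
        ], axis=1).astype(float)  # (n_points, b)
        c_rep = w @ reps  # (n_windows, b)
        llr_rep = _llr_many(c_rep, n_in[:, None], C, N)
        rep_max[done:done + b] = llr_rep.max(axis=0)
        done += b

    ids = df["id"].to_numpy()
    xs = df["x"].to_numpy(dtype=float)
    ys = df["y"].to_numpy(dtype=float)
    order = np.argsort(-llr_obs, kind="stable")
    clusters: list[ScanCluster] = []
    used = np.zeros(len(cases), dtype=bool)
    for wi in order:
        if llr_obs[wi] <= 0 or len(clusters) >= max_clusters:
            break
        mask = windows.members[wi]
        if (mask & used).any():
            continue
        used |= mask
        p = (1 + int(np.sum(rep_max >= llr_obs[wi]))) / (n_mc + 1)
        ci = windows.centre_idx[wi]
        r = windows.shape[wi]
        d = windows.radius[wi]
        clusters.append(ScanCluster(
            centre=(float(xs[ci]), float(ys[ci])),
            semi_axes=(float(r * d), float(d)),
            angle=float(windows.angle[wi]),
            member_ids=tuple(ids[mask]),
            cases_in=float(c_in[wi]),
            total_in=float(n_in[wi]),
            llr=float(llr_obs[wi]),
            rank=len(clusters) + 1,
            p_value=p,
        ))
    return ScanResult(
        clusters=clusters,
        max_llr=float(llr_obs.max()),
        n_mc=n_mc,
        replicate_max=rep_max,
    )
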