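"""Sex-stratified hierarchical Bayesian logistic model with BYM area effects.

The outcome of respondent *i* in area *j(i)* is Bernoulli with

    logit p_i = b0 + b_cycle[c_i] + b_age[a_i] + gamma * income_{j(i)} + u_{j(i)} + v_{j(i)}

where ``u`` carries an intrinsic CAR (ICAR) prior over the adjacency graph
(pairwise-difference form, identified by a sum-to-zero constraint) and ``v``
is an exchangeable normal effect.  Fixed effects get vague normal(0, 10)
priors; the random-effect scales get either gamma hyperpriors on the
precisions or uniform hyperpriors on the standard deviations (both arms are
run for prior-sensitivity checks).  Model 1 omits the area income covariate;
model 2 includes it (per $10,000, centred at the study mean) and drops areas
whose census income is suppressed.

Inference is Metropolis-within-Gibbs.  Respondents are aggregated to
(area, cycle, age-band) binomial cells, which leaves the likelihood exact
while making each sweep a handful of vectorised passes: scalar random-walk
updates for the fixed effects, simultaneous per-area proposals for ``u``
accepted colour-class by colour-class (areas of one colour are mutually
non-adjacent, so their ICAR full conditionals do not interact) and in one
block for ``v``, conjugate draws for the precisions, and a sum-to-zero
re-centring of ``u`` each sweep with a compensating intercept shift.
Proposal scales adapt toward ~44% acceptance during burn-in and are frozen
afterwards.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .spatial import AdjacencyGraph, build_adjacency
from .types import AGE_GROUPS, REFERENCE_AGE_INDEX

__all__ = [
    "ModelSpec",
    "MCMCConfig",
    "CellData",
    "PosteriorDraws",
    "DicResult",
    "build_cell_data",
    "log_posterior",
    "fit_bym",
    "convergence_diagnostics",
    "split_rhat",
    "autocorrelation",
    "dic",
    "compare_models_dic",
    "prior_sensitivity",
]

OUTCOME_COLUMNS = {"current_smoking": "smoker", "excess_bodyweight": "excess_bodyweight"}


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: outcome, stratum, covariates, coding and hyperpriors."""

    outcome: str = "current_smoking"
    sex_stratum: str = "M"
    include_income: bool = False  # False: model 1, True: model 2
    cycle_coding: str = "categorical"  # or "integer_trend"
    prior_family: str = "gamma_precision"  # or "uniform_sd"
    prior_hyperparameters: dict = field(default_factory=dict)
    income_scale: float = 10_000.0

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOME_COLUMNS:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.sex_stratum not in ("M", "F"):
            raise ValueError("sex_stratum must be 'M' or 'F'")
        if self.cycle_coding not in ("categorical", "integer_trend"):
            raise ValueError(f"unknown cycle coding {self.cycle_coding!r}")
        if self.prior_family not in ("gamma_precision", "uniform_sd"):
            raise ValueError(f"unknown prior family {self.prior_family!r}")
        if self.income_scale <= 0:
            raise ValueError("income_scale must be positive")

    def hyper(self, name: str) -> float:
        defaults = {"gamma_shape": 0.5, "gamma_rate": 0.0005,
                    "uniform_upper": 10.0, "fixed_effect_sd": 10.0}
        return float(self.prior_hyperparameters.get(name, defaults[name]))


@dataclass(frozen=True)
class MCMCConfig:
    """Chain layout.  ``n_saved_draws`` = n_chains * n_keep_iterations / thin."""

    n_chains: int = 3
    burn_in: int = 2_000
    n_keep_iterations: int = 2_000
    thin: int = 2
    seed: int = 0
    proposal_scales: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("need >= 2 chains for convergence diagnostics")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_keep_iterations % self.thin:
            raise ValueError("n_keep_iterations must be divisible by thin")

    @property
    def n_saved_draws(self) -> int:
        return self.n_chains * (self.n_keep_iterations // self.thin)

    @classmethod
    def desk_preset(cls, seed: int = 0) -> "MCMCConfig":
        """Workstation-scale default: 3 chains x (2,000 burn-in + 2,000 kept, thin 2)."""
        return cls(n_chains=3, burn_in=2_000, n_keep_iterations=2_000, thin=2, seed=seed)

    @classmethod
    def production_preset(cls, seed: int = 0) -> "MCMCConfig":
        """Production protocol: 3 chains, 500,000 burn-in, 50,000 further
        iterations with every 10th saved (15,000 saved draws in total)."""
        return cls(n_chains=3, burn_in=500_000, n_keep_iterations=50_000, thin=10,
                   seed=seed)


@dataclass
class CellData:
    """Respondents aggregated to (area, cycle, age-band) binomial cells."""

    y: np.ndarray
    n: np.ndarray
    area_idx: np.ndarray
    cycle_idx: np.ndarray  # 0-based
    age_idx: np.ndarray
    n_cycles: int
    graph: AdjacencyGraph
    area_ids: list[str]
    income_z: np.ndarray | None  # per area, centred, per income_scale
    dropped_area_ids: list[str]
    fingerprint: str
    sex: str = ""
    outcome: str = ""

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)


def _outcome_values(respondents: pd.DataFrame, spec: ModelSpec) -> pd.Series:
    col = OUTCOME_COLUMNS[spec.outcome]
    if col not in respondents.columns:
        col = "y"  # generator's raw binary outcome
    return respondents[col]


def build_cell_data(
    respondents: pd.DataFrame,
    areas: dict,
    spec: ModelSpec,
) -> CellData:
    """Aggregate one sex stratum's respondents into binomial model cells.

    Classification states other than 0/1 (missing, excluded) are dropped with
    their records intact upstream.  For model 2, areas with suppressed income
    are removed (recorded in ``dropped_area_ids``) together with their
    respondents, and the adjacency graph is rebuilt on the remainder.
    """
    df = respondents[respondents["sex"] == spec.sex_stratum].copy()
    df["_out"] = _outcome_values(df, spec)
    df = df[df["_out"].isin([0, 1])]
    df["_out"] = df["_out"].astype(int)
    fingerprint = hashlib.sha1(
        f"{spec.outcome}|{spec.sex_stratum}|{len(df)}|{int(df['_out'].sum())}".encode()
    ).hexdigest()[:16]

    kept_areas = dict(areas)
    dropped: list[str] = []
    if spec.include_income:
        dropped = [a for a, ar in areas.items() if ar.median_income is None]
        for a in dropped:
            kept_areas.pop(a)
        if not kept_areas:
            raise ValueError("no areas with observed income")
    graph = build_adjacency(kept_areas)
    dropped += graph.removed_ids
    area_ids = graph.area_ids
    aindex = {a: i for i, a in enumerate(area_ids)}
    df = df[df["area_id"].isin(aindex)]
    if df.empty:
        raise ValueError("no respondents left after filtering")

    income_z = None
    if spec.include_income:
        inc = np.array([areas[a].median_income for a in area_ids], dtype=float)
        income_z = (inc - inc.mean()) / spec.income_scale

    n_cycles = int(df["cycle"].max())
    grp = df.groupby(["area_id", "cycle", "age_group"], observed=True)["_out"]
    agg = grp.agg(["sum", "count"]).reset_index()
    area_idx = agg["area_id"].map(aindex).to_numpy()
    order = np.argsort(area_idx, kind="stable")  # area-contiguous for reduceat
    agg = agg.iloc[order]
    area_idx = area_idx[order]
    age_map = {g: i for i, g in enumerate(AGE_GROUPS)}
    return CellData(
        y=agg["sum"].to_numpy(dtype=float),
        n=agg["count"].to_numpy(dtype=float),
        area_idx=area_idx,
        cycle_idx=agg["cycle"].to_numpy(dtype=int) - 1,
        age_idx=agg["age_group"].map(age_map).to_numpy(dtype=int),
        n_cycles=n_cycles,
        graph=graph,
        area_ids=area_ids,
        income_z=income_z,
        dropped_area_ids=dropped,
        fingerprint=fingerprint,
        sex=spec.sex_stratum,
        outcome=spec.outcome,
    )


@dataclass
class PosteriorDraws:
    """Saved MCMC draws, stacked over chains (``chain`` gives provenance)."""

    beta0: np.ndarray
    cycle: np.ndarray | None  # (S, K-1), categorical coding
    trend_slope: np.ndarray | None  # (S,), integer coding
    age: np.ndarray  # (S, 7) non-reference bands
    gamma: np.ndarray | None
    u: np.ndarray  # (S, J)
    v: np.ndarray  # (S, J)
    sigma_u: np.ndarray
    sigma_v: np.ndarray
    deviance: np.ndarray
    chain: np.ndarray
    spec: ModelSpec
    config: MCMCConfig
    area_ids: list[str]
    income_z: np.ndarray | None
    n_cycles: int
    fingerprint: str

    @property
    def n_draws(self) -> int:
        return len(self.beta0)

    def age_effects_full(self) -> np.ndarray:
        """(S, 8) age effects with the reference band inserted as 0."""
        full = np.zeros((self.n_draws, len(AGE_GROUPS)))
        cols = [i for i in range(len(AGE_GROUPS)) if i != REFERENCE_AGE_INDEX]
        full[:, cols] = self.age
        return full

    def cycle_effects_full(self) -> np.ndarray:
        """(S, K) cycle effects (reference cycle 1 = 0, or slope * (k-1))."""
        if self.cycle is not None:
            return np.hstack([np.zeros((self.n_draws, 1)), self.cycle])
        k = np.arange(self.n_cycles)
        return self.trend_slope[:, None] * k[None, :]

    def to_frame(self) -> pd.DataFrame:
        cols = {"chain": self.chain, "beta0": self.beta0,
                "sigma_u": self.sigma_u, "sigma_v": self.sigma_v,
                "deviance": self.deviance}
        if self.cycle is not None:
            for k in range(self.cycle.shape[1]):
                cols[f"cycle_{k + 2}"] = self.cycle[:, k]
        else:
            cols["trend_slope"] = self.trend_slope
        idx = [i for i in range(len(AGE_GROUPS)) if i != REFERENCE_AGE_INDEX]
        for c, i in enumerate(idx):
            cols[f"age_{AGE_GROUPS[i]}"] = self.age[:, c]
        if self.gamma is not None:
            cols["gamma"] = self.gamma
        for j, a in enumerate(self.area_ids):
            cols[f"u_{a}"] = self.u[:, j]
            cols[f"v_{a}"] = self.v[:, j]
        return pd.DataFrame(cols)

    def save(self, csv_path: str, meta_path: str) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        meta = {
            "spec": {**self.spec.__dict__},
            "config": {**self.config.__dict__},
            "area_ids": self.area_ids,
            "n_cycles": self.n_cycles,
            "fingerprint": self.fingerprint,
            "income_z": None if self.income_z is None else self.income_z.tolist(),
        }
        with open(meta_path, "w") as fh:
            json.dump(meta, fh, indent=2)


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _icar_logprior(u: np.ndarray, tau: float, pairs: np.ndarray, rank: int) -> float:
    ss = float(np.sum((u[pairs[:, 0]] - u[pairs[:, 1]]) ** 2))
    return 0.5 * rank * (np.log(tau) - np.log(2 * np.pi)) - 0.5 * tau * ss


def log_posterior(params: dict, data: CellData, spec: ModelSpec) -> float:
    """Joint log density (likelihood + all priors) at a parameter point.

    ``params`` keys: ``beta0``, ``cycle`` (length K-1) or ``trend_slope``,
    ``age`` (length 7, non-reference bands), ``gamma`` (model 2), ``u``,
    ``v``, ``sigma_u``, ``sigma_v``.  The Bernoulli likelihood is evaluated
    on the aggregated cells (no binomial coefficient, matching a product of
    per-respondent Bernoulli densities).
    """
    from scipy.stats import gamma as gamma_dist, norm

    u = np.asarray(params["u"], dtype=float)
    v = np.asarray(params["v"], dtype=float)
    if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
        raise ValueError("non-finite random effects")
    sigma_u, sigma_v = float(params["sigma_u"]), float(params["sigma_v"])
    eta = _linear_predictor(params, data, spec)
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite linear predictor")
    ll = float(np.sum(data.y * eta - data.n * _softplus(eta)))

    sd0 = spec.hyper("fixed_effect_sd")
    lp = norm.logpdf(params["beta0"], 0, sd0)
    if spec.cycle_coding == "categorical":
        lp += norm.logpdf(np.asarray(params["cycle"]), 0, sd0).sum()
    else:
        lp += norm.logpdf(params["trend_slope"], 0, sd0)
    lp += norm.logpdf(np.asarray(params["age"]), 0, sd0).sum()
    if spec.include_income:
        lp += norm.logpdf(params["gamma"], 0, sd0)

    pairs = np.array(data.graph.neighbour_pairs())
    rank = data.n_areas - _n_components(data.graph)
    lp += _icar_logprior(u, sigma_u**-2, pairs, rank)
    lp += norm.logpdf(v, 0, sigma_v).sum()

    if spec.prior_family == "gamma_precision":
        a, b = spec.hyper("gamma_shape"), spec.hyper("gamma_rate")
        lp += gamma_dist.logpdf(sigma_u**-2, a, scale=1 / b)
        lp += gamma_dist.logpdf(sigma_v**-2, a, scale=1 / b)
    else:
        upper = spec.hyper("uniform_upper")
        if not (0 < sigma_u < upper and 0 < sigma_v < upper):
            return -np.inf
        lp += -2 * np.log(upper)
    return ll + float(lp)


def _linear_predictor(params: dict, data: CellData, spec: ModelSpec) -> np.ndarray:
    eta = params["beta0"] + np.asarray(params["u"])[data.area_idx] \
        + np.asarray(params["v"])[data.area_idx]
    age_full = np.zeros(len(AGE_GROUPS))
    cols = [i for i in range(len(AGE_GROUPS)) if i != REFERENCE_AGE_INDEX]
    age_full[cols] = np.asarray(params["age"], dtype=float)
    eta = eta + age_full[data.age_idx]
    if spec.cycle_coding == "categorical":
        cyc_full = np.concatenate([[0.0], np.asarray(params["cycle"], dtype=float)])
        eta = eta + cyc_full[data.cycle_idx]
    else:
        eta = eta + params["trend_slope"] * data.cycle_idx
    if spec.include_income:
        eta = eta + params["gamma"] * data.income_z[data.area_idx]
    return eta


def _n_components(graph: AdjacencyGraph) -> int:
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(graph.n))
    g.add_edges_from(graph.neighbour_pairs())
    return nx.number_connected_components(g)


def _graph_coloring(graph: AdjacencyGraph) -> list[np.ndarray]:
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(graph.n))
    g.add_edges_from(graph.neighbour_pairs())
    colors = nx.greedy_color(g, strategy="largest_first")
    n_col = max(colors.values()) + 1
    return [np.array([j for j, c in colors.items() if c == k]) for k in range(n_col)]


class _ChainState:
    """Mutable sampler state for one chain (cell eta kept incrementally)."""

    def __init__(self, data: CellData, spec: ModelSpec, rng: np.random.Generator,
                 scales: dict):
        self.rng = rng
        j = data.n_areas
        self.beta0 = rng.normal(0, 0.3)
        self.cycle = rng.normal(0, 0.1, data.n_cycles - 1)
        self.trend = rng.normal(0, 0.05)
        self.age = rng.normal(0, 0.1, len(AGE_GROUPS) - 1)
        self.gamma = rng.normal(0, 0.05) if spec.include_income else 0.0
        self.u = np.zeros(j)
        self.v = np.zeros(j)
        self.tau_u = 1.0 / max(rng.uniform(0.05, 0.5), 1e-6) ** 2
        self.tau_v = 1.0 / max(rng.uniform(0.05, 0.5), 1e-6) ** 2
        self.scales = dict(scales)


def fit_bym(data: CellData, spec: ModelSpec, config: MCMCConfig) -> PosteriorDraws:
    """Run the Metropolis-within-Gibbs sampler and return saved draws.

    Deterministic under a fixed ``config.seed``; raises on divergence
    (non-finite state) with the offending iteration index.
    """
    if not data.graph.is_connected():
        raise ValueError("adjacency graph must be connected after island removal")
    j = data.n_areas
    k_cycles = data.n_cycles
    pairs = np.array(data.graph.neighbour_pairs())
    rank = j - _n_components(data.graph)
    deg = data.graph.degree().astype(float)
    adj = data.graph.weight_matrix()
    colors = _graph_coloring(data.graph)
    # per-cell fixed covariates
    area_idx = data.area_idx
    cyc_idx = data.cycle_idx
    age_idx = data.age_idx
    y, n = data.y, data.n
    inc_cell = data.income_z[area_idx] if spec.include_income else None
    trend_x = cyc_idx.astype(float)
    # area-contiguous cell blocks for per-area likelihood reductions
    area_start = np.searchsorted(area_idx, np.arange(j))
    age_cols = [i for i in range(len(AGE_GROUPS)) if i != REFERENCE_AGE_INDEX]
    age_active = np.array(age_cols)
    cyc_active = np.arange(1, k_cycles)  # level 0 is the reference cycle

    base_scales = {"beta0": 0.1, "cycle": 0.1, "age": 0.1, "gamma": 0.05,
                   "u": 0.3, "v": 0.3}
    base_scales.update(config.proposal_scales)
    a_hyp = spec.hyper("gamma_shape")
    b_hyp = spec.hyper("gamma_rate")
    upper = spec.hyper("uniform_upper")
    sd0 = spec.hyper("fixed_effect_sd")
    use_gamma_prior = spec.prior_family == "gamma_precision"
    categorical = spec.cycle_coding == "categorical"

    n_save_per_chain = config.n_keep_iterations // config.thin
    s_total = config.n_chains * n_save_per_chain
    out = {
        "beta0": np.empty(s_total), "sigma_u": np.empty(s_total),
        "sigma_v": np.empty(s_total), "deviance": np.empty(s_total),
        "chain": np.empty(s_total, dtype=int),
        "age": np.empty((s_total, len(AGE_GROUPS) - 1)),
        "u": np.empty((s_total, j)), "v": np.empty((s_total, j)),
    }
    if categorical:
        out["cycle"] = np.empty((s_total, k_cycles - 1))
    else:
        out["trend"] = np.empty(s_total)
    if spec.include_income:
        out["gamma"] = np.empty(s_total)

    def eta_of(st: _ChainState) -> np.ndarray:
        eta = st.beta0 + st.u[area_idx] + st.v[area_idx]
        age_full = np.zeros(len(AGE_GROUPS))
        age_full[age_cols] = st.age
        eta = eta + age_full[age_idx]
        if categorical:
            cyc_full = np.concatenate([[0.0], st.cycle])
            eta = eta + cyc_full[cyc_idx]
        else:
            eta = eta + st.trend * trend_x
        if spec.include_income:
            eta = eta + st.gamma * inc_cell
        return eta

    def scalar_update(st, eta, sp, value, scale, sub, x_sub):
        """Random-walk MH for one coefficient; returns (new value, accepted).

        ``sp`` caches softplus(eta) and is kept in sync with ``eta``.
        """
        step = st.rng.normal(0, scale)
        d_eta = step * x_sub
        eta_new = eta[sub] + d_eta
        sp_new = _softplus(eta_new)
        d_ll = np.sum(y[sub] * d_eta - n[sub] * (sp_new - sp[sub]))
        d_lp = (value**2 - (value + step) ** 2) / (2 * sd0**2)
        if np.log(st.rng.random()) < d_ll + d_lp:
            eta[sub] = eta_new
            sp[sub] = sp_new
            return value + step, True
        return value, False

    def level_block_update(st, eta, sp, values, scale, level_idx, n_levels, active):
        """Per-level random-walk MH for a categorical effect, in one pass.

        Cells of different levels are disjoint, so the likelihood factorises
        over levels and simultaneous per-level accept/reject is a sequence of
        independent scalar MH updates.  ``values`` has one entry per level
        (reference level must not be in ``active``).  Returns acceptance rate.
        """
        steps = np.zeros(n_levels)
        steps[active] = st.rng.normal(0, scale, len(active))
        d_eta = steps[level_idx]
        eta_new = eta + d_eta
        sp_new = _softplus(eta_new)
        d_ll_cell = y * d_eta - n * (sp_new - sp)
        d_ll = np.bincount(level_idx, weights=d_ll_cell, minlength=n_levels)
        vals_full = np.zeros(n_levels)
        vals_full[active] = values
        d_lp = (vals_full**2 - (vals_full + steps) ** 2) / (2 * sd0**2)
        ok = np.zeros(n_levels, dtype=bool)
        ok[active] = np.log(st.rng.random(len(active))) < (d_ll + d_lp)[active]
        values[:] = (vals_full + np.where(ok, steps, 0.0))[active]
        ok_cell = ok[level_idx]
        eta[ok_cell] = eta_new[ok_cell]
        sp[ok_cell] = sp_new[ok_cell]
        return float(ok[active].mean()) if len(active) else 0.0

    def sample_precision(st, ss, rank_term, is_u):
        """Conjugate precision draw (gamma-precision or uniform-sd prior)."""
        if use_gamma_prior:
            shape = a_hyp + 0.5 * rank_term
            rate = b_hyp + 0.5 * ss
        else:
            shape = 0.5 * rank_term - 0.5
            rate = 0.5 * ss
            if shape <= 0:
                return st.tau_u if is_u else st.tau_v
        for _ in range(100):
            tau = st.rng.gamma(shape, 1.0 / max(rate, 1e-300))
            if use_gamma_prior or tau > upper**-2:
                return max(tau, 1e-12)
        return max(upper**-2 * 1.0000001, 1e-12)

    for chain_id, chain_seed in enumerate(
        np.random.SeedSequence(config.seed).spawn(config.n_chains)
    ):
        rng = np.random.default_rng(chain_seed)
        st = _ChainState(data, spec, rng, base_scales)
        eta = eta_of(st)
        sp = _softplus(eta)
        acc: dict[str, list[float]] = {k: [0, 0] for k in base_scales}
        full = np.arange(len(y))
        ones = np.ones(len(y))
        save_ptr = chain_id * n_save_per_chain
        total_iter = config.burn_in + config.n_keep_iterations
        for it in range(total_iter):
            adapting = it < config.burn_in
            # ---- fixed effects
            st.beta0, ok = scalar_update(st, eta, sp, st.beta0,
                                         st.scales["beta0"], full, ones)
            acc["beta0"][0] += ok
            acc["beta0"][1] += 1
            if categorical:
                rate = level_block_update(st, eta, sp, st.cycle,
                                          st.scales["cycle"], cyc_idx,
                                          k_cycles, cyc_active)
                acc["cycle"][0] += rate
                acc["cycle"][1] += 1
            else:
                st.trend, ok = scalar_update(st, eta, sp, st.trend,
                                             st.scales["cycle"], full, trend_x)
                acc["cycle"][0] += ok
                acc["cycle"][1] += 1
            rate = level_block_update(st, eta, sp, st.age, st.scales["age"],
                                      age_idx, len(AGE_GROUPS), age_active)
            acc["age"][0] += rate
            acc["age"][1] += 1
            if spec.include_income:
                st.gamma, ok = scalar_update(st, eta, sp, st.gamma,
                                             st.scales["gamma"], full, inc_cell)
                acc["gamma"][0] += ok
                acc["gamma"][1] += 1

            # ---- spatial effects u: joint proposal, accepted by colour class
            du = rng.normal(0, st.scales["u"], j)
            d_eta = du[area_idx]
            eta_new = eta + d_eta
            sp_new = _softplus(eta_new)
            d_ll_cell = y * d_eta - n * (sp_new - sp)
            d_ll_area = np.add.reduceat(d_ll_cell, area_start)
            logu = np.log(rng.random(j))
            accepted = np.zeros(j, dtype=bool)
            for block in colors:
                s_all = adj @ st.u  # neighbour sums under current state
                dub = du[block]
                ub = st.u[block]
                d_prior = -0.5 * st.tau_u * (
                    deg[block] * ((ub + dub) ** 2 - ub**2) - 2 * s_all[block] * dub
                )
                ok_b = logu[block] < d_ll_area[block] + d_prior
                idx_ok = block[ok_b]
                st.u[idx_ok] += du[idx_ok]
                accepted[idx_ok] = True
            ok_cell = accepted[area_idx]
            eta[ok_cell] = eta_new[ok_cell]
            sp[ok_cell] = sp_new[ok_cell]
            acc["u"][0] += accepted.mean()
            acc["u"][1] += 1
            # sum-to-zero re-centring with compensating intercept shift
            shift = st.u.mean()
            st.u -= shift
            st.beta0 += shift

            # ---- unstructured effects v: independent per-area MH in one block
            dv = rng.normal(0, st.scales["v"], j)
            d_eta = dv[area_idx]
            eta_new = eta + d_eta
            sp_new = _softplus(eta_new)
            d_ll_cell = y * d_eta - n * (sp_new - sp)
            d_ll_area = np.add.reduceat(d_ll_cell, area_start)
            d_prior = -0.5 * st.tau_v * ((st.v + dv) ** 2 - st.v**2)
            ok_v = np.log(rng.random(j)) < d_ll_area + d_prior
            st.v[ok_v] += dv[ok_v]
            ok_cell = ok_v[area_idx]
            eta[ok_cell] = eta_new[ok_cell]
            sp[ok_cell] = sp_new[ok_cell]
            acc["v"][0] += ok_v.mean()
            acc["v"][1] += 1

            # ---- scales
            ss_u = float(np.sum((st.u[pairs[:, 0]] - st.u[pairs[:, 1]]) ** 2))
            st.tau_u = sample_precision(st, ss_u, rank, True)
            st.tau_v = sample_precision(st, float(st.v @ st.v), j, False)

            if not np.isfinite(eta).all():
                raise RuntimeError(f"divergence at iteration {it} (non-finite state)")

            if adapting and (it + 1) % 50 == 0:
                for key in acc:
                    tries = acc[key][1]
                    if tries:
                        rate = acc[key][0] / tries
                        st.scales[key] *= float(np.exp(0.66 * (rate - 0.44)))
                    acc[key] = [0, 0]

            if not adapting:
                kept_it = it - config.burn_in
                if (kept_it + 1) % config.thin == 0:
                    ptr = save_ptr + kept_it // config.thin
                    out["beta0"][ptr] = st.beta0
                    out["sigma_u"][ptr] = st.tau_u**-0.5
                    out["sigma_v"][ptr] = st.tau_v**-0.5
                    out["deviance"][ptr] = -2.0 * float(np.sum(y * eta - n * sp))
                    out["chain"][ptr] = chain_id
                    out["age"][ptr] = st.age
                    out["u"][ptr] = st.u
                    out["v"][ptr] = st.v
                    if categorical:
                        out["cycle"][ptr] = st.cycle
                    else:
                        out["trend"][ptr] = st.trend
                    if spec.include_income:
                        out["gamma"][ptr] = st.gamma

    return PosteriorDraws(
        beta0=out["beta0"],
        cycle=out.get("cycle"),
        trend_slope=out.get("trend"),
        age=out["age"],
        gamma=out.get("gamma"),
        u=out["u"],
        v=out["v"],
        sigma_u=out["sigma_u"],
        sigma_v=out["sigma_v"],
        deviance=out["deviance"],
        chain=out["chain"],
        spec=spec,
        config=config,
        area_ids=list(data.area_ids),
        income_z=None if data.income_z is None else data.income_z.copy(),
        n_cycles=k_cycles,
        fingerprint=data.fingerprint,
    )


# ---------------------------------------------------------------------------
# Diagnostics

def split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor.

    ``chains`` is (n_chains, n_iter).  Chains whose draws are all identical
    (zero variance everywhere) are perfectly converged by convention (1.0).
    """
    chains = np.asarray(chains, dtype=float)
    m, n_it = chains.shape
    if m < 2 or n_it < 4:
        raise ValueError("need >= 2 chains and >= 4 draws per chain")
    half = n_it // 2
    split = np.concatenate([chains[:, :half], chains[:, half:2 * half]], axis=0)
    w = split.var(axis=1, ddof=1).mean()
    b_over_n = split.mean(axis=1).var(ddof=1)
    if w == 0:
        return 1.0 if b_over_n == 0 else np.inf
    var_hat = (half - 1) / half * w + b_over_n
    return float(np.sqrt(var_hat / w))


def autocorrelation(chains: np.ndarray, lags: tuple[int, ...] = (0, 1, 5, 10, 50)) -> dict[int, float]:
    """Within-chain autocorrelation averaged over chains (lag 0 = 1)."""
    chains = np.asarray(chains, dtype=float)
    result = {}
    for lag in lags:
        vals = []
        for ch in chains:
            if lag >= len(ch):
                continue
            x = ch - ch.mean()
            denom = float(x @ x)
            if denom == 0:
                vals.append(1.0 if lag == 0 else 0.0)
            else:
                vals.append(float(x[: len(x) - lag] @ x[lag:]) / denom)
        result[lag] = float(np.mean(vals)) if vals else np.nan
    return result


def convergence_diagnostics(draws: PosteriorDraws,
                            lags: tuple[int, ...] = (0, 1, 5, 10, 50)) -> pd.DataFrame:
    """Per-parameter split-R̂ and autocorrelation by lag (scalar parameters
    plus the random-effect scales)."""
    n_chains = int(draws.chain.max()) + 1
    if n_chains < 2:
        raise ValueError("convergence diagnostics require >= 2 chains")

    def per_chain(x: np.ndarray) -> np.ndarray:
        return np.stack([x[draws.chain == c] for c in range(n_chains)])

    params = {"beta0": draws.beta0, "sigma_u": draws.sigma_u,
              "sigma_v": draws.sigma_v}
    if draws.gamma is not None:
        params["gamma"] = draws.gamma
    if draws.trend_slope is not None:
        params["trend_slope"] = draws.trend_slope
    if draws.cycle is not None:
        for k in range(draws.cycle.shape[1]):
            params[f"cycle_{k + 2}"] = draws.cycle[:, k]
    rows = []
    for name, x in params.items():
        ch = per_chain(x)
        row = {"parameter": name, "rhat": split_rhat(ch)}
        row.update({f"acf_lag{lag}": v for lag, v in autocorrelation(ch, lags).items()})
        rows.append(row)
    return pd.DataFrame(rows).set_index("parameter")


# ---------------------------------------------------------------------------
# Model comparison

@dataclass
class DicResult:
    mean_deviance: float
    deviance_at_mean: float
    effective_parameters: float
    dic: float
    fingerprint: str


def dic(draws: PosteriorDraws, data: CellData, spec: ModelSpec) -> DicResult:
    """Deviance information criterion: DIC = D̄ + pD with pD = D̄ - D(θ̄).

    D(θ̄) is the deviance at the posterior means of *all* parameters
    (fixed effects and both sets of area effects).
    """
    d_bar = float(draws.deviance.mean())
    params = {
        "beta0": float(draws.beta0.mean()),
        "age": draws.age.mean(axis=0),
        "u": draws.u.mean(axis=0),
        "v": draws.v.mean(axis=0),
        "sigma_u": float(draws.sigma_u.mean()),
        "sigma_v": float(draws.sigma_v.mean()),
    }
    if draws.cycle is not None:
        params["cycle"] = draws.cycle.mean(axis=0)
    else:
        params["trend_slope"] = float(draws.trend_slope.mean())
    if draws.gamma is not None:
        params["gamma"] = float(draws.gamma.mean())
    eta = _linear_predictor(params, data, spec)
    d_at_mean = -2.0 * float(np.sum(data.y * eta - data.n * _softplus(eta)))
    pd_eff = d_bar - d_at_mean
    return DicResult(
        mean_deviance=d_bar,
        deviance_at_mean=d_at_mean,
        effective_parameters=pd_eff,
        dic=d_bar + pd_eff,
        fingerprint=draws.fingerprint,
    )


def compare_models_dic(dic_a: DicResult, dic_b: DicResult,
                       meaningful_threshold: float = 7.0) -> dict:
    """Lower DIC is preferred; a difference > 7 is treated as meaningful."""
    if dic_a.fingerprint != dic_b.fingerprint:
        raise ValueError("DIC comparison across different data/outcome/stratum")
    diff = dic_b.dic - dic_a.dic
    if diff == 0:
        preferred = None
    else:
        preferred = "a" if dic_a.dic < dic_b.dic else "b"
    return {
        "preferred": preferred,
        "difference": diff,
        "meaningful": abs(diff) > meaningful_threshold,
    }


def prior_sensitivity(data: CellData, spec: ModelSpec, config: MCMCConfig) -> dict:
    """Refit with gamma-precision vs uniform-sd hyperpriors (same seed).

    Reports the maximum absolute difference in area-level posterior mean
    effects (u + v) between the two arms, and that difference relative to the
    posterior sd, plus both draws objects.
    """
    arms = {}
    for fam in ("gamma_precision", "uniform_sd"):
        arms[fam] = fit_bym(data, replace(spec, prior_family=fam), config)
    mean_a = (arms["gamma_precision"].u + arms["gamma_precision"].v).mean(axis=0)
    mean_b = (arms["uniform_sd"].u + arms["uniform_sd"].v).mean(axis=0)
    sd = (arms["gamma_precision"].u + arms["gamma_precision"].v).std(axis=0)
    diff = np.abs(mean_a - mean_b)
    return {
        "max_abs_difference": float(diff.max()),
        "max_relative_difference": float((diff / np.maximum(sd, 1e-12)).max()),
        "draws_gamma_precision": arms["gamma_precision"],
        "draws_uniform_sd": arms["uniform_sd"],
    }
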