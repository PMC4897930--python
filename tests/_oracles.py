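"""Independent brute-force reference implementations.

Everything here is written directly from the mathematical definitions (plain
loops, scipy densities) without reusing any package internals, so agreement
with the package is a genuine two-route check.
"""

import numpy as np
from scipy import stats
from scipy.special import expit


def brute_morans_i(obs, exp, edge_pairs, n):
    """Moran's I by explicit double loop over binary symmetric weights."""
    z = np.asarray(obs, float) - np.asarray(exp, float)
    w = np.zeros((n, n))
    for i, j in edge_pairs:
        w[i, j] = 1.0
        w[j, i] = 1.0
    s0 = w.sum()
    num = 0.0
    for i in range(n):
        for j in range(n):
            num += w[i, j] * z[i] * z[j]
    return n / s0 * num / np.sum(z**2)


def brute_bernoulli_llr(c, n, C, N):
    """Bernoulli scan LLR from its definition (0*log(0) treated as 0)."""
    if n == N or c * N <= C * n:
        return 0.0

    def xl(a, b):
        return 0.0 if a == 0 else a * np.log(b)

    return (
        xl(c, c / n) + xl(n - c, (n - c) / n)
        + xl(C - c, (C - c) / (N - n))
        + xl(N - n - C + c, (N - n - C + c) / (N - n))
        - xl(C, C / N) - xl(N - C, (N - C) / N)
    )


def brute_poststratified_prevalence(cell_probs_by_cycle_age, census_by_age):
    """Post-stratified prevalence: equal-weight cycle average then
    census-count weighting, by explicit loops."""
    n_cycles = len(cell_probs_by_cycle_age)
    n_ages = len(census_by_age)
    num = 0.0
    den = 0.0
    for a in range(n_ages):
        p_a = sum(cell_probs_by_cycle_age[c][a] for c in range(n_cycles)) / n_cycles
        num += census_by_age[a] * p_a
        den += census_by_age[a]
    return num / den


def brute_log_posterior(
    params, records, edge_pairs, n_areas, income_z=None,
    prior_family="gamma_precision", fixed_sd=10.0,
    gamma_shape=0.5, gamma_rate=0.0005, uniform_upper=10.0,
    n_components=1,
):
    """Joint log density summed respondent by respondent with scipy pdfs.

    ``records`` is a list of dicts with keys area (index), cycle_idx (0-based),
    age_idx (0..7), y.  ``params`` uses full-length age/cycle vectors with the
    reference entries at 0.
    """
    u = np.asarray(params["u"], float)
    v = np.asarray(params["v"], float)
    total = 0.0
    for r in records:
        eta = (
            params["beta0"]
            + params["cycle_full"][r["cycle_idx"]]
            + params["age_full"][r["age_idx"]]
            + u[r["area"]] + v[r["area"]]
        )
        if income_z is not None:
            eta += params["gamma"] * income_z[r["area"]]
        total += stats.bernoulli.logpmf(r["y"], expit(eta))
    # fixed-effect priors
    total += stats.norm.logpdf(params["beta0"], 0, fixed_sd)
    for k, val in enumerate(params["cycle_full"]):
        if k > 0:
            total += stats.norm.logpdf(val, 0, fixed_sd)
    for k, val in enumerate(params["age_full"]):
        if k != params["reference_age_index"]:
            total += stats.norm.logpdf(val, 0, fixed_sd)
    if income_z is not None:
        total += stats.norm.logpdf(params["gamma"], 0, fixed_sd)
    # ICAR prior (pairwise differences, rank-deficient normalisation)
    tau_u = params["sigma_u"] ** -2
    ss = sum((u[i] - u[j]) ** 2 for i, j in edge_pairs)
    rank = n_areas - n_components
    total += 0.5 * rank * (np.log(tau_u) - np.log(2 * np.pi)) - 0.5 * tau_u * ss
    # iid effects
    total += stats.norm.logpdf(v, 0, params["sigma_v"]).sum()
    # hyperpriors
    if prior_family == "gamma_precision":
        total += stats.gamma.logpdf(params["sigma_u"] ** -2, gamma_shape,
                                    scale=1 / gamma_rate)
        total += stats.gamma.logpdf(params["sigma_v"] ** -2, gamma_shape,
                                    scale=1 / gamma_rate)
    else:
        if not (0 < params["sigma_u"] < uniform_upper
                and 0 < params["sigma_v"] < uniform_upper):
            return -np.inf
        total += -2 * np.log(uniform_upper)
    return float(total)


def brute_deviance(params, records, income_z=None):
    """-2 * Bernoulli log likelihood, respondent by respondent."""
    u = np.asarray(params["u"], float)
    v = np.asarray(params["v"], float)
    total = 0.0
    for r in records:
        eta = (
            params["beta0"]
            + params["cycle_full"][r["cycle_idx"]]
            + params["age_full"][r["age_idx"]]
            + u[r["area"]] + v[r["area"]]
        )
        if income_z is not None:
            eta += params["gamma"] * income_z[r["area"]]
        total += stats.bernoulli.logpmf(r["y"], expit(eta))
    return -2.0 * float(total)


def brute_weighted_prevalence(weights, outcomes):
    num = sum(w * y for w, y in zip(weights, outcomes))
    return num / sum(weights)


def brute_scan_max(points_xy, cases, totals, shapes, angles, max_frac):
    """Maximum Bernoulli LLR over all distance-ordered prefix windows."""
    xy = np.asarray(points_xy, float)
    cases = np.asarray(cases, float)
    totals = np.asarray(totals, float)
    C, N = cases.sum(), totals.sum()
    cap = np.floor(max_frac * N)
    best = 0.0
    for ci in range(len(xy)):
        for ratio in shapes:
            for ang in (angles if ratio != 1.0 else angles[:1]):
                th = np.deg2rad(ang)
                dx = xy[:, 0] - xy[ci, 0]
                dy = xy[:, 1] - xy[ci, 1]
                dxr = np.cos(th) * dx + np.sin(th) * dy
                dyr = -np.sin(th) * dx + np.cos(th) * dy
                d = np.sqrt((dxr / ratio) ** 2 + dyr**2)
                order = np.argsort(d, kind="stable")
                c_in = n_in = 0.0
                i = 0
                while i < len(order):
                    k = i
                    while k < len(order) and d[order[k]] == d[order[i]]:
                        k += 1
                    group = order[i:k]
                    if n_in + totals[group].sum() > cap:
                        break
                    c_in += cases[group].sum()
                    n_in += totals[group].sum()
                    best = max(best, brute_bernoulli_llr(c_in, n_in, C, N))
                    i = k
    return best
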