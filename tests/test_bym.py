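"""Hierarchical spatial logistic model: density, sampler, diagnostics, DIC."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import microprev as mp
from microprev.bym import _icar_logprior, autocorrelation, split_rhat
from microprev.types import AGE_GROUPS, REFERENCE_AGE_INDEX
from conftest import make_tiny_instance
from _oracles import brute_deviance, brute_log_posterior


def _records_and_params(resp, data, rng, include_income):
    """Respondent-level records aligned to the cell data, plus random params."""
    aindex = {a: i for i, a in enumerate(data.area_ids)}
    age_map = {g: i for i, g in enumerate(AGE_GROUPS)}
    records = [
        {"area": aindex[r.area_id], "cycle_idx": r.cycle - 1,
         "age_idx": age_map[r.age_group], "y": int(r.y)}
        for r in resp.itertuples()
    ]
    j = data.n_areas
    params = {
        "beta0": rng.normal(-1, 0.3),
        "cycle": rng.normal(0, 0.2, data.n_cycles - 1),
        "age": rng.normal(0, 0.3, len(AGE_GROUPS) - 1),
        "u": rng.normal(0, 0.4, j),
        "v": rng.normal(0, 0.3, j),
        "sigma_u": rng.uniform(0.2, 0.8),
        "sigma_v": rng.uniform(0.2, 0.8),
    }
    params["u"] -= params["u"].mean()
    if include_income:
        params["gamma"] = rng.normal(0, 0.2)
    age_full = np.zeros(len(AGE_GROUPS))
    cols = [i for i in range(len(AGE_GROUPS)) if i != REFERENCE_AGE_INDEX]
    age_full[cols] = params["age"]
    oracle_params = {
        "beta0": params["beta0"],
        "cycle_full": np.concatenate([[0.0], params["cycle"]]),
        "age_full": age_full,
        "reference_age_index": REFERENCE_AGE_INDEX,
        "u": params["u"], "v": params["v"],
        "sigma_u": params["sigma_u"], "sigma_v": params["sigma_v"],
    }
    if include_income:
        oracle_params["gamma"] = params["gamma"]
    return records, params, oracle_params


class TestLogPosterior:
    @pytest.mark.parametrize("include_income,prior_family", [
        (False, "gamma_precision"), (True, "gamma_precision"),
        (True, "uniform_sd"),
    ])
    def test_matches_respondent_level_oracle(self, include_income, prior_family):
        areas, resp = make_tiny_instance(seed=2, n_respondents=8)
        spec = mp.ModelSpec(sex_stratum="M", include_income=include_income,
                            prior_family=prior_family)
        data = mp.build_cell_data(resp, areas, spec)
        rng = np.random.default_rng(3)
        records, params, oparams = _records_and_params(resp, data, rng,
                                                       include_income)
        got = mp.log_posterior(params, data, spec)
        want = brute_log_posterior(
            oparams, records, data.graph.neighbour_pairs(), data.n_areas,
            income_z=data.income_z, prior_family=prior_family,
        )
        assert got == pytest.approx(want, rel=1e-9)

    def test_single_null_respondent_contributes_log_half(self):
        areas, resp = make_tiny_instance(seed=4, n_respondents=1)
        resp = resp.assign(y=1)
        spec = mp.ModelSpec(sex_stratum="M", include_income=False)
        data = mp.build_cell_data(resp, areas, spec)
        zero = {"beta0": 0.0, "cycle": np.zeros(data.n_cycles - 1),
                "age": np.zeros(7), "u": np.zeros(4), "v": np.zeros(4),
                "sigma_u": 0.5, "sigma_v": 0.5}
        base = mp.log_posterior(zero, data, spec)
        # removing the only respondent's likelihood leaves priors only
        data_zero = data
        data_zero.y = np.zeros_like(data.y)
        data_zero.n = np.zeros_like(data.n)
        priors_only = mp.log_posterior(zero, data_zero, spec)
        assert base - priors_only == pytest.approx(np.log(0.5), rel=1e-12)

    def test_respondent_order_invariance(self):
        areas, resp = make_tiny_instance(seed=5, n_respondents=12)
        spec = mp.ModelSpec(sex_stratum="M", include_income=True)
        shuffled = resp.sample(frac=1.0, random_state=9)
        d1 = mp.build_cell_data(resp, areas, spec)
        d2 = mp.build_cell_data(shuffled, areas, spec)
        rng = np.random.default_rng(10)
        _, params, _ = _records_and_params(resp, d1, rng, True)
        assert mp.log_posterior(params, d1, spec) == pytest.approx(
            mp.log_posterior(params, d2, spec), rel=1e-12)

    def test_icar_prior_shift_invariant_and_zero_for_constants(self):
        pairs = np.array([(0, 1), (1, 2), (2, 3), (0, 3)])
        u = np.array([0.3, -0.1, 0.2, -0.4])
        base = _icar_logprior(u, 4.0, pairs, 3)
        shifted = _icar_logprior(u + 5.0, 4.0, pairs, 3)
        assert shifted == pytest.approx(base, rel=1e-12)
        const = _icar_logprior(np.full(4, 2.0), 4.0, pairs, 3)
        # pairwise differences vanish: only the normalising term remains
        assert const == pytest.approx(0.5 * 3 * (np.log(4.0) - np.log(2 * np.pi)))


class TestConfig:
    def test_production_preset_saved_draw_count(self):
        cfg = mp.MCMCConfig.production_preset()
        assert cfg.n_saved_draws == 15_000
        assert cfg.n_chains == 3 and cfg.burn_in == 500_000

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            mp.MCMCConfig(n_chains=1)
        with pytest.raises(ValueError):
            mp.MCMCConfig(thin=0)
        with pytest.raises(ValueError):
            mp.ModelSpec(income_scale=-1)


class TestSampler:
    def test_deterministic_under_seed(self, grid_areas, grid_survey):
        spec = mp.ModelSpec(sex_stratum="F", include_income=False)
        data = mp.build_cell_data(grid_survey, grid_areas, spec)
        cfg = mp.MCMCConfig(n_chains=2, burn_in=100, n_keep_iterations=100,
                            thin=2, seed=77)
        d1 = mp.fit_bym(data, spec, cfg)
        d2 = mp.fit_bym(data, spec, cfg)
        assert np.array_equal(d1.beta0, d2.beta0)
        assert np.array_equal(d1.u, d2.u)
        assert np.array_equal(d1.deviance, d2.deviance)

    def test_u_sums_to_zero_every_draw(self, tiny_fit):
        draws, _, _ = tiny_fit
        assert np.abs(draws.u.sum(axis=1)).max() < 1e-9

    def test_scales_positive_and_draw_count(self, tiny_fit):
        draws, _, _ = tiny_fit
        assert draws.n_draws == draws.config.n_saved_draws
        assert (draws.sigma_u > 0).all() and (draws.sigma_v > 0).all()

    def test_posterior_mean_matches_ensemble_sampler_oracle(self):
        """Cross-check the Gibbs sampler against an affine-invariant ensemble
        sampler run on an independently coded posterior (same model, single
        age band so only intercept, area effects and scales are informed)."""
        emcee = pytest.importorskip("emcee")
        areas = mp.make_geography(2, 2, "rook", seed=30)
        mp.simulate_census(areas, mean_pop=120, seed=31)
        mp.simulate_income(areas, seed=32)
        truth = mp.make_ground_truth(areas, seed=33, cycle_effects=np.zeros(1),
                                     sigma_u=0.3, sigma_v=0.2)
        resp = mp.simulate_survey(areas, truth, n_cycles=1, sampling_rate=0.2,
                                  n_bootstrap=0, seed=34)
        resp = resp[resp["sex"] == "M"].copy()
        resp["age_group"] = "50-59"
        resp["age_years"] = 55
        spec = mp.ModelSpec(sex_stratum="M", include_income=False)
        data = mp.build_cell_data(resp, areas, spec)
        cfg = mp.MCMCConfig(n_chains=3, burn_in=3000, n_keep_iterations=6000,
                            thin=2, seed=35)
        draws = mp.fit_bym(data, spec, cfg)

        # independent target: theta = (beta0, w[3], v[4], log su, log sv)
        aindex = {a: i for i, a in enumerate(data.area_ids)}
        area_of = resp["area_id"].map(aindex).to_numpy()
        yv = resp["y"].to_numpy(dtype=float)
        pairs = np.array(data.graph.neighbour_pairs())
        lap = np.zeros((4, 4))
        for i, j in pairs:
            lap[i, j] -= 1
            lap[j, i] -= 1
            lap[i, i] += 1
            lap[j, j] += 1
        basis = np.linalg.svd(np.eye(4) - 0.25)[0][:, :3]  # sum-zero basis

        def log_prob(theta):
            theta = np.atleast_2d(theta)
            b0 = theta[:, 0]
            u = theta[:, 1:4] @ basis.T
            v = theta[:, 4:8]
            lsu, lsv = theta[:, 8], theta[:, 9]
            tau_u, tau_v = np.exp(-2 * lsu), np.exp(-2 * lsv)
            eta = b0[:, None] + u[:, area_of] + v[:, area_of]
            ll = (yv * eta - np.logaddexp(0, eta)).sum(axis=1)
            quad = np.einsum("si,ij,sj->s", u, lap, u)
            lp = 1.5 * np.log(tau_u) - 0.5 * tau_u * quad
            lp += (2.0 * np.log(tau_v) - 0.5 * tau_v * (v**2).sum(axis=1)
                   - 0.5 * 4 * np.log(2 * np.pi))
            lp += -0.5 * (b0 / 10.0) ** 2
            a, b = 0.5, 0.0005
            for tau in (tau_u, tau_v):  # gamma prior on tau + d tau/d log sigma
                lp += (a - 1) * np.log(tau) - b * tau + np.log(2 * tau)
            return ll + lp

        rng = np.random.default_rng(36)
        nw = 40
        p0 = np.hstack([
            rng.normal(-1, 0.2, (nw, 1)), rng.normal(0, 0.1, (nw, 7)),
            rng.normal(-1.2, 0.2, (nw, 2)),
        ])
        sampler = emcee.EnsembleSampler(nw, 10, log_prob, vectorize=True)
        state = sampler.run_mcmc(p0, 3000, progress=False)
        chain = sampler.get_chain(discard=1500, thin=5, flat=True)
        beta0_oracle = chain[:, 0].mean()
        assert draws.beta0.mean() == pytest.approx(beta0_oracle, abs=0.06)

    def test_sigma_u_shrinks_when_truth_is_flat(self, grid_areas):
        """Paired fits: data generated without spatial structure yield much
        less posterior mass on large sigma_u than data with sigma_u = 0.5."""
        means = {}
        for su in (0.0, 0.5):
            truth = mp.make_ground_truth(grid_areas, seed=40, sigma_u=su,
                                         sigma_v=0.05)
            resp = mp.simulate_survey(grid_areas, truth, n_cycles=5,
                                      sampling_rate=0.15, n_bootstrap=0,
                                      seed=41)
            spec = mp.ModelSpec(sex_stratum="M", include_income=False)
            data = mp.build_cell_data(resp, grid_areas, spec)
            cfg = mp.MCMCConfig(n_chains=2, burn_in=800, n_keep_iterations=800,
                                thin=2, seed=42)
            means[su] = mp.fit_bym(data, spec, cfg).sigma_u.mean()
        assert means[0.0] < 0.5 * means[0.5]


class TestDiagnostics:
    def test_identical_constant_chains_converged(self):
        chains = np.full((3, 100), 2.5)
        assert split_rhat(chains) == 1.0

    def test_well_mixed_chains_near_one(self):
        rng = np.random.default_rng(1)
        assert abs(split_rhat(rng.standard_normal((4, 2000))) - 1) < 0.02

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(2)
        chains = np.stack([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
        assert split_rhat(chains) > 2.0

    def test_autocorrelation_lag_zero_is_one(self):
        rng = np.random.default_rng(3)
        acf = autocorrelation(rng.standard_normal((2, 500)), lags=(0, 1, 5))
        assert acf[0] == pytest.approx(1.0)
        assert abs(acf[5]) < 0.2

    def test_requires_multiple_chains(self, tiny_fit):
        import copy

        draws, _, _ = tiny_fit
        single = copy.copy(draws)
        single.chain = np.zeros_like(draws.chain)
        with pytest.raises(ValueError):
            mp.convergence_diagnostics(single)

    def test_diagnostics_frame_contents(self, tiny_fit):
        draws, _, _ = tiny_fit
        diag = mp.convergence_diagnostics(draws)
        assert {"beta0", "sigma_u", "sigma_v"} <= set(diag.index)
        assert np.allclose(diag["acf_lag0"], 1.0)


class TestDic:
    def test_identity_and_oracle_deviance(self):
        areas, resp = make_tiny_instance(seed=6, n_respondents=10)
        spec = mp.ModelSpec(sex_stratum="M", include_income=True)
        data = mp.build_cell_data(resp, areas, spec)
        cfg = mp.MCMCConfig(n_chains=2, burn_in=200, n_keep_iterations=200,
                            thin=2, seed=7)
        draws = mp.fit_bym(data, spec, cfg)
        res = mp.dic(draws, data, spec)
        assert res.dic == pytest.approx(2 * res.mean_deviance
                                        - res.deviance_at_mean, rel=1e-12)
        # deviance at the posterior mean vs respondent-level recomputation
        aindex = {a: i for i, a in enumerate(data.area_ids)}
        age_map = {g: i for i, g in enumerate(AGE_GROUPS)}
        records = [
            {"area": aindex[r.area_id], "cycle_idx": r.cycle - 1,
             "age_idx": age_map[r.age_group], "y": int(r.y)}
            for r in resp.itertuples()
        ]
        age_full = np.zeros(len(AGE_GROUPS))
        cols = [i for i in range(len(AGE_GROUPS)) if i != REFERENCE_AGE_INDEX]
        age_full[cols] = draws.age.mean(axis=0)
        oracle = brute_deviance({
            "beta0": draws.beta0.mean(),
            "cycle_full": np.concatenate([[0.0], draws.cycle.mean(axis=0)]),
            "age_full": age_full,
            "u": draws.u.mean(axis=0), "v": draws.v.mean(axis=0),
            "gamma": draws.gamma.mean(),
        }, records, income_z=data.income_z)
        assert res.deviance_at_mean == pytest.approx(oracle, rel=1e-9)

    def test_degenerate_posterior_has_zero_complexity(self, tiny_fit):
        draws, data, spec = tiny_fit
        import copy

        frozen = copy.copy(draws)
        for name in ("beta0", "sigma_u", "sigma_v", "deviance"):
            arr = getattr(draws, name)
            setattr(frozen, name, np.repeat(arr[:1], draws.n_draws))
        for name in ("cycle", "age", "u", "v"):
            arr = getattr(draws, name)
            setattr(frozen, name, np.repeat(arr[:1], draws.n_draws, axis=0))
        res = mp.dic(frozen, data, spec)
        assert res.effective_parameters == pytest.approx(0.0, abs=1e-8)
        assert res.dic == pytest.approx(res.deviance_at_mean, abs=1e-8)


class TestModelComparison:
    def _mk(self, dic_value, fp="f"):
        from microprev.bym import DicResult

        return DicResult(dic_value, dic_value, 0.0, dic_value, fp)

    def test_threshold_is_strict(self):
        out = mp.compare_models_dic(self._mk(100.0), self._mk(107.0))
        assert not out["meaningful"] and out["preferred"] == "a"

    def test_large_difference_meaningful(self):
        out = mp.compare_models_dic(self._mk(1000.0), self._mk(907.6))
        assert out["meaningful"] and out["preferred"] == "b"
        assert out["difference"] == pytest.approx(-92.4)

    def test_equal_dic_no_preference(self):
        out = mp.compare_models_dic(self._mk(50.0), self._mk(50.0))
        assert out["preferred"] is None and not out["meaningful"]

    def test_fingerprint_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mp.compare_models_dic(self._mk(1.0, "x"), self._mk(2.0, "y"))


class TestPriorSensitivity:
    def test_same_family_gives_identical_fits(self, grid_areas, grid_survey):
        from microprev.bym import fit_bym
        from dataclasses import replace

        spec = mp.ModelSpec(sex_stratum="M", include_income=False)
        data = mp.build_cell_data(grid_survey, grid_areas, spec)
        cfg = mp.MCMCConfig(n_chains=2, burn_in=100, n_keep_iterations=100,
                            thin=2, seed=55)
        a = fit_bym(data, replace(spec, prior_family="gamma_precision"), cfg)
        b = fit_bym(data, replace(spec, prior_family="gamma_precision"), cfg)
        assert np.array_equal(a.u + a.v, b.u + b.v)

    def test_two_arm_report(self, grid_areas, grid_survey):
        spec = mp.ModelSpec(sex_stratum="M", include_income=False)
        data = mp.build_cell_data(grid_survey, grid_areas, spec)
        cfg = mp.MCMCConfig(n_chains=2, burn_in=600, n_keep_iterations=600,
                            thin=2, seed=56)
        rep = mp.prior_sensitivity(data, spec, cfg)
        assert rep["max_abs_difference"] >= 0
        # well-identified area effects barely move across hyperprior families
        assert rep["max_relative_difference"] < 1.5


class TestModelTwoIncomeHandling:
    def test_missing_income_areas_dropped_and_flagged(self, grid_areas,
                                                      grid_survey):
        spec = mp.ModelSpec(sex_stratum="M", include_income=True)
        data = mp.build_cell_data(grid_survey, grid_areas, spec)
        missing = {a for a, ar in grid_areas.items() if ar.median_income is None}
        assert missing
        assert missing <= set(data.dropped_area_ids)
        assert not missing & set(data.area_ids)
        # model 1 keeps every area
        data1 = mp.build_cell_data(
            grid_survey, grid_areas,
            mp.ModelSpec(sex_stratum="M", include_income=False))
        assert missing <= set(data1.area_ids)
        # same survey -> same fingerprint, so DIC comparison is allowed
        assert data.fingerprint == data1.fingerprint
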