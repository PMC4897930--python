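import numpy as np
import pytest
from hypothesis import settings

import microprev as mp

settings.register_profile("ci", max_examples=50, deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid_areas():
    """6x6 queen lattice with census and (partially suppressed) income."""
    areas = mp.make_geography(6, 6, "queen", seed=11)
    mp.simulate_census(areas, seed=12)
    mp.simulate_income(areas, missing_fraction=0.05, seed=13)
    return areas


@pytest.fixture(scope="session")
def grid_truth(grid_areas):
    return mp.make_ground_truth(grid_areas, seed=14)


@pytest.fixture(scope="session")
def grid_survey(grid_areas, grid_truth):
    return mp.simulate_survey(
        grid_areas, grid_truth, n_cycles=5, sampling_rate=0.06,
        n_bootstrap=50, seed=15,
    )


@pytest.fixture(scope="session")
def tiny_fit(grid_areas, grid_survey):
    """One small model-1 fit shared by poststrat/surveillance/diagnostic tests."""
    spec = mp.ModelSpec(outcome="current_smoking", sex_stratum="M",
                        include_income=False)
    data = mp.build_cell_data(grid_survey, grid_areas, spec)
    config = mp.MCMCConfig(n_chains=2, burn_in=600, n_keep_iterations=600,
                           thin=2, seed=16)
    return mp.fit_bym(data, spec, config), data, spec


def make_tiny_instance(seed=0, n_respondents=8, include_income=True):
    """2x2 rook geography with a handful of respondents, for oracle checks."""
    rng = np.random.default_rng(seed)
    areas = mp.make_geography(2, 2, "rook", seed=seed)
    mp.simulate_census(areas, mean_pop=100, seed=seed + 1)
    mp.simulate_income(areas, seed=seed + 2)
    truth = mp.make_ground_truth(areas, seed=seed + 3,
                                 cycle_effects=np.array([0.0, -0.1]))
    resp = mp.simulate_survey(areas, truth, n_cycles=2, sampling_rate=0.5,
                              n_bootstrap=0, seed=seed + 4)
    resp = resp[resp["sex"] == "M"]
    resp = resp.sample(n=n_respondents, random_state=int(rng.integers(2**31)))
    return areas, resp.reset_index(drop=True)
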