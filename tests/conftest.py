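import numpy as np
import pandas as pd
import pytest

import multikern as mk


def small_sim_config(seed=3, **overrides):
    """A reduced three-year trial: same structure as the default design,
    scaled to sizes that keep mixed-model and MCMC fits fast."""
    params = dict(
        n_lines_per_year={"2021": 60, "2022": 50, "2023": 40},
        n_overlap={("2021", "2022"): 12, ("2022", "2023"): 10,
                   ("2021", "2023"): 5, ("2021", "2022", "2023"): 3},
        n_markers=400,
        n_bands=16,
        blocks_per_rep=5,
        seed=seed,
    )
    params.update(overrides)
    return mk.SimConfig(**params)


def single_year_config(n_lines=120, seed=0, **overrides):
    params = dict(
        n_lines_per_year={"2021": n_lines},
        n_overlap={},
        n_markers=300,
        n_bands=12,
        blocks_per_rep=5,
        var_gxe=0.0,   # meaningless with a single environment
        var_year=0.0,
        seed=seed,
    )
    params.update(overrides)
    return mk.SimConfig(**params)


@pytest.fixture(scope="session")
def small_dataset():
    cfg = small_sim_config()
    markers, plots, weather, truth = mk.simulate_dataset(cfg)
    return cfg, markers, plots, weather, truth


@pytest.fixture(scope="session")
def prepared(small_dataset):
    _, markers, plots, weather, _ = small_dataset
    return mk.prepare_dataset(markers, plots, weather)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
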