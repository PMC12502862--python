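import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import drivenchain as dc
from drivenchain.config import PROFILES
from drivenchain.dataset import build_dataset, sample_parameters, split_dataset
from drivenchain.gpr import evaluate_inversion, fit_inversion
from drivenchain.scattering import make_q_grid

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """Tiny end-to-end dataset (6 rows, N=12, 11x11 grid) for contract tests."""
    grid = make_q_grid(11, 10 * np.pi / 12)
    schedule = dc.MCSchedule(100, 100, 10, seed=0)
    params = sample_parameters(6, seed=5)
    return build_dataset(params, 12, schedule, grid, seed=5)


@pytest.fixture(scope="session")
def desk_dataset():
    """The scaled-down study: 240 rows, N=50, 21x21 grid with spacing 2*pi/L,
    200 approximately independent configurations averaged per map."""
    cfg = PROFILES["desk"]
    n_bonds = cfg["n_bonds"]
    grid = make_q_grid(cfg["grid_n"], cfg["q_max_factor"] * np.pi / n_bonds)
    schedule = dc.MCSchedule(
        cfg["schedule"]["n_equilibration_sweeps"],
        cfg["schedule"]["n_sample_sweeps"],
        cfg["schedule"]["sample_interval"],
    )
    params = sample_parameters(cfg["n_samples"], seed=0)
    return build_dataset(params, n_bonds, schedule, grid, seed=0)


@pytest.fixture(scope="session")
def desk_split(desk_dataset):
    return split_dataset(desk_dataset, 0.7, seed=11)


@pytest.fixture(scope="session")
def desk_inversion(desk_split):
    """Trained per-target GP regressors plus their held-out evaluation."""
    train, test = desk_split
    models = fit_inversion(train, n_restarts=5, random_state=0)
    report = evaluate_inversion(models, test)
    return models, report
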