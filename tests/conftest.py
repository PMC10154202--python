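import numpy as np
import pytest

from macroqs.param_estimation import AreaSeries
from macroqs.stochastic_quorum import QSParams, find_threshold_density
from macroqs.synthetic_data import (
    RECOVERY_DENSITIES,
    TIMELAPSE_DISH_AREA_CM2,
    generate_timelapse,
    seed_dish,
    timelapse_params,
)


@pytest.fixture(scope="session")
def measured_params() -> QSParams:
    """The experimentally measured parameter set of the stochastic model
    (10-cm dish, 10 ml of medium)."""
    return QSParams()


@pytest.fixture(scope="session")
def recovery_dataset():
    """Synthetic time-lapse dishes across the full seeding-density range,
    generated with the measured rates as ground truth.

    Returns (series, params): one AreaSeries per seeding density under the
    time-lapse culture condition (6-cm dish, 4 ml), hourly frames, 96 h.
    """
    params = timelapse_params()
    series = []
    for i, density in enumerate(RECOVERY_DENSITIES):
        seeding = seed_dish(density, dish_area_cm2=TIMELAPSE_DISH_AREA_CM2, seed=100 + i)
        exp = generate_timelapse(seeding, params, horizon=96.0, seed=200 + i)
        series.append(exp.to_area_series())
    return series, params


@pytest.fixture(scope="session")
def threshold_10ml(measured_params):
    """Bisected threshold density under the measured parameters."""
    return find_threshold_density(measured_params, n_reps=10, seed=1)


def pure_death_series(gamma: float, A0: float = 1e6, hours: int = 96,
                      density: float = 500.0) -> AreaSeries:
    """Analytic area record of a pure-death population: alive area
    A0 e^{-gamma t}, cumulative dead area A0 (1 - e^{-gamma t})."""
    t = np.arange(hours + 1, dtype=float)
    alive = A0 * np.exp(-gamma * t)
    dead = A0 * (1.0 - np.exp(-gamma * t))
    return AreaSeries(times=t, total_alive_area=alive,
                      cumulative_dead_area=dead, initial_density=density)
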