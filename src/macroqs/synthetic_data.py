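"""Synthetic microscopy-style data with the statistical structure of
sparsely seeded differentiation dishes.

The generator emulates the observational design the rate-fitting module
assumes: cells seeded uniformly at random across a culture dish as small
microcolonies (1-3 cells each by default, ~80 um^2 per cell, well under
1% dish coverage at the densities studied), followed by hourly time-lapse
"imaging" over 96 h in fields of view of 1,399.16 um x 994.95 um.  Every
colony on a dish evolves by the stochastic quorum model's binomial
birth/death rules while sharing a single well-mixed survival-factor
concentration (the well-mixed assumption holds because the factor's
diffusion length far exceeds both colony sizes and colony spacing).
Dead cells detach: each death adds one mean cell area to the cumulative
dead-area record, and a colony whose count reaches zero is marked
detached.  Ground-truth parameters are always emitted next to the data so
estimation can close the loop.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd

from .stochastic_quorum import QSParams, replication_probability

__all__ = [
    "DishSeeding",
    "SyntheticExperiment",
    "NearestNeighborStats",
    "seed_dish",
    "nearest_neighbor_stats",
    "generate_timelapse",
    "generate_factor_series",
    "timelapse_params",
    "TIMELAPSE_DENSITIES",
    "write_seeding_csv",
    "read_seeding_csv",
    "write_timelapse_csv",
    "read_timelapse_csv",
    "write_factor_csv",
    "read_factor_csv",
    "write_ground_truth_json",
]

#: field-of-view dimensions of the time-lapse microscope, um
FOV_WIDTH_UM = 1399.16
FOV_HEIGHT_UM = 994.95

#: mean footprint of one cell, um^2 (10-um-diameter disk, rounded)
DEFAULT_CELL_AREA_UM2 = 80.0

#: growth area of a 6-cm-diameter dish (the time-lapse dish), cm^2
TIMELAPSE_DISH_AREA_CM2 = math.pi * 3.0**2
#: medium volume used for time-lapse dishes, ml
TIMELAPSE_VOLUME_ML = 4.0

#: initial densities monitored by time-lapse imaging, cells/cm^2
TIMELAPSE_DENSITIES = (455, 818, 1227, 1636, 2045, 2727, 3409, 4091)

#: seeding densities for parameter-recovery studies, cells/cm^2: the
#: time-lapse densities extended to the top of the seeding range the
#: growth experiments covered.  The maximum replication probability is
#: only identifiable at densities high enough for the factor
#: concentration to saturate (M >> K_half) within the imaging window.
RECOVERY_DENSITIES = TIMELAPSE_DENSITIES + (8621, 15517)


def timelapse_params(**overrides) -> QSParams:
    """Model parameters matching the time-lapse culture condition
    (6-cm dish, 4 ml of medium)."""
    kwargs = dict(V=TIMELAPSE_VOLUME_ML, dish_area=TIMELAPSE_DISH_AREA_CM2)
    kwargs.update(overrides)
    return QSParams(**kwargs)


@dataclass(frozen=True)
class DishSeeding:
    """A sparsely seeded dish: uniform random colony positions (cm, dish
    centered at the origin) with per-colony initial cell counts."""

    dish_area_cm2: float
    positions_cm: np.ndarray  # (n, 2)
    cells0: np.ndarray        # (n,) int
    mean_cell_area_um2: float
    density_label: float      # seeded cells/cm^2

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_cm, dtype=float)
        c0 = np.asarray(self.cells0)
        if pos.ndim != 2 or pos.shape[1] != 2 or pos.shape[0] != c0.shape[0]:
            raise ValueError("positions must be (n, 2) and match cells0")
        if np.any(c0 < 1):
            raise ValueError("every colony starts with at least 1 cell")
        radius = math.sqrt(self.dish_area_cm2 / math.pi)
        if np.any(np.hypot(pos[:, 0], pos[:, 1]) > radius * (1 + 1e-9)):
            raise ValueError("colony positions must lie inside the dish")
        object.__setattr__(self, "positions_cm", pos)
        object.__setattr__(self, "cells0", c0.astype(np.int64))

    @property
    def n_colonies(self) -> int:
        return int(self.cells0.shape[0])

    @property
    def area0_um2(self) -> np.ndarray:
        return self.cells0 * self.mean_cell_area_um2

    @property
    def coverage_fraction(self) -> float:
        """Fraction of the dish covered by cells (um^2 over cm^2)."""
        return float(self.area0_um2.sum() * 1e-8 / self.dish_area_cm2)

    def field_ids(self) -> np.ndarray:
        """Tile the dish with microscope fields of view and assign each
        colony the index of the field containing it."""
        radius_um = math.sqrt(self.dish_area_cm2 / math.pi) * 1e4
        x = self.positions_cm[:, 0] * 1e4 + radius_um
        y = self.positions_cm[:, 1] * 1e4 + radius_um
        n_cols = int(math.ceil(2 * radius_um / FOV_WIDTH_UM))
        fx = np.floor(x / FOV_WIDTH_UM).astype(np.int64)
        fy = np.floor(y / FOV_HEIGHT_UM).astype(np.int64)
        return fy * n_cols + fx


def seed_dish(
    density: float,
    dish_area_cm2: float = 78.54,
    cells_per_colony: tuple[int, int] = (1, 3),
    mean_cell_area_um2: float = DEFAULT_CELL_AREA_UM2,
    seed: int | np.random.Generator = 0,
) -> DishSeeding:
    """Seed a dish at the given density (cells/cm^2).

    Colony positions are uniform over the (disk-shaped) dish; initial
    colony sizes are uniform integers in ``cells_per_colony`` (the
    near-single-cell seeding regime).  The colony count is
    round(density * area / mean cells per colony).  Densities implying
    more than full coverage are rejected.
    """
    if not density >= 0:
        raise ValueError("density must be nonnegative")
    coverage = density * mean_cell_area_um2 * 1e-8
    if coverage > 1.0:
        raise ValueError(
            f"density {density:g} cells/cm^2 implies {coverage:.0%} dish coverage"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = cells_per_colony
    mean_cells = 0.5 * (lo + hi)
    n = int(round(density * dish_area_cm2 / mean_cells))
    radius = math.sqrt(dish_area_cm2 / math.pi)
    r = radius * np.sqrt(rng.random(n))
    theta = rng.random(n) * 2.0 * math.pi
    positions = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    cells0 = rng.integers(lo, hi + 1, size=n) if n else np.zeros(0, dtype=np.int64)
    return DishSeeding(
        dish_area_cm2=dish_area_cm2,
        positions_cm=positions,
        cells0=cells0,
        mean_cell_area_um2=mean_cell_area_um2,
        density_label=density,
    )


@dataclass(frozen=True)
class NearestNeighborStats:
    """Nearest-neighbor colony distances; for uniform (Poisson-like)
    seeding at colony density rho per cm^2 the mean is ~ 1/(2 sqrt(rho))."""

    distances_um: np.ndarray

    @property
    def mean_um(self) -> float:
        return float(self.distances_um.mean())


def nearest_neighbor_stats(seeding: DishSeeding) -> NearestNeighborStats:
    """Exact nearest-neighbor distances (um) via a spatial index."""
    if seeding.n_colonies < 2:
        raise ValueError("need at least 2 colonies for nearest-neighbor distances")
    from scipy.spatial import cKDTree

    tree = cKDTree(seeding.positions_cm)
    dists, _ = tree.query(seeding.positions_cm, k=2)
    return NearestNeighborStats(distances_um=dists[:, 1] * 1e4)


@dataclass(frozen=True)
class SyntheticExperiment:
    """Full synthetic time-lapse: per-colony counts at 1-h frames, the
    shared factor concentration, and the cumulative dead-area record,
    plus the ground-truth parameters used."""

    seeding: DishSeeding
    params: QSParams
    times: np.ndarray                # hours, (T+1,)
    counts: np.ndarray               # (T+1, n_colonies) int
    M: np.ndarray                    # (T+1,)
    cumulative_dead_area_um2: np.ndarray  # (T+1,)
    seed: int | None = None

    @property
    def areas_um2(self) -> np.ndarray:
        return self.counts * self.seeding.mean_cell_area_um2

    @property
    def total_alive_area_um2(self) -> np.ndarray:
        return self.areas_um2.sum(axis=1)

    def to_timelapse_frame(self) -> pd.DataFrame:
        """Long-format table (time_h, field_id, colony_id, area_um2,
        status) mirroring a per-frame colony-area extraction."""
        T1, n = self.counts.shape
        fields = self.seeding.field_ids()
        frame = pd.DataFrame({
            "time_h": np.repeat(self.times, n),
            "field_id": np.tile(fields, T1),
            "colony_id": np.tile(np.arange(n), T1),
            "area_um2": self.areas_um2.reshape(-1).astype(float),
        })
        frame["status"] = np.where(frame["area_um2"] > 0, "alive", "detached")
        return frame

    def to_area_series(self):
        """Collapse to the AreaSeries the fitting module consumes."""
        from .param_estimation import AreaSeries

        return AreaSeries(
            times=self.times,
            total_alive_area=self.total_alive_area_um2.astype(float),
            cumulative_dead_area=self.cumulative_dead_area_um2.astype(float),
            initial_density=self.seeding.density_label,
        )

    def ground_truth(self) -> dict:
        gt = asdict(self.params)
        gt.update(
            mean_cell_area_um2=self.seeding.mean_cell_area_um2,
            density_label=self.seeding.density_label,
            seed=self.seed,
        )
        return gt


def generate_timelapse(
    seeding: DishSeeding,
    params: QSParams,
    horizon: float = 96.0,
    seed: int | np.random.SeedSequence = 0,
) -> SyntheticExperiment:
    """Evolve every colony on a dish under the shared-concentration model.

    All colonies feel one dish-level concentration M_t (well-mixed).  Per
    step, each colony's births and deaths are binomial draws on its own
    count; each dead cell detaches, adding one mean cell area to the
    cumulative dead area.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    n_steps = int(round(horizon / params.dt))
    n = seeding.n_colonies
    times = np.arange(n_steps + 1, dtype=float) * params.dt
    counts = np.zeros((n_steps + 1, n), dtype=np.int64)
    M = np.zeros(n_steps + 1)
    dead_area = np.zeros(n_steps + 1)
    counts[0] = seeding.cells0
    current = seeding.cells0.copy()
    M_now = 0.0
    cell_area = seeding.mean_cell_area_um2
    for k in range(1, n_steps + 1):
        p_mu = replication_probability(params, M_now)
        births = rng.binomial(current, p_mu)
        deaths = rng.binomial(current, params.gamma)
        M_now = current.sum() / params.V + params.d * M_now
        current = current + births - deaths  # never negative: deaths <= current
        counts[k] = current
        M[k] = M_now
        dead_area[k] = dead_area[k - 1] + deaths.sum() * cell_area
    return SyntheticExperiment(
        seeding=seeding, params=params, times=times, counts=counts,
        M=M, cumulative_dead_area_um2=dead_area,
        seed=seed if isinstance(seed, int) else None,
    )


def generate_factor_series(
    N,
    params: QSParams,
    n_steps: int | None = None,
    M0: float = 0.0,
    noise_cv: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterate the factor-accumulation rule M_{t+1} = N_t/V + d*M_t.

    ``N`` is a constant cell count or a per-step trajectory.  With a
    constant N the series follows the closed form
    M_t = (N/V)(1-d^t)/(1-d) + d^t M0.  ``noise_cv`` adds multiplicative
    Gaussian measurement noise (immunoassay emulation); the noiseless
    series is returned when it is 0.
    """
    if n_steps is None:
        if np.isscalar(N):
            raise ValueError("n_steps required for a constant N")
        n_steps = len(np.asarray(N)) - 1
    N_arr = np.full(n_steps, float(N)) if np.isscalar(N) else np.asarray(N, dtype=float)[:n_steps]
    times = np.arange(n_steps + 1, dtype=float) * params.dt
    M = np.zeros(n_steps + 1)
    M[0] = M0
    for t in range(n_steps):
        M[t + 1] = N_arr[t] / params.V + params.d * M[t]
    if noise_cv > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        M = np.clip(M * (1.0 + noise_cv * rng.standard_normal(M.shape)), 0.0, None)
    return times, M


# ---------------------------------------------------------------------------
# plain-text round-trip IO

def write_seeding_csv(seeding: DishSeeding, path) -> None:
    pd.DataFrame({
        "colony_id": np.arange(seeding.n_colonies),
        "x_cm": seeding.positions_cm[:, 0],
        "y_cm": seeding.positions_cm[:, 1],
        "cells0": seeding.cells0,
        "area0_um2": seeding.area0_um2.astype(float),
    }).to_csv(path, index=False, float_format="%.17g")


def read_seeding_csv(path, dish_area_cm2: float, mean_cell_area_um2: float,
                     density_label: float = float("nan")) -> DishSeeding:
    df = pd.read_csv(path, float_precision="round_trip")
    return DishSeeding(
        dish_area_cm2=dish_area_cm2,
        positions_cm=df[["x_cm", "y_cm"]].to_numpy(),
        cells0=df["cells0"].to_numpy(),
        mean_cell_area_um2=mean_cell_area_um2,
        density_label=density_label,
    )


def write_timelapse_csv(experiment: SyntheticExperiment, path) -> None:
    experiment.to_timelapse_frame().to_csv(path, index=False, float_format="%.17g")


def read_timelapse_csv(path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        float_precision="round_trip",
        dtype={"time_h": "float64", "area_um2": "float64"},
    )


def write_factor_csv(times: np.ndarray, M: np.ndarray, path) -> None:
    pd.DataFrame({"time_h": times, "M": M}).to_csv(path, index=False, float_format="%.17g")


def read_factor_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip",
                       dtype={"time_h": "float64", "M": "float64"})


def write_ground_truth_json(experiment: SyntheticExperiment, path) -> None:
    with open(path, "w") as fh:
        json.dump(experiment.ground_truth(), fh, indent=2, sort_keys=True)
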