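"""Stochastic quorum-sensing model of collective survival.

A population of N_t cells (t in 1-hour steps) secretes a survival factor
into a well-mixed liquid volume V.  The factor concentration M_t, measured
in units of the per-cell secretion rate (secretion is 1/V per cell per
step), obeys

    M_{t+1} = N_t / V + d * M_t,        M_0 = 0,

where d in [0, 1] is the per-step retention (degradation) factor.  Each
cell replicates with probability

    P_mu(t) = mu * M_t / (K_half + M_t)

and dies with constant probability gamma, so per step

    R_t ~ Binom(N_t, P_mu(t)),   D_t ~ Binom(N_t, gamma),
    N_{t+1} = N_t + R_t - D_t.

Replication balances death at the threshold concentration
M* = K_half * gamma / (mu - gamma).  Because M_0 = 0, a population must
survive on its initial numbers long enough to accumulate an
above-threshold concentration: this produces an Allee-type threshold in
the *initial density*, and near it the outcome is genuinely random.
There is no carrying capacity in this model; "expansion" is defined by
fold change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "QSParams",
    "PopState",
    "PopTrajectory",
    "EnsembleResult",
    "ThresholdResult",
    "PhaseDiagram",
    "replication_probability",
    "step",
    "simulate_population",
    "simulate_fixed_concentration",
    "simulate_ensemble",
    "classify_outcome",
    "extinction_fraction",
    "find_threshold_density",
    "phase_diagram",
]

#: nominal growth area of a 10-cm-diameter culture dish, cm^2
DEFAULT_DISH_AREA_CM2 = 78.54

EXTINCT = "extinct"
EXPANDED = "expanded"
UNDECIDED = "undecided"


@dataclass(frozen=True)
class QSParams:
    """Parameters of the stochastic quorum-sensing model.

    Attributes
    ----------
    mu : float
        Maximum replication probability per 1-h step.
    gamma : float
        Death probability per 1-h step (constant, factor-independent).
    K_half : float
        Half-saturation concentration of the survival factor, in units of
        the per-cell secretion rate.  Distinct from any carrying capacity.
    V : float
        Liquid medium volume, ml.
    d : float
        Per-step retention factor in [0, 1] (1 = permanently stable
        factor, 0 = fully degraded each step).
    dt : float
        Timestep, hours.  The model is calibrated with 1-h steps;
        probabilities are per-step, not rates.
    dish_area : float
        Growth area, cm^2, used only to convert counts <-> densities.
    """

    mu: float = 0.052
    gamma: float = 0.023
    K_half: float = 4.85e5
    V: float = 10.0
    d: float = 0.99
    dt: float = 1.0
    dish_area: float = DEFAULT_DISH_AREA_CM2

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must be a probability in [0, 1]")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be a probability in [0, 1]")
        if not 0.0 <= self.d <= 1.0:
            raise ValueError("d must lie in [0, 1]")
        if not self.K_half > 0:
            raise ValueError("K_half must be positive")
        if not self.V > 0:
            raise ValueError("V must be positive")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if not self.dish_area > 0:
            raise ValueError("dish_area must be positive")

    @property
    def threshold_concentration(self) -> float:
        """Concentration at which P_mu = gamma; infinite if mu <= gamma."""
        if self.mu <= self.gamma:
            return math.inf
        return self.K_half * self.gamma / (self.mu - self.gamma)

    def cells_from_density(self, density: float) -> int:
        """Convert a density (cells/cm^2) to a whole-dish cell count."""
        return int(round(density * self.dish_area))

    def density_from_cells(self, n: float) -> float:
        return n / self.dish_area


@dataclass(frozen=True)
class PopState:
    """State of one population at integer timestep t: alive count N,
    factor concentration M, and the last birth/death draws R and D."""

    t: int
    N: int
    M: float
    R: int | None = None
    D: int | None = None

    def __post_init__(self) -> None:
        if self.N < 0:
            raise ValueError("N must be a nonnegative integer")
        if self.M < 0:
            raise ValueError("M must be nonnegative")


@dataclass(frozen=True)
class PopTrajectory:
    """Hourly trajectory of one simulated population."""

    times: np.ndarray  # hours
    N: np.ndarray      # alive cells, int64
    M: np.ndarray      # factor concentration, units of secretion rate

    def fold_change(self, t: float) -> float:
        if self.N[0] == 0:
            raise ValueError("fold change undefined for N0 = 0")
        idx = int(np.searchsorted(self.times, t))
        if idx >= len(self.times) or self.times[idx] != t:
            raise ValueError(f"time {t} h not on the report grid")
        return float(self.N[idx]) / float(self.N[0])


def replication_probability(params: QSParams, M):
    """P_mu = mu * M / (K_half + M); saturating, in [0, mu]."""
    M_arr = np.asarray(M, dtype=float)
    if np.any(M_arr < 0):
        raise ValueError("concentration M must be nonnegative")
    out = params.mu * M_arr / (params.K_half + M_arr)
    return float(out) if np.isscalar(M) else out


def step(params: QSParams, state: PopState, rng: np.random.Generator) -> PopState:
    """Advance one timestep.

    Births and deaths are independent binomial draws on the same N_t; the
    concentration update uses the pre-update count N_t.  N is clamped at
    zero in the (extreme) event D_t - R_t > N_t.
    """
    p_mu = replication_probability(params, state.M)
    R = int(rng.binomial(state.N, p_mu))
    D = int(rng.binomial(state.N, params.gamma))
    N_next = max(state.N + R - D, 0)
    M_next = state.N / params.V + params.d * state.M
    return PopState(t=state.t + 1, N=N_next, M=M_next, R=R, D=D)


def simulate_population(
    params: QSParams,
    N0: int,
    horizon: float,
    seed: int | np.random.Generator | np.random.SeedSequence = 0,
) -> PopTrajectory:
    """Simulate one population for ``horizon`` hours at 1-h resolution.

    Deterministic given the seed.  Counts are held in int64 and are safe
    well beyond 1e9 cells.
    """
    if N0 < 0 or int(N0) != N0:
        raise ValueError("N0 must be a nonnegative integer")
    rng = np.random.default_rng(seed)
    n_steps = int(round(horizon / params.dt))
    times = np.arange(n_steps + 1, dtype=float) * params.dt
    N = np.zeros(n_steps + 1, dtype=np.int64)
    M = np.zeros(n_steps + 1, dtype=float)
    state = PopState(t=0, N=int(N0), M=0.0)
    N[0] = state.N
    for k in range(1, n_steps + 1):
        state = step(params, state, rng)
        N[k] = state.N
        M[k] = state.M
    return PopTrajectory(times=times, N=N, M=M)


def simulate_fixed_concentration(
    params: QSParams,
    N0: int,
    M_fixed: float,
    horizon: float,
    seed: int | np.random.Generator | np.random.SeedSequence = 0,
) -> PopTrajectory:
    """Reference mode with the concentration held fixed at ``M_fixed``.

    With M frozen the population is a Galton-Watson-like branching
    process with constant per-step birth probability P_mu(M_fixed) and
    death probability gamma, so E[N_t] = N0 (1 + P_mu - gamma)^t.  Used
    for calibration checks; the full model couples M to the population.
    """
    if N0 < 0 or int(N0) != N0:
        raise ValueError("N0 must be a nonnegative integer")
    rng = np.random.default_rng(seed)
    p_mu = replication_probability(params, M_fixed)
    n_steps = int(round(horizon / params.dt))
    times = np.arange(n_steps + 1, dtype=float) * params.dt
    N = np.zeros(n_steps + 1, dtype=np.int64)
    N[0] = int(N0)
    for k in range(1, n_steps + 1):
        R = rng.binomial(N[k - 1], p_mu)
        D = rng.binomial(N[k - 1], params.gamma)
        N[k] = max(N[k - 1] + R - D, 0)
    return PopTrajectory(times=times, N=N, M=np.full(n_steps + 1, float(M_fixed)))


@dataclass(frozen=True)
class EnsembleResult:
    """Replicate trajectories plus per-replicate outcome labels and the
    extinction fraction as a function of time."""

    trajectories: list[PopTrajectory]
    labels: list[str]
    times: np.ndarray
    extinct_fraction_vs_time: np.ndarray

    @property
    def extinction_fraction(self) -> float:
        return sum(lab == EXTINCT for lab in self.labels) / len(self.labels)


def simulate_ensemble(
    params: QSParams,
    N0: int,
    horizon: float,
    n_reps: int,
    seed: int | np.random.SeedSequence = 0,
    horizon_days: float = 6.0,
) -> EnsembleResult:
    """Run ``n_reps`` replicate populations from one root seed.

    Each replicate uses its own child stream of the root seed, so the
    ensemble is reproducible and replicates are independent.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_reps)
    trajs = [simulate_population(params, N0, horizon, child) for child in children]
    labels = [classify_outcome(tr, horizon_days=horizon_days) for tr in trajs]
    times = trajs[0].times
    # a replicate counts as extinct from the first time its fold change
    # drops below the extinction cut (0.6), or immediately if N0 = 0
    frac = np.zeros_like(times)
    for tr in trajs:
        if tr.N[0] == 0:
            frac += 1.0
            continue
        below = tr.N < 0.6 * tr.N[0]
        if below.any():
            frac[np.argmax(below):] += 1.0
    frac /= n_reps
    return EnsembleResult(trajs, labels, times, frac)


def classify_outcome(traj: PopTrajectory, horizon_days: float = 6.0) -> str:
    """Label a trajectory ``extinct``, ``expanded`` or ``undecided``.

    ``extinct``: fold change below 0.6 at day ``horizon_days``;
    ``expanded``: fold change above 1 at the horizon end and still
    increasing there (nonnegative trend over the trailing 24 h);
    otherwise ``undecided``.
    """
    if traj.N[0] == 0:
        return EXTINCT
    t_cut = horizon_days * 24.0
    if traj.times[-1] < t_cut:
        raise ValueError("trajectory does not cover the classification horizon")
    if traj.fold_change(t_cut) < 0.6:
        return EXTINCT
    fold_end = float(traj.N[-1]) / float(traj.N[0])
    tail = max(0, len(traj.N) - 1 - int(round(24.0 / traj_dt(traj))))
    still_rising = traj.N[-1] >= traj.N[tail]
    if fold_end > 1.0 and still_rising:
        return EXPANDED
    return UNDECIDED


def traj_dt(traj: PopTrajectory) -> float:
    return float(traj.times[1] - traj.times[0]) if len(traj.times) > 1 else 1.0


def extinction_fraction(
    params: QSParams,
    N0: int,
    n_reps: int,
    horizon: float,
    seed: int | np.random.SeedSequence = 0,
    horizon_days: float = 6.0,
) -> float:
    """Fraction of replicates labeled extinct by the horizon."""
    res = simulate_ensemble(params, N0, horizon, n_reps, seed, horizon_days=horizon_days)
    return res.extinction_fraction


@dataclass(frozen=True)
class ThresholdResult:
    """Bisection estimate of the threshold initial density (cells/cm^2):
    the density at which the extinction fraction crosses 50%."""

    density: float
    bracket_low: float
    bracket_high: float
    n_reps: int

    def __float__(self) -> float:
        return self.density


def find_threshold_density(
    params: QSParams,
    bounds: tuple[float, float] = (50.0, 30000.0),
    n_reps: int = 10,
    horizon: float = 144.0,
    seed: int | np.random.SeedSequence = 0,
    rel_resolution: float = 0.02,
    max_iter: int = 20,
) -> ThresholdResult:
    """Bisect on initial density for the 50% extinction crossing.

    Requires mu > gamma (otherwise no density can sustain growth) and a
    bracket whose low end is extinction-dominated and high end is
    survival-dominated; a degenerate bracket (both ends on the same side
    of 50%) raises a ValueError naming the measured fractions.
    """
    if params.mu <= params.gamma:
        raise ValueError("mu must exceed gamma for a finite threshold to exist")
    if params.gamma == 0:
        return ThresholdResult(0.0, 0.0, 0.0, n_reps)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    lo, hi = bounds

    def frac(density: float, child: np.random.SeedSequence) -> float:
        N0 = params.cells_from_density(density)
        return extinction_fraction(params, N0, n_reps, horizon, child)

    children = iter(ss.spawn(max_iter + 2))
    f_lo = frac(lo, next(children))
    f_hi = frac(hi, next(children))
    if not (f_lo >= 0.5 > f_hi):
        raise ValueError(
            "degenerate threshold bracket: extinction fraction is "
            f"{f_lo:.2f} at {lo:g} cells/cm^2 and {f_hi:.2f} at {hi:g} cells/cm^2"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if (hi - lo) <= rel_resolution * mid:
            break
        if frac(mid, next(children)) >= 0.5:
            lo = mid
        else:
            hi = mid
    return ThresholdResult(0.5 * (lo + hi), lo, hi, n_reps)


@dataclass(frozen=True)
class PhaseDiagram:
    """Survival/extinction phase diagram over (volume, initial density).

    ``conditions`` is a DataFrame with columns ``V_ml``,
    ``density_cells_per_cm2`` and ``label`` (always_survives /
    always_extinct / both_possible); ``boundary`` maps each volume to its
    bisected threshold density.
    """

    conditions: "object"  # pandas.DataFrame
    boundary: "object"    # pandas.DataFrame with V_ml, threshold_density


ALWAYS_SURVIVES = "always_survives"
ALWAYS_EXTINCT = "always_extinct"
BOTH_POSSIBLE = "both_possible"


def phase_diagram(
    params_base: QSParams,
    V_list,
    density_list,
    n_reps: int = 8,
    horizon: float = 144.0,
    seed: int | np.random.SeedSequence = 0,
    threshold_bounds: tuple[float, float] = (50.0, 60000.0),
) -> PhaseDiagram:
    """Label every (V, initial density) condition and fit the boundary.

    Eight replicate simulations per condition by default: a condition is
    ``always_extinct`` if all replicates go extinct, ``always_survives``
    if all expand, and ``both_possible`` otherwise.  The boundary is the
    per-volume 50% extinction density from :func:`find_threshold_density`.
    """
    import pandas as pd

    V_list = list(V_list)
    density_list = list(density_list)
    if not V_list or not density_list:
        raise ValueError("V_list and density_list must be nonempty")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    grid_ss, boundary_ss = ss.spawn(2)
    grid_children = iter(grid_ss.spawn(len(V_list) * len(density_list)))

    rows = []
    for V in V_list:
        params = replace(params_base, V=V)
        for density in density_list:
            N0 = params.cells_from_density(density)
            res = simulate_ensemble(params, N0, horizon, n_reps, next(grid_children))
            n_ext = sum(lab == EXTINCT for lab in res.labels)
            n_exp = sum(lab == EXPANDED for lab in res.labels)
            if n_ext == n_reps:
                label = ALWAYS_EXTINCT
            elif n_exp == n_reps:
                label = ALWAYS_SURVIVES
            else:
                label = BOTH_POSSIBLE
            rows.append({"V_ml": V, "density_cells_per_cm2": density, "label": label})

    boundary_rows = []
    for V, child in zip(V_list, boundary_ss.spawn(len(V_list))):
        params = replace(params_base, V=V)
        thr = find_threshold_density(
            params, bounds=threshold_bounds, n_reps=n_reps, horizon=horizon, seed=child
        )
        boundary_rows.append({"V_ml": V, "threshold_density": thr.density})

    return PhaseDiagram(
        conditions=pd.DataFrame(rows),
        boundary=pd.DataFrame(boundary_rows),
    )
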