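"""Phenomenological growth laws for autonomous and collective cell populations.

Three continuum scenarios are modeled, all built on the logistic equation

    dN/dt = (1 - N/K_cap) * r(N) * N

with time in hours and N a continuous population size (or density):

* ``autonomous`` — r(N) = r, a constant: every population grows to the
  carrying capacity K_cap.
* ``collective_no_threshold`` — r(N) = mu_max*N/(K_M + N) + r0 with r0 > 0:
  cells help each other replicate via secreted molecules, so larger
  populations grow faster, but even an isolated cell has positive net
  growth and every population survives.
* ``collective_with_threshold`` — same hyperbolic r(N) but with r0 < 0 and
  mu_max + r0 > 0: an isolated cell dies on average, and only populations
  above a threshold size N* (where r(N*) = 0) can grow.  This is an
  Allee-type threshold: below N* populations head to extinction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "AUTONOMOUS",
    "COLLECTIVE_NO_THRESHOLD",
    "COLLECTIVE_WITH_THRESHOLD",
    "GrowthLaw",
    "Trajectory",
    "net_growth_rate",
    "threshold_population",
    "integrate",
    "fold_change",
    "logistic_closed_form",
]

AUTONOMOUS = "autonomous"
COLLECTIVE_NO_THRESHOLD = "collective_no_threshold"
COLLECTIVE_WITH_THRESHOLD = "collective_with_threshold"

_KINDS = (AUTONOMOUS, COLLECTIVE_NO_THRESHOLD, COLLECTIVE_WITH_THRESHOLD)


@dataclass(frozen=True)
class GrowthLaw:
    """Parameters of one growth scenario.

    Parameters
    ----------
    kind : str
        One of ``autonomous``, ``collective_no_threshold``,
        ``collective_with_threshold``.
    K_cap : float
        Carrying capacity, cells. Must be positive.
    r : float, optional
        Autonomous net growth rate, per hour (autonomous kind only).
    mu_max : float, optional
        Maximum collective net-growth-rate increase, per hour (collective
        kinds).
    K_M : float, optional
        Population size at which half the maximum collective increase is
        attained, cells (collective kinds).
    r0 : float, optional
        Net growth rate of an isolated cell, per hour. Positive for
        ``collective_no_threshold``; nonpositive (with mu_max + r0 > 0) for
        ``collective_with_threshold``.
    """

    kind: str
    K_cap: float
    r: float | None = None
    mu_max: float | None = None
    K_M: float | None = None
    r0: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown growth-law kind {self.kind!r}")
        if not self.K_cap > 0:
            raise ValueError("carrying capacity K_cap must be positive")
        if self.kind == AUTONOMOUS:
            if self.r is None:
                raise ValueError("autonomous law needs r")
        else:
            if self.mu_max is None or self.K_M is None or self.r0 is None:
                raise ValueError("collective laws need mu_max, K_M and r0")
            if self.mu_max < 0:
                raise ValueError("mu_max must be nonnegative")
            if not self.K_M > 0:
                raise ValueError("K_M must be positive")
            if self.kind == COLLECTIVE_NO_THRESHOLD and not self.r0 > 0:
                raise ValueError("collective_no_threshold requires r0 > 0")
            if self.kind == COLLECTIVE_WITH_THRESHOLD:
                if self.r0 > 0:
                    raise ValueError("collective_with_threshold requires r0 <= 0")
                if not self.mu_max + self.r0 > 0:
                    raise ValueError(
                        "collective_with_threshold requires mu_max + r0 > 0 "
                        "(otherwise no interior threshold exists)"
                    )

    @classmethod
    def autonomous(cls, r: float, K_cap: float) -> "GrowthLaw":
        return cls(kind=AUTONOMOUS, K_cap=K_cap, r=r)

    @classmethod
    def collective(cls, mu_max: float, K_M: float, r0: float, K_cap: float) -> "GrowthLaw":
        """Build a collective law; the sign of r0 selects the variant."""
        kind = COLLECTIVE_NO_THRESHOLD if r0 > 0 else COLLECTIVE_WITH_THRESHOLD
        return cls(kind=kind, K_cap=K_cap, mu_max=mu_max, K_M=K_M, r0=r0)


@dataclass(frozen=True)
class Trajectory:
    """A reported population time course: ``times`` in hours, ``values`` in
    cells (or cells/cm² when used for densities)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(v < 0):
            raise ValueError("population values must be nonnegative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def value_at(self, t: float) -> float:
        """Linear interpolation between report points."""
        if t < self.times[0] or t > self.times[-1]:
            raise ValueError(f"t={t} outside trajectory span")
        return float(np.interp(t, self.times, self.values))


def net_growth_rate(law: GrowthLaw, N):
    """Net growth rate r(N), per hour.

    Constant for the autonomous kind; the saturating hyperbola
    ``mu_max*N/(K_M+N) + r0`` for the collective kinds.  Accepts scalars or
    arrays; rejects negative N.
    """
    N_arr = np.asarray(N, dtype=float)
    if np.any(N_arr < 0):
        raise ValueError("population size N must be nonnegative")
    if law.kind == AUTONOMOUS:
        out = np.full_like(N_arr, law.r)
    else:
        out = law.mu_max * N_arr / (law.K_M + N_arr) + law.r0
    return float(out) if np.isscalar(N) else out


def threshold_population(law: GrowthLaw) -> float | None:
    """Allee threshold N*: the positive root of r(N*) = 0.

    Only the ``collective_with_threshold`` kind has one; the closed form is
    ``N* = K_M * (-r0) / (mu_max + r0)``.  Returns ``None`` for the other
    kinds or when no real positive root exists.
    """
    if law.kind != COLLECTIVE_WITH_THRESHOLD:
        return None
    if law.r0 == 0:
        return 0.0
    denom = law.mu_max + law.r0
    if denom <= 0:
        return None
    return law.K_M * (-law.r0) / denom


def integrate(
    law: GrowthLaw,
    N0: float,
    t_end: float,
    dt_report: float = 1.0,
    rtol: float = 1e-9,
    atol: float = 1e-9,
) -> Trajectory:
    """Integrate dN/dt = (1 - N/K_cap) * r(N) * N from N0 to t_end.

    Uses an adaptive-step solver with tight error control; the report grid
    defaults to 1 h to mirror the stochastic model's timestep.  N0 = 0 and
    N0 = K_cap are fixed points and return constant trajectories exactly.
    """
    if N0 < 0:
        raise ValueError("N0 must be nonnegative")
    if not t_end > 0:
        raise ValueError("t_end must be positive")
    times = np.arange(0.0, t_end + 0.5 * dt_report, dt_report)
    if times[-1] < t_end:
        times = np.append(times, t_end)

    if N0 == 0.0:
        return Trajectory(times, np.zeros_like(times))

    def rhs(t, y):
        N = max(y[0], 0.0)
        return [(1.0 - N / law.K_cap) * net_growth_rate(law, N) * N]

    sol = solve_ivp(
        rhs, (0.0, t_end), [float(N0)], t_eval=times,
        method="LSODA", rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"growth-law integration failed: {sol.message}")
    values = sol.y[0]
    if not np.all(np.isfinite(values)):
        raise RuntimeError("growth-law integration produced non-finite values")
    # solver round-off can leave values a hair below zero near extinction
    values = np.clip(values, 0.0, None)
    return Trajectory(times, values)


def fold_change(traj: Trajectory, t1: float) -> float:
    """Population at time t1 divided by the initial population.

    Interpolates linearly between report points; rejects trajectories that
    start at zero.
    """
    if traj.values[0] <= 0:
        raise ValueError("fold change undefined for a zero initial population")
    return traj.value_at(t1) / float(traj.values[0])


def logistic_closed_form(r: float, K: float, N0: float, t) -> np.ndarray:
    """Analytic logistic solution N(t) = K / (1 + (K/N0 - 1) e^{-rt}).

    Serves as the exact oracle for the autonomous kind.
    """
    t = np.asarray(t, dtype=float)
    if N0 == 0:
        return np.zeros_like(t)
    return K / (1.0 + (K / N0 - 1.0) * np.exp(-r * t))
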