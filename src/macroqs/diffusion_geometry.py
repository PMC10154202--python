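"""Reaction-diffusion theory of a secreted factor's communication range.

A single spherical cell of radius R secreting at steady state creates the
concentration profile

    c(r)/c_R = (R/r) * exp(-(r - R)/lambda),        r >= R,

where c_R is the surface concentration and lambda = sqrt(D/gamma_deg) is
the diffusion length of a molecule with diffusion coefficient D and
degradation rate gamma_deg (equivalently lambda = sqrt(D*tau) with tau
the molecule's lifetime, taken here verbatim as the half-life).

For a circular colony idealized as concentric rings of touching spherical
cells, ring m (m >= 1) sits with its cell centers a distance
r_m = (2m - 1) R from the surface of the colony's center ("receiver")
cell and carries N_m ~ 2*m*pi cells, so the total normalized
concentration at the receiver is

    c_tot/c_R = sum_{m>=1} (2 m pi / (2m - 1)) exp(-2 (m - 1) R / lambda).

The summand decays like exp(-2 m R / lambda): only cells within about one
diffusion length of the receiver contribute, so c_tot saturates once the
colony radius reaches the order of lambda.  A colony can survive on
intra-colony communication alone iff its center concentration clears the
threshold concentration.

Diffusion coefficients come from the Stokes-Einstein relation,
D = k_B T / (6 pi eta R_h), with the hydrodynamic radius R_h of a sphere
of typical protein density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MoleculeSpec",
    "ColonyGeometry",
    "ConcentrationProfile",
    "point_source_profile",
    "ring_contribution",
    "center_concentration",
    "saturation_radius",
    "hydrodynamic_radius",
    "diffusion_coefficient",
    "diffusion_length",
    "colony_survival_criterion",
]

BOLTZMANN_J_PER_K = 1.380649e-23
DALTON_KG = 1.66053906660e-27

#: dynamic viscosity of water at 37 C, Pa*s
WATER_VISCOSITY_37C = 6.9e-4
#: typical globular-protein density, g/cm^3
PROTEIN_DENSITY_G_CM3 = 1.35
BODY_TEMPERATURE_K = 310.0

# relative tolerance at which infinite ring sums are truncated
_SUM_RTOL = 1e-12


@dataclass(frozen=True)
class MoleculeSpec:
    """Physical properties of a secreted molecule.

    Parameters
    ----------
    mass_kda : float
        Molecular weight, kDa.
    half_life_h : float, optional
        Half-life tau, hours.  Used verbatim as the lifetime in
        lambda = sqrt(D*tau) unless ``use_mean_lifetime`` is set, in
        which case tau = half_life / ln 2.
    decay_rate_per_h : float, optional
        Degradation rate, per hour; if given together with a half-life the
        two must satisfy decay_rate = 1/tau (to 1%).
    temperature_K, viscosity_Pa_s, protein_density_g_cm3 : float
        Medium/molecule constants for the Stokes-Einstein estimate;
        defaults are water at 37 C and a typical globular protein.
    """

    mass_kda: float
    half_life_h: float | None = None
    decay_rate_per_h: float | None = None
    temperature_K: float = BODY_TEMPERATURE_K
    viscosity_Pa_s: float = WATER_VISCOSITY_37C
    protein_density_g_cm3: float = PROTEIN_DENSITY_G_CM3
    use_mean_lifetime: bool = False

    def __post_init__(self) -> None:
        for name in ("mass_kda", "temperature_K", "viscosity_Pa_s", "protein_density_g_cm3"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.half_life_h is None and self.decay_rate_per_h is None:
            raise ValueError("give half_life_h or decay_rate_per_h")
        if self.half_life_h is not None and self.half_life_h < 0:
            raise ValueError("half_life_h must be nonnegative")
        if self.decay_rate_per_h is not None and self.decay_rate_per_h <= 0:
            raise ValueError("decay_rate_per_h must be positive")
        if self.half_life_h and self.decay_rate_per_h:
            if not math.isclose(self.decay_rate_per_h, 1.0 / self.lifetime_h, rel_tol=0.01):
                raise ValueError(
                    "inconsistent molecule lifetime: decay_rate_per_h must equal "
                    "1/tau for the declared half-life convention"
                )

    @property
    def lifetime_h(self) -> float:
        """Effective lifetime tau, hours."""
        if self.half_life_h is not None:
            return self.half_life_h / math.log(2) if self.use_mean_lifetime else self.half_life_h
        return 1.0 / self.decay_rate_per_h


def hydrodynamic_radius(mol: MoleculeSpec) -> float:
    """Radius (m) of a sphere with the molecule's mass and protein density."""
    mass_kg = mol.mass_kda * 1000.0 * DALTON_KG
    density_kg_m3 = mol.protein_density_g_cm3 * 1000.0
    volume_m3 = mass_kg / density_kg_m3
    return (3.0 * volume_m3 / (4.0 * math.pi)) ** (1.0 / 3.0)


def diffusion_coefficient(mol: MoleculeSpec) -> float:
    """Stokes-Einstein diffusion coefficient, m^2/s."""
    R_h = hydrodynamic_radius(mol)
    return BOLTZMANN_J_PER_K * mol.temperature_K / (6.0 * math.pi * mol.viscosity_Pa_s * R_h)


def diffusion_length(mol: MoleculeSpec) -> float:
    """Diffusion length lambda = sqrt(D * tau), millimeters.

    Scales as sqrt(tau) and (mass)^{-1/6}; zero half-life gives zero.
    """
    D = diffusion_coefficient(mol)
    tau_s = mol.lifetime_h * 3600.0
    return math.sqrt(D * tau_s) * 1000.0


@dataclass(frozen=True)
class ColonyGeometry:
    """Concentric-ring idealization of a circular colony.

    ``cell_radius_um`` is the spherical cell radius R; the colony is
    ``n_rings`` rings around one receiver cell (ring m at distance
    r_m = (2m-1) R from the receiver surface with ~2*m*pi cells).  Either
    ``n_rings`` or ``colony_radius_um`` may be given; ``n_rings=None``
    with no radius means an unbounded (infinite) colony.
    """

    cell_radius_um: float
    lambda_um: float
    n_rings: int | None = None
    colony_radius_um: float | None = None

    def __post_init__(self) -> None:
        if not self.cell_radius_um > 0:
            raise ValueError("cell_radius_um must be positive")
        if not self.lambda_um > 0:
            raise ValueError("lambda_um must be positive")
        if self.n_rings is None and self.colony_radius_um is not None:
            # ring m spans out to radius (2m + 1) R; count whole rings inside
            n = int(math.floor((self.colony_radius_um / self.cell_radius_um - 1.0) / 2.0))
            object.__setattr__(self, "n_rings", max(n, 0))
        if self.n_rings is not None and self.n_rings < 0:
            raise ValueError("n_rings must be >= 0")


@dataclass(frozen=True)
class ConcentrationProfile:
    """Normalized radial profile c(r)/c_R around a secreting cell."""

    radii_um: np.ndarray
    c_over_cR: np.ndarray


def point_source_profile(lambda_um: float, cell_radius_um: float, r_um):
    """Normalized steady-state concentration (R/r) exp(-(r-R)/lambda).

    ``lambda_um`` may be ``inf`` (no degradation: pure geometric dilution
    R/r).  Distances below the cell surface (r < R) are rejected.
    """
    if not cell_radius_um > 0:
        raise ValueError("cell_radius_um must be positive")
    if not lambda_um > 0:
        raise ValueError("lambda_um must be positive")
    r = np.asarray(r_um, dtype=float)
    if np.any(r < cell_radius_um):
        raise ValueError("r must be >= the cell radius")
    if math.isinf(lambda_um):
        out = cell_radius_um / r
    else:
        out = (cell_radius_um / r) * np.exp(-(r - cell_radius_um) / lambda_um)
    return float(out) if np.isscalar(r_um) else out


def _per_cell_term(m, R, lam):
    """Per-cell normalized concentration from ring m:
    1/(2m-1) * exp(-2(m-1) R / lambda)."""
    m = np.asarray(m, dtype=float)
    if math.isinf(lam):
        return 1.0 / (2.0 * m - 1.0)
    return np.exp(-2.0 * (m - 1.0) * R / lam) / (2.0 * m - 1.0)


def ring_contribution(m: int, cell_radius_um: float, lambda_um: float,
                      per_cell: bool = True) -> float:
    """Contribution of ring m at the receiver cell, normalized by c_R.

    With ``per_cell=True`` (default) returns the per-cell value
    ``1/(2m-1) exp(-2(m-1)R/lambda)``; with ``per_cell=False`` returns
    the whole ring's summand, i.e. multiplied by N_m = 2*m*pi.
    """
    if m < 1:
        raise ValueError("ring index m must be >= 1")
    val = float(_per_cell_term(m, cell_radius_um, lambda_um))
    if not per_cell:
        val *= 2.0 * m * math.pi
    return val


def center_concentration(geom: ColonyGeometry) -> float:
    """Total normalized concentration c_tot/c_R at the colony center.

    Sums the ring contributions (the receiver cell itself never
    contributes).  ``n_rings=0`` (isolated cell) gives 0; ``n_rings=None``
    evaluates the infinite colony, truncating when the geometric tail
    bound falls below 1e-12 of the accumulated sum (diverges, and raises,
    when lambda is infinite).
    """
    R, lam = geom.cell_radius_um, geom.lambda_um
    if geom.n_rings is not None:
        if geom.n_rings == 0:
            return 0.0
        m = np.arange(1, geom.n_rings + 1)
        return float(np.sum(2.0 * m * math.pi * _per_cell_term(m, R, lam)))
    if math.isinf(lam):
        raise ValueError("infinite colony with infinite diffusion length: c_tot diverges")
    x = math.exp(-2.0 * R / lam)
    total = 0.0
    m = 1
    while True:
        term = 2.0 * m * math.pi * float(_per_cell_term(m, R, lam))
        total += term
        # terms decay at least geometrically with ratio x once 2m/(2m-1)
        # stops mattering; term * x/(1-x) bounds the remaining tail
        if m >= 2 and term * x / (1.0 - x) < _SUM_RTOL * total:
            return total
        m += 1
        if m > 10_000_000:  # pragma: no cover - guards absurd R/lambda
            raise RuntimeError("ring sum failed to converge")


def saturation_radius(cell_radius_um: float, lambda_um: float, tol: float = 0.05) -> float:
    """Smallest colony radius whose missing tail of c_tot is below tol.

    Returns the radius (um) of the smallest concentric-ring colony whose
    center concentration is within ``tol`` (relative) of the infinite
    colony's value - of order the diffusion length.  An infinite lambda
    means the sum grows without bound and ``inf`` is returned.
    """
    if not 0.0 < tol < 1.0:
        raise ValueError("tol must lie in (0, 1)")
    if math.isinf(lambda_um):
        return math.inf
    total = center_concentration(ColonyGeometry(cell_radius_um, lambda_um, n_rings=None))
    target = (1.0 - tol) * total
    partial = 0.0
    m = 1
    while partial < target:
        partial += 2.0 * m * math.pi * float(_per_cell_term(m, cell_radius_um, lambda_um))
        m += 1
    n = m - 1
    return (2.0 * n + 1.0) * cell_radius_um


def colony_survival_criterion(geom: ColonyGeometry, c_thres: float) -> bool:
    """True iff the colony can survive on intra-colony communication alone.

    The survival factor is most abundant at the colony center, so the
    whole colony clears the threshold iff the center cell does:
    c_tot/c_R >= c_thres (both in units of c_R).
    """
    if c_thres < 0:
        raise ValueError("c_thres must be nonnegative")
    return center_concentration(geom) >= c_thres


def profile(lambda_um: float, cell_radius_um: float, radii_um) -> ConcentrationProfile:
    """Convenience wrapper returning a tabulated radial profile."""
    radii = np.asarray(radii_um, dtype=float)
    return ConcentrationProfile(radii, point_source_profile(lambda_um, cell_radius_um, radii))
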