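"""Hindered pore-transport theory for drugs crossing tumor vessel walls.

A therapeutic agent is treated as a neutral rigid sphere of radius ``r_s``
and the openings in the vessel wall as liquid-filled cylindrical pores of
radius ``r_0``.  Everything drug- and pore-size-dependent in the simulator
derives from the ratio ``lambda = r_s / r_0``:

* ``H(lambda)`` -- hindrance factor for diffusion through the pore
  (includes steric partitioning), so the transvascular drug permeability is
  ``P = gamma * H * D_free / L_vw``.
* ``sigma_f(lambda) = 1 - W(lambda)`` -- reflection coefficient, where
  ``W`` is the convective hindrance factor.
* ``L_p = gamma * r_0**2 / (8 * mu * L_vw)`` -- hydraulic conductivity of
  the wall (Poiseuille flow through the pore population).
* ``D_free = K_b*T / (6*pi*mu*r_s)`` -- Stokes-Einstein free diffusivity,
  reduced to an interstitial diffusivity by ``D_i = D_free / tortuosity**2``.

Two standard correlations for ``H`` and ``W`` are provided: the
Bungay-Brenner (1973) cylindrical-pore expressions (default) and the
Renkin-style centerline polynomials.  They agree within a few percent for
``lambda <= 0.6``.  ``lambda >= 1`` is treated as total exclusion
(``H = 0``, ``sigma_f = 1``, ``P = 0``) rather than an error, because drug
diameters exceeding the pore diameter are legitimate points of the
parametric study.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "BOLTZMANN",
    "PoreDrugGeometry",
    "VesselWallParameters",
    "HinderedTransportCoefficients",
    "free_diffusivity",
    "hindrance_factor",
    "convective_hindrance",
    "reflection_coefficient",
    "wall_hydraulic_conductivity",
    "wall_permeability",
    "tissue_diffusivity",
    "transport_coefficients",
]

#: Boltzmann constant, J/K (2019 SI exact value).
BOLTZMANN = 1.380649e-23


@dataclass(frozen=True)
class PoreDrugGeometry:
    """Drug / pore size pair. Radii in meters."""

    drug_radius: float
    pore_radius: float

    def __post_init__(self) -> None:
        if self.drug_radius <= 0 or self.pore_radius <= 0:
            raise ValueError("drug_radius and pore_radius must be positive")

    @property
    def lam(self) -> float:
        """Size ratio lambda = r_s / r_0."""
        return self.drug_radius / self.pore_radius


@dataclass(frozen=True)
class VesselWallParameters:
    """Structural/physical parameters of the vessel wall and plasma.

    gamma
        Fraction of the wall surface occupied by pores (dimensionless).
    wall_thickness
        Endothelial wall thickness L_vw, m.
    plasma_viscosity
        Plasma viscosity at body temperature, Pa s.
    temperature
        Absolute temperature, K.
    """

    gamma: float = 1.0e-3
    wall_thickness: float = 5.0e-6
    plasma_viscosity: float = 1.0e-3
    temperature: float = 310.0

    def __post_init__(self) -> None:
        if not (0.0 < self.gamma <= 1.0):
            raise ValueError("gamma must lie in (0, 1]")
        if self.wall_thickness <= 0 or self.plasma_viscosity <= 0 or self.temperature <= 0:
            raise ValueError("wall_thickness, plasma_viscosity, temperature must be positive")


@dataclass(frozen=True)
class HinderedTransportCoefficients:
    """Bundle of all size-dependent coefficients for one drug/pore pair."""

    lam: float
    H: float
    sigma_f: float
    D_free: float
    D_tissue: float
    L_p: float
    P: float


def free_diffusivity(r_s: float, T: float = 310.0, mu: float = 1.0e-3) -> float:
    """Stokes-Einstein diffusivity of a sphere of radius ``r_s`` (m^2/s)."""
    if r_s <= 0 or T <= 0 or mu <= 0:
        raise ValueError("r_s, T and mu must be positive")
    return BOLTZMANN * T / (6.0 * math.pi * mu * r_s)


def _bungay_brenner_Kt_Ks(lam: float) -> tuple[float, float]:
    """Bungay-Brenner drag coefficients K_t, K_s for a sphere in a pore."""
    one = 1.0 - lam
    pref = 2.25 * math.pi**2 * math.sqrt(2.0) * one ** (-2.5)
    Kt = pref * (1.0 + (-73.0 / 60.0) * one + (77293.0 / 50400.0) * one**2)
    Kt += -22.5083 - 5.6117 * lam - 0.3363 * lam**2 - 1.216 * lam**3 + 1.647 * lam**4
    Ks = pref * (1.0 + (7.0 / 60.0) * one + (-2227.0 / 50400.0) * one**2)
    Ks += 4.0180 - 3.9788 * lam - 1.9215 * lam**2 + 4.392 * lam**3 + 5.006 * lam**4
    return Kt, Ks


def hindrance_factor(lam: float, correlation: str = "bungay-brenner") -> float:
    """Diffusive hindrance factor H(lambda), partitioning included.

    H(0) = 1 (unhindered), H is decreasing in lambda and H = 0 for
    lambda >= 1 (steric exclusion).  The correlations carry a small
    (~5e-5) truncation error at lambda -> 0 which is clipped so the
    physical bound H <= 1 always holds.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if lam >= 1.0:
        return 0.0
    phi = (1.0 - lam) ** 2  # steric partition coefficient
    if correlation == "bungay-brenner":
        Kt, _ = _bungay_brenner_Kt_Ks(lam)
        H = 6.0 * math.pi * phi / Kt
    elif correlation == "renkin":
        H = phi * (1.0 - 2.1044 * lam + 2.089 * lam**3 - 0.948 * lam**5)
    else:
        raise ValueError(f"unknown hindrance correlation: {correlation!r}")
    return min(max(H, 0.0), 1.0)


def convective_hindrance(lam: float, correlation: str = "bungay-brenner") -> float:
    """Convective hindrance factor W(lambda); sigma_f = 1 - W."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if lam >= 1.0:
        return 0.0
    phi = (1.0 - lam) ** 2
    if correlation == "bungay-brenner":
        Kt, Ks = _bungay_brenner_Kt_Ks(lam)
        W = phi * (2.0 - phi) * Ks / (2.0 * Kt)
    elif correlation == "renkin":
        W = phi * (2.0 - phi) * (1.0 - (2.0 / 3.0) * lam**2 - 0.163 * lam**3)
    else:
        raise ValueError(f"unknown hindrance correlation: {correlation!r}")
    return min(max(W, 0.0), 1.0)


def reflection_coefficient(lam: float, correlation: str = "bungay-brenner") -> float:
    """Reflection coefficient sigma_f(lambda) = 1 - W(lambda) in [0, 1]."""
    return 1.0 - convective_hindrance(lam, correlation)


def wall_hydraulic_conductivity(wall: VesselWallParameters, r_0: float) -> float:
    """Vessel-wall hydraulic conductivity L_p = gamma r_0^2 / (8 mu L_vw)."""
    if r_0 <= 0:
        raise ValueError("pore radius must be positive")
    return wall.gamma * r_0**2 / (8.0 * wall.plasma_viscosity * wall.wall_thickness)


def wall_permeability(
    wall: VesselWallParameters,
    geom: PoreDrugGeometry,
    correlation: str = "bungay-brenner",
) -> float:
    """Transvascular drug permeability P = gamma H(lambda) D_free / L_vw (m/s)."""
    lam = geom.lam
    if lam >= 1.0:
        return 0.0
    D = free_diffusivity(geom.drug_radius, wall.temperature, wall.plasma_viscosity)
    return wall.gamma * hindrance_factor(lam, correlation) * D / wall.wall_thickness


def tissue_diffusivity(D_free: float, tortuosity: float = 1.6) -> float:
    """Interstitial diffusivity D_i = D_free / tortuosity^2."""
    if D_free <= 0:
        raise ValueError("D_free must be positive")
    if tortuosity < 1.0:
        raise ValueError("tortuosity must be >= 1")
    return D_free / tortuosity**2


def transport_coefficients(
    drug_diameter: float,
    pore_diameter: float,
    wall: VesselWallParameters | None = None,
    tortuosity: float = 1.6,
    correlation: str = "bungay-brenner",
) -> HinderedTransportCoefficients:
    """All size-dependent coefficients for one drug/pore pair (SI units)."""
    if drug_diameter <= 0 or pore_diameter <= 0:
        raise ValueError("diameters must be positive")
    wall = wall or VesselWallParameters()
    geom = PoreDrugGeometry(drug_diameter / 2.0, pore_diameter / 2.0)
    lam = geom.lam
    D_free = free_diffusivity(geom.drug_radius, wall.temperature, wall.plasma_viscosity)
    return HinderedTransportCoefficients(
        lam=lam,
        H=hindrance_factor(lam, correlation),
        sigma_f=reflection_coefficient(lam, correlation),
        D_free=D_free,
        D_tissue=tissue_diffusivity(D_free, tortuosity),
        L_p=wall_hydraulic_conductivity(wall, geom.pore_radius),
        P=wall_permeability(wall, geom, correlation),
    )
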