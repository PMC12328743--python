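"""Pore geometry: conductance models, beta-barrel radii, permeant sizing.

Connects three independent observables of a large membrane pore:

* single-channel conductance, through the access-resistance-corrected
  cylinder (Hille) model  G = sigma * [l / (pi r^2) + 1 / (2r)]^-1, whose
  inverse is a closed-form quadratic in r;
* oligomer stoichiometry, through standard beta-barrel polygon geometry
  (backbone circumradius from strand count, interstrand distance and tilt);
* permeant size, through Stokes-Einstein radii and a simple size-exclusion
  predicate.

For TMcin-scale pores (~5 nm radius, ~5 nm bilayer span, 150 mM KCl) the
cylinder model predicts ~10 nS, the conductance scale the recordings show.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "BOLTZMANN",
    "KCL_150MM_CONDUCTIVITY",
    "WATER_VISCOSITY_25C",
    "PoreModel",
    "BarrelSpec",
    "BarrelGeometry",
    "SoluteProbe",
    "PermeationResult",
    "cylinder_conductance",
    "radius_from_conductance",
    "barrel_radius",
    "stokes_einstein_radius",
    "diffusion_from_radius",
    "permeation_predicate",
]

BOLTZMANN = 1.380649e-23  # J/K
#: Conductivity of 150 mM KCl at 25 C, S/m (configurable everywhere).
KCL_150MM_CONDUCTIVITY = 1.66
WATER_VISCOSITY_25C = 8.9e-4  # Pa s


@dataclass(frozen=True)
class PoreModel:
    """Water-filled cylindrical pore: radius and length in nm, bath
    conductivity in S/m."""

    radius_nm: float
    length_nm: float = 5.0
    conductivity_S_per_m: float = KCL_150MM_CONDUCTIVITY

    def __post_init__(self):
        if self.radius_nm <= 0:
            raise ValueError("radius must be positive")
        if self.length_nm < 0:
            raise ValueError("length must be non-negative")
        if self.conductivity_S_per_m <= 0:
            raise ValueError("conductivity must be positive")


@dataclass(frozen=True)
class BarrelSpec:
    """Beta-barrel built from n_protomers hairpins (2 strands each by
    default), interstrand distance d in Angstrom, strand tilt in degrees."""

    n_protomers: int
    strands_per_protomer: int = 2
    interstrand_distance_A: float = 4.8
    strand_tilt_deg: float = 0.0

    def __post_init__(self):
        if self.n_protomers < 2:
            raise ValueError("need at least two protomers")
        if self.interstrand_distance_A <= 0:
            raise ValueError("interstrand distance must be positive")
        if not 0 <= self.strand_tilt_deg < 90:
            raise ValueError("tilt must be in [0, 90) degrees")

    @property
    def n_strands(self) -> int:
        return self.n_protomers * self.strands_per_protomer


@dataclass(frozen=True)
class BarrelGeometry:
    backbone_radius_nm: float
    lumen_diameter_nm: float


@dataclass(frozen=True)
class SoluteProbe:
    name: str
    stokes_einstein_radius_nm: float

    def __post_init__(self):
        if self.stokes_einstein_radius_nm <= 0:
            raise ValueError("probe radius must be positive")


@dataclass(frozen=True)
class PermeationResult:
    permeant: bool
    margin_nm: float


def cylinder_conductance(model: PoreModel) -> float:
    """Pore conductance in nS, with access resistance at both mouths.

    G = sigma [ l/(pi r^2) + 1/(2r) ]^-1; at l = 0 this reduces to the pure
    access-resistance limit G = 2 sigma r.
    """
    r, l, s = model.radius_nm, model.length_nm, model.conductivity_S_per_m
    # lengths in nm and sigma in S/m give G in nS directly
    return s / (l / (math.pi * r**2) + 1 / (2 * r))


def radius_from_conductance(
    conductance_nS: float,
    length_nm: float = 5.0,
    conductivity_S_per_m: float = KCL_150MM_CONDUCTIVITY,
) -> float:
    """Closed-form inverse of the cylinder model (positive quadratic root):

    sigma r^2 - (G/2) r - G l / pi = 0
    r = [ G/2 + sqrt(G^2/4 + 4 sigma G l / pi) ] / (2 sigma), in nm.
    """
    g, l, s = conductance_nS, length_nm, conductivity_S_per_m
    if g <= 0:
        raise ValueError("conductance must be positive")
    return (g / 2 + math.sqrt(g**2 / 4 + 4 * s * g * l / math.pi)) / (2 * s)


def barrel_radius(spec: BarrelSpec, wall_allowance_nm: float = 0.25) -> BarrelGeometry:
    """Backbone circumradius and lumen diameter of a beta-barrel.

    The n_s strands sit at the vertices of a regular n_s-gon of side d, so
    the circumradius is d / (2 sin(pi/n_s)); tilting the strands by alpha
    widens the barrel by 1/cos(alpha).  The lumen subtracts a configurable
    side-chain wall allowance from the backbone radius.
    """
    ns = spec.n_strands
    if ns < 4:
        raise ValueError("a barrel needs at least four strands")
    d_nm = spec.interstrand_distance_A / 10.0
    alpha = math.radians(spec.strand_tilt_deg)
    backbone = d_nm / (2 * math.sin(math.pi / ns)) / math.cos(alpha)
    return BarrelGeometry(backbone, 2 * (backbone - wall_allowance_nm))


def stokes_einstein_radius(
    diffusion_m2_per_s: float,
    temperature_K: float = 298.15,
    viscosity_Pa_s: float = WATER_VISCOSITY_25C,
) -> float:
    """Hydrodynamic radius in nm: r = k_B T / (6 pi eta D)."""
    if min(diffusion_m2_per_s, temperature_K, viscosity_Pa_s) <= 0:
        raise ValueError("all inputs must be positive")
    r_m = BOLTZMANN * temperature_K / (6 * math.pi * viscosity_Pa_s * diffusion_m2_per_s)
    return r_m * 1e9


def diffusion_from_radius(
    radius_nm: float,
    temperature_K: float = 298.15,
    viscosity_Pa_s: float = WATER_VISCOSITY_25C,
) -> float:
    """Inverse Stokes-Einstein: D in m^2/s from radius in nm."""
    if min(radius_nm, temperature_K, viscosity_Pa_s) <= 0:
        raise ValueError("all inputs must be positive")
    return BOLTZMANN * temperature_K / (6 * math.pi * viscosity_Pa_s * radius_nm * 1e-9)


def permeation_predicate(probe: SoluteProbe, pore_radius_nm: float) -> PermeationResult:
    """Size-exclusion call: permeant iff the probe's hydrodynamic radius
    does not exceed the pore radius; margin is the clearance in nm."""
    if pore_radius_nm <= 0:
        raise ValueError("pore radius must be positive")
    margin = pore_radius_nm - probe.stokes_einstein_radius_nm
    return PermeationResult(margin >= 0, margin)
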