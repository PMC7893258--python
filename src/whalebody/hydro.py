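"""Hydrodynamic glide model.

Along-path acceleration of a passively gliding whale is the sum of three
forces per unit mass: drag, net tissue buoyancy (the non-gas body compartment,
compressible with depth), and buoyancy of the residual diving air compressed
by Boyle's law.  Fitting this forward model to accelerations observed during
stroke-free glides yields the tissue body density -- the quantity that tracks
lipid stores, because lipid (~920 kg m^-3) is much less dense than lean
tissue (~1060 kg m^-3).

All functions are pure and vectorize over numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Pa per atmosphere; hydrostatic pressure is expressed as (1 + 0.1 d) atm.
ATMOSPHERE_PA = 101_325.0

#: Tissue compressibility (fractional volume change per Pa), fixed at the
#: value estimated for northern bottlenose whales.
DEFAULT_COMPRESSIBILITY = 0.38e-9


@dataclass(frozen=True)
class PhysicalConstants:
    """Physical constants of the glide model.

    Attributes
    ----------
    g : float
        Gravitational acceleration, m s^-2.
    rho_air : float
        Air density at 1 atm, kg m^-3.  Scaled by absolute pressure
        (1 + 0.1 d) inside the air-buoyancy term.
    atmosphere_pa : float
        Pascals per atmosphere.
    """

    g: float = 9.8
    rho_air: float = 1.225
    atmosphere_pa: float = ATMOSPHERE_PA

    def __post_init__(self) -> None:
        if self.g <= 0 or self.rho_air <= 0 or self.atmosphere_pa <= 0:
            raise ValueError("physical constants must be positive")


@dataclass(frozen=True)
class HydroParams:
    """Unknowns of the glide model.

    Attributes
    ----------
    tissue_density : float
        Tissue body density at zero pressure, rho_tissue(0), kg m^-3.
    drag_term : float
        Combined drag term C_D * A / m, m^2 kg^-1.  The three factors are
        not separately identifiable from glide data.
    air_per_mass : float
        Diving air volume per unit body mass at the surface, V_air / m,
        m^3 kg^-1.
    compressibility : float
        Tissue compressibility r, Pa^-1.
    """

    tissue_density: float
    drag_term: float
    air_per_mass: float = 0.0
    compressibility: float = DEFAULT_COMPRESSIBILITY

    def __post_init__(self) -> None:
        if not 800.0 <= self.tissue_density <= 1200.0:
            raise ValueError(
                f"tissue_density {self.tissue_density} outside [800, 1200] kg m^-3"
            )
        if self.drag_term <= 0:
            raise ValueError("drag_term must be > 0")
        if self.air_per_mass < 0:
            raise ValueError("air_per_mass must be >= 0")
        if self.compressibility < 0:
            raise ValueError("compressibility must be >= 0")


def tissue_density_at_depth(rho_tissue_0, compressibility, depth):
    """Tissue density at depth under hydrostatic compression.

    rho(d) = rho(0) / (1 - r * (1 + 0.1 d) * 101325), with pressure in
    atmospheres approximated as 1 + 0.1 d.  Note the full 1 atm is applied at
    d = 0, i.e. rho(0) is a zero-pressure reference density.

    Parameters are scalars or broadcastable arrays; depth in metres.
    """
    pressure_pa = (1.0 + 0.1 * np.asarray(depth, dtype=float)) * ATMOSPHERE_PA
    denom = 1.0 - compressibility * pressure_pa
    if np.any(denom <= 0):
        raise ValueError("non-physical compression: 1 - r*P <= 0")
    return rho_tissue_0 / denom


def glide_acceleration(params, depth, pitch, speed, rho_sw,
                       constants: PhysicalConstants = PhysicalConstants()):
    """Predicted along-path acceleration (m s^-2) of a gliding whale.

    a = -0.5 (C_D A/m) rho_sw v^2
        + (rho_sw / rho_tissue(d) - 1) g sin(p)
        + (V_air/m) g sin(p) (rho_sw - rho_air (1 + 0.1 d)) / (1 + 0.1 d)

    Positive along the direction of motion; pitch in radians, positive
    ascending.  Accepts arrays for the observation arguments.

    Parameters
    ----------
    params : HydroParams
    depth, pitch, speed, rho_sw : array_like
        Glide depth (m), pitch (rad), swim speed (m s^-1), seawater
        density (kg m^-3).
    """
    depth = np.asarray(depth, dtype=float)
    pitch = np.asarray(pitch, dtype=float)
    speed = np.asarray(speed, dtype=float)
    rho_sw = np.asarray(rho_sw, dtype=float)
    if np.any(speed < 0) or np.any(depth < 0):
        raise ValueError("speed and depth must be non-negative")

    rho_t = tissue_density_at_depth(
        params.tissue_density, params.compressibility, depth
    )
    g = constants.g
    sinp = np.sin(pitch)
    press_atm = 1.0 + 0.1 * depth

    drag = -0.5 * params.drag_term * rho_sw * speed**2
    tissue = (rho_sw / rho_t - 1.0) * g * sinp
    air = (
        params.air_per_mass
        * g
        * sinp
        * (rho_sw - constants.rho_air * press_atm)
        / press_atm
    )
    return drag + tissue + air


@dataclass(frozen=True)
class NormalPrior:
    """Normal prior, optionally truncated to (lower, upper)."""

    mean: float
    sd: float
    lower: float = -np.inf
    upper: float = np.inf

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        out = -0.5 * ((x - self.mean) / self.sd) ** 2 - np.log(self.sd)
        return np.where((x > self.lower) & (x < self.upper), out, -np.inf)


def drag_prior_default(sd: float = 5e-6) -> NormalPrior:
    """Default prior for the combined drag term.

    Normal with mean 11e-6 m^2 kg^-1 (lift-induced drag expectation for a
    large-flippered whale), truncated to positive values; sd configurable.
    """
    return NormalPrior(mean=11e-6, sd=sd, lower=0.0)
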