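"""Laser beam definition, photon energetics and the photon-flux scaling factor.

The simulated source emits ``emission_rate`` photons per second (a number
chosen for statistics, not physics); the *photon flux scaling factor* links
that to the physical beam: it is the physical photon flux through the tip
cross-section divided by the simulated emission rate, and multiplies
per-voxel simulated energies in post-processing.

The flux can be referred to mm^2, cm^2 or m^2 of tip area.  The default is
mm^2, the only convention under which a 2.1 W, 0.3 mm, 808 nm beam sampled
at 2e6 photons/s yields the reference scaling factor of ~6e13; the choice is
a config switch because the source literature mixes units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import E_CHARGE, HC_EV_NM

__all__ = [
    "LaserBeam",
    "LaserDomainError",
    "photon_energy",
    "photon_flux",
    "flux_scaling_factor",
    "emit_photon",
    "emit_photons",
]

_AREA_MM2 = {"mm2": 1.0, "cm2": 100.0, "m2": 1e6}


class LaserDomainError(ValueError):
    """Invalid beam parameter."""


@dataclass(frozen=True)
class LaserBeam:
    """Continuous-wave collimated beam launched from a circular fiber tip.

    Photons start uniformly on the tip disc (diameter ``tip_diameter_mm``,
    centered at ``tip_position_mm``, perpendicular to ``direction``) and
    travel along ``direction``; no divergence is modelled.
    """

    wavelength_nm: float = 808.0
    power_w: float = 2.1
    tip_diameter_mm: float = 0.3
    tip_position_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    emission_rate: float = 2.0e6
    duration_s: float = 120.0
    area_unit: str = "mm2"

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0:
            raise LaserDomainError("wavelength must be > 0")
        if self.power_w < 0:
            raise LaserDomainError("power must be >= 0")
        if self.tip_diameter_mm <= 0:
            raise LaserDomainError("tip diameter must be > 0")
        if self.duration_s < 0:
            raise LaserDomainError("duration must be >= 0")
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise LaserDomainError("direction must be a unit vector")
        if self.area_unit not in _AREA_MM2:
            raise LaserDomainError(f"area_unit must be one of {sorted(_AREA_MM2)}")

    @property
    def photon_energy_ev(self) -> float:
        return photon_energy(self.wavelength_nm)

    @property
    def tip_area_mm2(self) -> float:
        return math.pi * (self.tip_diameter_mm / 2.0) ** 2


def photon_energy(wavelength_nm: float) -> float:
    """Photon energy E0 = hc/lambda in eV (hc = 1239.842 eV·nm)."""
    if wavelength_nm <= 0:
        raise LaserDomainError("wavelength must be > 0")
    return HC_EV_NM / wavelength_nm


def photon_flux(
    power_w: float, e0_ev: float, tip_diameter_mm: float, area_unit: str = "mm2"
) -> float:
    """Physical photon flux through the tip, photons/(s·area_unit)."""
    if e0_ev <= 0:
        raise LaserDomainError("photon energy must be > 0")
    if tip_diameter_mm <= 0:
        raise LaserDomainError("tip diameter must be > 0")
    if power_w < 0:
        raise LaserDomainError("power must be >= 0")
    try:
        area = math.pi * (tip_diameter_mm / 2.0) ** 2 / _AREA_MM2[area_unit]
    except KeyError:
        raise LaserDomainError(f"area_unit must be one of {sorted(_AREA_MM2)}") from None
    return power_w / (e0_ev * E_CHARGE * area)


def flux_scaling_factor(beam: LaserBeam) -> float:
    """Physical photon flux divided by the simulated emission rate.

    Multiplying simulated per-voxel deposited energies by this factor
    converts them to the physical deposition scale used by the heat
    post-processing.
    """
    if beam.emission_rate <= 0:
        raise LaserDomainError("emission rate must be > 0")
    return (
        photon_flux(beam.power_w, beam.photon_energy_ev, beam.tip_diameter_mm, beam.area_unit)
        / beam.emission_rate
    )


def _disc_basis(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = np.asarray(direction, dtype=float)
    helper = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return e1, e2


def emit_photons(
    beam: LaserBeam, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float]:
    """Sample n initial photons: positions on the tip disc, beam direction, E0."""
    d = np.asarray(beam.direction, dtype=float)
    e1, e2 = _disc_basis(d)
    r = beam.tip_diameter_mm / 2.0 * np.sqrt(rng.random(n))
    phi = 2.0 * math.pi * rng.random(n)
    offsets = r[:, None] * (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2)
    positions = np.asarray(beam.tip_position_mm, dtype=float) + offsets
    directions = np.broadcast_to(d, (n, 3)).copy()
    return positions, directions, beam.photon_energy_ev


def emit_photon(
    beam: LaserBeam, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float]:
    """Single-photon convenience wrapper around :func:`emit_photons`."""
    pos, dirs, e0 = emit_photons(beam, 1, rng)
    return pos[0], dirs[0], e0
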