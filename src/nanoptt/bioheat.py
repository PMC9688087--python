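"""Energy-to-temperature conversion and analytic bioheat diffusion.

Deposited optical energy becomes a temperature increase either through the
calorimetric conversion factor F = e/(m·Cp) per voxel, or — for
nanoparticle-loaded voxels — through the per-voxel steady heating estimate
ΔT = N R² C_abs I / (2k) with R the voxel half-size and I the per-voxel
irradiance.  Both are scaled by the laser's photon-flux scaling factor.

The perfused heat equation with constant coefficients,

    dT/dt = α ∇²T + Q_b (T_b − T) + source,

is solved analytically: an initial increment field convolved with the
Gaussian Green's function of per-axis standard deviation sqrt(2αt), times
the perfusion decay exp(−Q_b t).  Continuous-wave heating is approximated
by superposing per-Δt injections of the per-second deposition map, each
diffused for its remaining time (midpoint time stepping, default Δt = 1 s).
The convolution is evaluated with a truncated Gaussian filter and
constant-zero boundaries, i.e. the far field is held at the baseline
temperature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .constants import E_CHARGE
from .transport import EnergyMap

__all__ = [
    "ThermalModel",
    "TemperatureField",
    "conversion_factor",
    "energy_to_deltaT",
    "voxel_irradiance",
    "gnr_deltaT",
    "heat_kernel",
    "diffuse",
    "irradiate",
]


@dataclass(frozen=True)
class ThermalModel:
    """Homogenized thermal parameters for the analytic solver.

    A single diffusivity represents the mixture (the tumor/GNR value for
    loaded scenarios); ``q_b`` is the perfusion decay rate
    (rho_b c_b)/(rho c) * w_b in 1/s, zero for ex vivo phantoms.
    """

    alpha_mm2_s: float
    conductivity_w_mk: float = 0.6
    q_b: float = 0.0
    baseline_c: float = 26.0

    def __post_init__(self) -> None:
        if self.alpha_mm2_s < 0:
            raise ValueError("thermal diffusivity must be >= 0")
        if self.q_b < 0:
            raise ValueError("perfusion decay rate must be >= 0")


@dataclass
class TemperatureField:
    """Per-voxel temperature increase (°C) above the baseline at time t."""

    deltaT: np.ndarray
    baseline_c: float
    time_s: float
    pitch: float
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.deltaT = np.asarray(self.deltaT, dtype=np.float64)
        self.origin = np.asarray(self.origin, dtype=float)
        if not np.isfinite(self.deltaT).all():
            raise ValueError("temperature field must be finite")

    @property
    def absolute_c(self) -> np.ndarray:
        return self.deltaT + self.baseline_c


def conversion_factor(cp_j_kg_k: float, voxel_mass_kg: float) -> float:
    """Calorimetric factor F, °C per eV deposited in one voxel.

    F = e / (m·Cp); with m in g and Cp in J/(g·°C) the numerical value is
    the same as with SI units, so SI is used directly.
    """
    if cp_j_kg_k <= 0 or voxel_mass_kg <= 0:
        raise ValueError("heat capacity and voxel mass must be > 0")
    return E_CHARGE / (voxel_mass_kg * cp_j_kg_k)


def energy_to_deltaT(
    emap: EnergyMap, f_c_per_ev: float | np.ndarray, scaling: float
) -> TemperatureField:
    """Voxelwise ΔT = energy × F × scaling at t = 0 (before diffusion).

    ``f_c_per_ev`` may be a scalar or a per-voxel array (mixed materials).
    """
    if scaling < 0:
        raise ValueError("scaling factor must be >= 0")
    return TemperatureField(
        deltaT=emap.energy * f_c_per_ev * scaling,
        baseline_c=26.0,
        time_s=0.0,
        pitch=emap.pitch,
        origin=emap.origin.copy(),
    )


def voxel_irradiance(voxel_energy_ev: float, t_laser_s: float, voxel_area_m2: float) -> float:
    """Light irradiance per voxel, W/m²: deposited energy over exposure time and face area."""
    if t_laser_s <= 0 or voxel_area_m2 <= 0:
        raise ValueError("exposure time and voxel area must be > 0")
    return voxel_energy_ev * E_CHARGE / (t_laser_s * voxel_area_m2)


def gnr_deltaT(
    n_per_m3: float, r_m: float, c_abs_m2: float, irradiance_w_m2: float, k_w_mk: float
) -> float:
    """Steady temperature rise of a uniformly nanoparticle-heated region.

    ΔT = N R² C_abs I / (2k); applied per voxel with R the voxel half-size
    and I the per-voxel irradiance.
    """
    if k_w_mk <= 0:
        raise ValueError("thermal conductivity must be > 0")
    return n_per_m3 * r_m**2 * c_abs_m2 * irradiance_w_m2 / (2.0 * k_w_mk)


def heat_kernel(
    alpha_mm2_s: float, t_s: float, pitch_mm: float, truncate_sigmas: float = 6.0
) -> np.ndarray:
    """Discretized 3-D Gaussian Green's function of the heat equation.

    Per-axis standard deviation sqrt(2αt) mm; normalized to unit sum.  At
    t = 0 (or α = 0) this degenerates to the identity (delta) kernel.
    """
    if alpha_mm2_s < 0 or t_s < 0:
        raise ValueError("alpha and t must be >= 0")
    sigma_mm = math.sqrt(2.0 * alpha_mm2_s * t_s)
    if sigma_mm == 0.0:
        return np.ones((1, 1, 1))
    half = max(1, int(math.ceil(truncate_sigmas * sigma_mm / pitch_mm)))
    ax = np.arange(-half, half + 1) * pitch_mm
    g1 = np.exp(-(ax**2) / (4.0 * alpha_mm2_s * t_s))
    kern = g1[:, None, None] * g1[None, :, None] * g1[None, None, :]
    return kern / kern.sum()


def diffuse(field: TemperatureField, model: ThermalModel, t_s: float) -> TemperatureField:
    """Evolve an increment field for t seconds: Gaussian convolution × perfusion decay."""
    if t_s < 0:
        raise ValueError("t must be >= 0")
    if t_s == 0.0:
        return replace(field, deltaT=field.deltaT.copy())
    sigma_vox = math.sqrt(2.0 * model.alpha_mm2_s * t_s) / field.pitch
    out = (
        ndimage.gaussian_filter(field.deltaT, sigma=sigma_vox, mode="constant", truncate=6.0)
        if sigma_vox > 0
        else field.deltaT.copy()
    )
    out *= math.exp(-model.q_b * t_s)
    return replace(field, deltaT=out, time_s=field.time_s + t_s)


def irradiate(
    rate_c_per_s: np.ndarray,
    model: ThermalModel,
    times_s: Sequence[float],
    pitch_mm: float,
    origin_mm: np.ndarray,
    heating_duration_s: float,
    dt_s: float = 1.0,
) -> list[TemperatureField]:
    """Temperature fields at the requested times under continuous-wave heating.

    ``rate_c_per_s`` is the physical per-second per-voxel temperature
    injection (already flux-scaled).  Heating runs from t = 0 to
    ``heating_duration_s``; each Δt slab is injected at its midpoint
    (half-step diffuse, inject, half-step diffuse), which superposes the
    Green's-function solutions of the individual injections.
    """
    times = list(times_s)
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("requested times must be strictly increasing")
    if any(t < 0 for t in times):
        raise ValueError("requested times must be >= 0")
    if dt_s <= 0:
        raise ValueError("dt must be > 0")
    field = TemperatureField(
        deltaT=np.zeros_like(rate_c_per_s, dtype=np.float64),
        baseline_c=model.baseline_c,
        time_s=0.0,
        pitch=pitch_mm,
        origin=np.asarray(origin_mm, float),
    )
    out: list[TemperatureField] = []
    for target in times:
        while field.time_s < target - 1e-12:
            remaining = target - field.time_s
            step = min(dt_s, remaining)
            heat_left = heating_duration_s - field.time_s
            inject = min(max(heat_left, 0.0), step)
            if inject > 0.0:
                # midpoint injection: half-step diffuse, inject, half-step diffuse
                field = diffuse(field, model, step / 2.0)
                field.deltaT += rate_c_per_s * inject
                field = diffuse(field, model, step / 2.0)
            else:
                field = diffuse(field, model, step)
            field.time_s = round(field.time_s, 12)
        out.append(replace(field, deltaT=field.deltaT.copy(), time_s=target))
    return out
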