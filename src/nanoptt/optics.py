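"""Gold-nanorod quasi-static (Gans) optics.

The longitudinal surface-plasmon resonance of a gold nanorod is what makes
it an efficient near-infrared photothermal absorber.  In the quasi-static
limit a rod of diameter D and length l is treated as a prolate spheroid with
depolarization factors P_i; its per-axis polarizability is

    alpha_i = 4 pi a b c (eps - eps_m) / (3 eps_m + 3 P_i (eps - eps_m)),

with semi-axes a = l/2, b = c = D/2, particle permittivity eps and host
permittivity eps_m.  The orientation-averaged absorption cross section is
C_abs = k * Im[(alpha_1 + alpha_2 + alpha_3)/3] with k = 2 pi sqrt(eps_m)/lambda.
This convention reduces to the Clausius-Mossotti sphere polarizability at
D = l.

For particles smaller than the conduction-electron mean free path the metal
permittivity acquires extra surface-scattering damping; the size-corrected
permittivity is eps(a) = eps_bulk + Delta_eps(a), the difference of two
Drude terms evaluated at the bulk collision rate gamma = vF/l_mfp and the
size-augmented rate gamma_a = gamma + g vF / a.  The rod volume and the
radius fed to the size correction come from the s-cylinder model (cylinder
with hemispherical caps).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .constants import C_LIGHT

__all__ = [
    "GNRSpec",
    "DrudeParams",
    "CrossSections",
    "OpticsDomainError",
    "depolarization_factors",
    "equivalent_radius",
    "particle_volume",
    "size_corrected_permittivity",
    "gans_polarizability",
    "absorption_cross_section",
    "cross_sections",
    "volume_fraction",
    "number_density",
    "nano_absorption",
    "gold_permittivity",
    "load_dielectric_table",
    "cross_section_spectrum",
]


class OpticsDomainError(ValueError):
    """Invalid particle geometry or dielectric input."""


@dataclass(frozen=True)
class GNRSpec:
    """Gold-nanorod geometry and loading.

    diameter/length in nm, mass concentration in µg/mL, bulk gold density in
    g/cm^3 (default 19.3).
    """

    diameter_nm: float = 10.0
    length_nm: float = 41.0
    mass_concentration_ug_ml: float = 12.5
    bulk_gold_density_g_cm3: float = 19.3
    peak_wavelength_nm: float = 808.0

    def __post_init__(self) -> None:
        if not 0 < self.diameter_nm <= self.length_nm:
            raise OpticsDomainError("require 0 < diameter <= length (prolate rod)")
        if self.mass_concentration_ug_ml < 0:
            raise OpticsDomainError("mass concentration must be >= 0")

    @property
    def aspect_ratio(self) -> float:
        return self.length_nm / self.diameter_nm


@dataclass(frozen=True)
class DrudeParams:
    """Free-electron parameters of gold for the finite-size damping correction.

    plasma_frequency in rad/s, fermi_velocity in m/s, electron mean free path
    in nm; ``surface_scattering`` is the dimensionless proportionality
    constant g of the surface term (1 for gold).
    """

    plasma_frequency: float = 1.37e16
    fermi_velocity: float = 1.40e6
    mean_free_path_nm: float = 42.0
    surface_scattering: float = 1.0

    def __post_init__(self) -> None:
        if self.mean_free_path_nm <= 0:
            raise OpticsDomainError("electron mean free path must be > 0")
        if self.surface_scattering < 0:
            raise OpticsDomainError("surface scattering constant must be >= 0")

    @property
    def gamma_bulk(self) -> float:
        """Bulk collision rate vF / l_mfp, rad/s."""
        return self.fermi_velocity / (self.mean_free_path_nm * 1e-9)


@dataclass(frozen=True)
class CrossSections:
    """Per-axis polarizabilities (nm^3-scaled), depolarization factors, and C_abs (nm^2)."""

    c_abs_nm2: float
    polarizabilities: tuple[complex, complex, complex]
    depolarization: tuple[float, float, float]


def depolarization_factors(diameter_nm: float, length_nm: float) -> tuple[float, float, float]:
    """Geometric (depolarization) factors of a prolate spheroid.

    P1 is the longitudinal factor; P2 = P3 = (1 - P1)/2.  Continuous at the
    sphere limit, where all three equal 1/3.
    """
    if not 0 < diameter_nm <= length_nm:
        raise OpticsDomainError("prolate-only model requires 0 < D <= l")
    ratio = diameter_nm / length_nm
    x2 = 1.0 - ratio * ratio  # eccentricity squared
    if x2 < 1e-9:
        return (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)
    x = math.sqrt(x2)
    p1 = (1.0 - x2) / x2 * (math.log((1.0 + x) / (1.0 - x)) / (2.0 * x) - 1.0)
    p23 = (1.0 - p1) / 2.0
    return (p1, p23, p23)


def particle_volume(spec: GNRSpec) -> float:
    """s-cylinder volume, nm^3: cylinder of radius b = D/2 and length 2a with
    hemispherical caps, total length 2(a + b) = l."""
    b = spec.diameter_nm / 2.0
    a = spec.length_nm / 2.0 - b
    return 2.0 * math.pi * a * b * b + 4.0 / 3.0 * math.pi * b**3


def equivalent_radius(diameter_nm: float, length_nm: float) -> float:
    """Volume-equivalent radius of the s-cylinder, nm (equals D/2 at l = D)."""
    if length_nm < diameter_nm or diameter_nm <= 0:
        raise OpticsDomainError("require l >= D > 0")
    v = particle_volume(GNRSpec(diameter_nm=diameter_nm, length_nm=length_nm))
    return (3.0 * v / (4.0 * math.pi)) ** (1.0 / 3.0)


def _drude_term(omega: float, gamma: float, plasma_frequency: float) -> complex:
    # +wp^2/(w(w+ig)) convention; the *difference* of two such terms is the
    # size correction, so the overall Drude sign cancels out of eps_bulk.
    return plasma_frequency**2 / (omega * complex(omega, gamma))


def size_corrected_permittivity(
    a_nm: float,
    wavelength_nm: float,
    drude: DrudeParams = DrudeParams(),
    eps_bulk: complex | None = None,
) -> complex:
    """eps(a) = eps_bulk(lambda) + Delta_eps(a) with surface-scattering damping.

    Delta_eps is the difference of two Drude terms at the bulk and
    size-augmented collision rates; it vanishes as a -> infinity or when the
    surface-scattering constant g is 0, and only adds loss (Im >= 0 of the
    increment) otherwise.
    """
    if a_nm <= 0:
        raise OpticsDomainError("equivalent radius must be > 0")
    if wavelength_nm <= 0:
        raise OpticsDomainError("wavelength must be > 0")
    if eps_bulk is None:
        eps_bulk = gold_permittivity(wavelength_nm)
    omega = 2.0 * math.pi * C_LIGHT / (wavelength_nm * 1e-9)
    gamma_b = drude.gamma_bulk
    gamma_a = gamma_b + drude.surface_scattering * drude.fermi_velocity / (a_nm * 1e-9)
    delta = _drude_term(omega, gamma_b, drude.plasma_frequency) - _drude_term(
        omega, gamma_a, drude.plasma_frequency
    )
    return eps_bulk + delta


def gans_polarizability(
    eps: complex, eps_m: complex, diameter_nm: float, length_nm: float
) -> tuple[complex, complex, complex]:
    """Quasi-static polarizabilities alpha_i of a prolate spheroid, nm^3-scaled."""
    p = depolarization_factors(diameter_nm, length_nm)
    a = length_nm / 2.0
    b = diameter_nm / 2.0
    abc = a * b * b
    out = []
    for pi in p:
        denom = 3.0 * eps_m + 3.0 * pi * (eps - eps_m)
        if denom == 0:
            raise OpticsDomainError("polarizability denominator at exact resonance")
        out.append(4.0 * math.pi * abc * (eps - eps_m) / denom)
    return tuple(out)  # type: ignore[return-value]


def cross_sections(
    spec: GNRSpec, eps: complex, eps_m: complex, wavelength_nm: float
) -> CrossSections:
    """Orientation-averaged absorption cross section with its ingredients."""
    if abs(eps_m.imag) > 1e-12:
        raise OpticsDomainError("absorptive host medium is not supported")
    if eps_m.real <= 0:
        raise OpticsDomainError("host permittivity must be transparent (Re > 0)")
    alphas = gans_polarizability(eps, eps_m, spec.diameter_nm, spec.length_nm)
    k = 2.0 * math.pi * math.sqrt(eps_m.real) / wavelength_nm  # 1/nm
    c_abs = k * sum(al.imag for al in alphas) / 3.0
    return CrossSections(
        c_abs_nm2=c_abs,
        polarizabilities=alphas,
        depolarization=depolarization_factors(spec.diameter_nm, spec.length_nm),
    )


def absorption_cross_section(
    spec: GNRSpec, eps: complex, eps_m: complex, wavelength_nm: float
) -> float:
    """Orientation-averaged C_abs, nm^2."""
    return cross_sections(spec, eps, eps_m, wavelength_nm).c_abs_nm2


def volume_fraction(mass_concentration_ug_ml: float, bulk_gold_density_g_cm3: float) -> float:
    """Gold volume fraction of the suspension (dimensionless)."""
    if bulk_gold_density_g_cm3 <= 0:
        raise OpticsDomainError("bulk density must be > 0")
    if mass_concentration_ug_ml < 0:
        raise OpticsDomainError("concentration must be >= 0")
    # µg/mL = 1e-6 g/cm^3
    return mass_concentration_ug_ml * 1e-6 / bulk_gold_density_g_cm3


def number_density(mass_concentration_ug_ml: float, spec: GNRSpec) -> float:
    """Particle number density N, particles/m^3."""
    v_nm3 = particle_volume(spec)
    if v_nm3 <= 0:
        raise OpticsDomainError("particle volume must be > 0")
    frac = volume_fraction(mass_concentration_ug_ml, spec.bulk_gold_density_g_cm3)
    return frac / (v_nm3 * 1e-27)


def nano_absorption(n_per_m3: float, c_abs_nm2: float) -> tuple[float, float]:
    """Nano-absorption coefficient (1/cm) and length (cm) of the particle population.

    mu_a = N * C_abs; the length is its inverse (infinite at N = 0).
    """
    if n_per_m3 < 0 or c_abs_nm2 < 0:
        raise OpticsDomainError("inputs must be >= 0")
    mu_per_m = n_per_m3 * c_abs_nm2 * 1e-18
    mu_per_cm = mu_per_m / 100.0
    return mu_per_cm, (math.inf if mu_per_cm == 0 else 1.0 / mu_per_cm)


# -- bulk gold dielectric data ------------------------------------------------

_GOLD_TABLE: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None


def load_dielectric_table(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Load a (wavelength nm, Re eps, Im eps) delimited text table."""
    data = np.loadtxt(path)
    if data.ndim != 2 or data.shape[1] != 3:
        raise OpticsDomainError("dielectric table must have 3 columns: lambda, Re, Im")
    order = np.argsort(data[:, 0])
    return data[order, 0], data[order, 1], data[order, 2]


def gold_permittivity(wavelength_nm: float | np.ndarray) -> complex | np.ndarray:
    """Bulk gold permittivity from the packaged near-infrared table.

    The table (``data/gold_drude_synthetic.tsv``) is generated from an
    analytic Drude representation of measured gold optical constants and is
    intended for the 600-1100 nm window; interpolation is linear in lambda
    on Re and Im separately.
    """
    global _GOLD_TABLE
    if _GOLD_TABLE is None:
        with resources.as_file(
            resources.files("nanoptt.data") / "gold_drude_synthetic.tsv"
        ) as p:
            _GOLD_TABLE = load_dielectric_table(p)
    lam, re, im = _GOLD_TABLE
    w = np.asarray(wavelength_nm, dtype=float)
    if (w < lam[0]).any() or (w > lam[-1]).any():
        raise OpticsDomainError(
            f"wavelength outside tabulated range [{lam[0]:g}, {lam[-1]:g}] nm"
        )
    out = np.interp(w, lam, re) + 1j * np.interp(w, lam, im)
    return complex(out) if np.isscalar(wavelength_nm) else out


def cross_section_spectrum(
    spec: GNRSpec,
    wavelengths_nm: np.ndarray,
    eps_m: complex,
    drude: DrudeParams = DrudeParams(),
) -> np.ndarray:
    """C_abs(lambda) sweep using tabulated bulk gold plus the size correction."""
    a_eq = equivalent_radius(spec.diameter_nm, spec.length_nm)
    out = np.empty(len(wavelengths_nm))
    for i, lam in enumerate(wavelengths_nm):
        eps = size_corrected_permittivity(a_eq, float(lam), drude)
        out[i] = absorption_cross_section(spec, eps, eps_m, float(lam))
    return out
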