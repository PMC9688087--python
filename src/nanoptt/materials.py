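"""Materials and voxelized phantoms.

A :class:`Material` bundles the optical constants (refractive index,
absorption/scattering coefficients, host permittivity) and thermal constants
(density, heat capacity, diffusivity, blood perfusion) of one medium.  A
:class:`Phantom` is a uniform cubic voxel grid whose per-voxel labels index a
material table; geometry is expressed in mm with the world box centered at
the origin.

The packaged material table ships the pancreas-tissue and GNR-loaded-tumor
property sets used by the bundled scenarios, plus water and air for the
suspension benchmark.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Material",
    "Phantom",
    "InvalidGeometryError",
    "MaterialValidationError",
    "build_world",
    "embed_spherical_tumor",
    "embed_cylinder",
    "load_material_table",
    "default_material_table",
]


class InvalidGeometryError(ValueError):
    """Raised for degenerate or out-of-bounds phantom geometry."""


class MaterialValidationError(ValueError):
    """Raised when a material violates its physical invariants."""


@dataclass(frozen=True)
class Material:
    """Optical and thermal properties of one medium.

    Parameters
    ----------
    density : float
        Mass density rho, kg/m^3.
    refractive_index : float
        Real refractive index at the working wavelength.
    mu_a, mu_s : float
        Absorption and scattering coefficients, 1/cm.
    g_hg : float
        Henyey-Greenstein anisotropy factor, in [-1, 1].
    heat_capacity : float
        Specific heat Cp, J/(kg·K).
    thermal_diffusivity : float
        alpha, mm^2/s.  Thermal conductivity is derived, not stored:
        k = rho * Cp * alpha.
    perfusion : float
        Blood perfusion rate w_b, 1/s (0 for ex vivo phantoms).
    permittivity : complex
        Host dielectric function epsilon_m (dimensionless) seen by embedded
        nanoparticles.
    composition : mapping
        Element -> weight fraction; normalized weights must sum to 1.
    """

    name: str
    density: float
    refractive_index: float
    mu_a: float
    mu_s: float
    g_hg: float
    heat_capacity: float
    thermal_diffusivity: float
    perfusion: float = 0.0
    permittivity: complex = complex(1.0, 0.0)
    composition: Mapping[str, float] = field(default_factory=dict)
    blood_density: float = 1050.0
    blood_heat_capacity: float = 3617.0
    blood_temperature: float = 37.0

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise MaterialValidationError(f"{self.name}: density must be > 0")
        if self.heat_capacity <= 0:
            raise MaterialValidationError(f"{self.name}: heat capacity must be > 0")
        if self.thermal_diffusivity < 0:
            raise MaterialValidationError(f"{self.name}: diffusivity must be >= 0")
        if self.mu_a < 0 or self.mu_s < 0:
            raise MaterialValidationError(f"{self.name}: mu_a/mu_s must be >= 0")
        if abs(self.g_hg) > 1:
            raise MaterialValidationError(f"{self.name}: |g| must be <= 1")
        if self.perfusion < 0:
            raise MaterialValidationError(f"{self.name}: perfusion must be >= 0")
        if self.composition:
            weights = np.asarray(list(self.composition.values()), dtype=float)
            if (weights < 0).any():
                raise MaterialValidationError(f"{self.name}: negative weight fraction")
            if abs(weights.sum() - 1.0) > 1e-6:
                raise MaterialValidationError(
                    f"{self.name}: composition sums to {weights.sum():.8f}, not 1"
                )

    @property
    def thermal_conductivity(self) -> float:
        """k = rho * Cp * alpha, W/(m·K)."""
        return self.density * self.heat_capacity * self.thermal_diffusivity * 1e-6

    @property
    def perfusion_decay(self) -> float:
        """Q_b = (rho_b c_b)/(rho c) * w_b, 1/s — exponential heat-loss rate."""
        return (
            self.blood_density
            * self.blood_heat_capacity
            / (self.density * self.heat_capacity)
            * self.perfusion
        )


@dataclass
class Phantom:
    """Voxelized label grid mapping voxels to materials.

    ``labels[i, j, k]`` indexes ``materials``; voxel (i, j, k) occupies the
    world box ``origin + [i, j, k] * pitch`` to ``origin + [i+1, j+1, k+1] *
    pitch`` (mm), with its center at ``origin + ([i, j, k] + 0.5) * pitch``.
    """

    labels: np.ndarray
    materials: Sequence[Material]
    pitch: float
    origin: np.ndarray

    def __post_init__(self) -> None:
        if self.pitch <= 0:
            raise InvalidGeometryError("pitch must be > 0")
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.labels.ndim != 3:
            raise InvalidGeometryError("labels must be a 3-D grid")
        if self.labels.max(initial=0) >= len(self.materials):
            raise InvalidGeometryError("label without a material table entry")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.labels.shape)  # type: ignore[return-value]

    @property
    def extent(self) -> np.ndarray:
        """World edge lengths, mm."""
        return np.array(self.shape) * self.pitch

    @property
    def voxel_volume_mm3(self) -> float:
        return self.pitch**3

    @property
    def material_table(self) -> dict[str, Material]:
        return {m.name: m for m in self.materials}

    def label_of(self, name: str) -> int:
        for idx, m in enumerate(self.materials):
            if m.name == name:
                return idx
        raise KeyError(name)

    def index_of(self, point_mm: Sequence[float]) -> tuple[int, int, int]:
        """Voxel containing a world point; raises if outside the world."""
        idx = np.floor((np.asarray(point_mm, float) - self.origin) / self.pitch)
        if (idx < 0).any() or (idx >= np.array(self.shape)).any():
            raise InvalidGeometryError(f"point {point_mm} outside world")
        return tuple(int(i) for i in idx)

    def voxel_centers(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.pitch

    def contains(self, point_mm: Sequence[float]) -> bool:
        p = np.asarray(point_mm, float)
        return bool((p >= self.origin).all() and (p <= self.origin + self.extent).all())

    def volume_by_label(self) -> dict[str, float]:
        """Material name -> occupied volume, mm^3 (sums exactly to the world volume)."""
        counts = np.bincount(self.labels.ravel(), minlength=len(self.materials))
        return {m.name: int(c) * self.voxel_volume_mm3 for m, c in zip(self.materials, counts)}


def build_world(side_volume_cm3: float, pitch_mm: float, material: Material) -> Phantom:
    """Cubic world phantom of the given volume, centered at the origin.

    The cube edge is ``side_volume^(1/3)``; the grid covers at least that
    extent (voxel count is the ceiling of edge/pitch), so e.g. a 4 cm^3 cube
    at 0.25 mm pitch becomes a 64^3 grid.
    """
    if side_volume_cm3 <= 0 or pitch_mm <= 0:
        raise InvalidGeometryError("volume and pitch must be > 0")
    edge_mm = side_volume_cm3 ** (1.0 / 3.0) * 10.0
    n = int(math.ceil(edge_mm / pitch_mm - 1e-9))
    labels = np.zeros((n, n, n), dtype=np.uint8)
    origin = np.full(3, -n * pitch_mm / 2.0)
    return Phantom(labels=labels, materials=[material], pitch=pitch_mm, origin=origin)


def _with_material(phantom: Phantom, material: Material) -> tuple[Phantom, int]:
    """Return a phantom whose table contains ``material`` and its label index."""
    materials = list(phantom.materials)
    for idx, m in enumerate(materials):
        if m.name == material.name:
            return phantom, idx
    materials.append(material)
    return (
        Phantom(phantom.labels.copy(), materials, phantom.pitch, phantom.origin.copy()),
        len(materials) - 1,
    )


def embed_spherical_tumor(
    phantom: Phantom,
    volume_cm3: float,
    center_mm: Sequence[float],
    material: Material,
    clip: bool = False,
) -> Phantom:
    """Relabel voxels whose centers fall within a sphere of the given volume.

    The sphere radius is ``(3 V / 4 pi)^(1/3)``.  By default the sphere must
    fit inside the world; ``clip=True`` permits a sphere that pokes out of
    the world box, labelling only the interior part (used by the packaged
    tumor scenario, whose nominal tumor sphere is larger than the phantom's
    inscribed sphere).
    """
    if volume_cm3 <= 0:
        raise InvalidGeometryError("tumor volume must be > 0")
    center = np.asarray(center_mm, dtype=float)
    r_mm = (3.0 * volume_cm3 * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
    lo, hi = phantom.origin, phantom.origin + phantom.extent
    if not clip and ((center - r_mm < lo).any() or (center + r_mm > hi).any()):
        raise InvalidGeometryError(
            f"sphere of radius {r_mm:.3f} mm at {center} exceeds world bounds"
        )
    out, label = _with_material(phantom, material)
    xs = out.voxel_centers(0)[:, None, None]
    ys = out.voxel_centers(1)[None, :, None]
    zs = out.voxel_centers(2)[None, None, :]
    inside = (xs - center[0]) ** 2 + (ys - center[1]) ** 2 + (zs - center[2]) ** 2 <= r_mm**2
    out.labels[inside] = label
    return out


def embed_cylinder(
    phantom: Phantom,
    radius_mm: float,
    z_range_mm: tuple[float, float],
    material: Material,
    axis_xy_mm: tuple[float, float] = (0.0, 0.0),
) -> Phantom:
    """Relabel voxels inside a z-aligned cylinder (used for the water-drop well)."""
    if radius_mm <= 0:
        raise InvalidGeometryError("cylinder radius must be > 0")
    out, label = _with_material(phantom, material)
    xs = out.voxel_centers(0)[:, None, None]
    ys = out.voxel_centers(1)[None, :, None]
    zs = out.voxel_centers(2)[None, None, :]
    z0, z1 = min(z_range_mm), max(z_range_mm)
    inside = (
        ((xs - axis_xy_mm[0]) ** 2 + (ys - axis_xy_mm[1]) ** 2 <= radius_mm**2)
        & (zs >= z0)
        & (zs <= z1)
    )
    out.labels[inside] = label
    return out


_COLUMNS = (
    "name",
    "density",
    "refractive_index",
    "mu_a",
    "mu_s",
    "g_hg",
    "heat_capacity",
    "thermal_diffusivity",
    "perfusion",
    "eps_re",
    "eps_im",
)


def load_material_table(path: str | Path) -> dict[str, Material]:
    """Read a delimited material table.

    One material per row; columns: name, rho [kg/m^3], RI, mu_a [1/cm],
    mu_s [1/cm], g, Cp [J/(kg K)], alpha [mm^2/s], w_b [1/s], Re(eps_m),
    Im(eps_m), then optional ``element:weight`` pairs.  Composition weights
    are normalized by their sum at load time.
    """
    path = Path(path)
    table: dict[str, Material] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < len(_COLUMNS):
                raise MaterialValidationError(
                    f"{path.name}:{lineno}: expected at least {len(_COLUMNS)} columns "
                    f"({', '.join(_COLUMNS)}), got {len(parts)}"
                )
            name = parts[0]
            try:
                vals = [float(v) for v in parts[1 : len(_COLUMNS)]]
            except ValueError as exc:
                raise MaterialValidationError(f"{path.name}:{lineno}: {exc}") from exc
            composition: dict[str, float] = {}
            for pair in parts[len(_COLUMNS):]:
                if ":" not in pair:
                    raise MaterialValidationError(
                        f"{path.name}:{lineno}: malformed composition entry {pair!r}"
                    )
                el, w = pair.split(":", 1)
                composition[el] = float(w)
            if composition:
                total = sum(composition.values())
                if total <= 0:
                    raise MaterialValidationError(f"{path.name}:{lineno}: empty composition")
                composition = {el: w / total for el, w in composition.items()}
            table[name] = Material(
                name=name,
                density=vals[0],
                refractive_index=vals[1],
                mu_a=vals[2],
                mu_s=vals[3],
                g_hg=vals[4],
                heat_capacity=vals[5],
                thermal_diffusivity=vals[6],
                perfusion=vals[7],
                permittivity=complex(vals[8], vals[9]),
                composition=composition,
            )
    return table


def default_material_table() -> dict[str, Material]:
    """The packaged material table (pancreas, GNR-loaded tumor, water, air)."""
    with resources.as_file(resources.files("nanoptt.data") / "materials.tsv") as p:
        return load_material_table(p)


def with_optics(material: Material, **overrides) -> Material:
    """Copy of a material with selected fields replaced (convenience)."""
    return replace(material, **overrides)
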