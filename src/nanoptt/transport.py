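"""Monte Carlo optical photon transport in a voxelized phantom.

Analog transport: each photon carries the full beam energy E0 and random
walks through the grid — exponential free paths from the local total
attenuation, Henyey-Greenstein scattering, and two absorption channels
(tissue and nano-absorption by embedded nanoparticles).  An absorption
deposits E0 in the current voxel and increments its photon count; crossing
the world boundary terminates the history (the boundary is a perfect
absorber).  Refractive-index mismatch between voxels is not modelled.

The per-voxel photon counts Np drive the standard statistical-uncertainty
estimate 1/sqrt(Np(Np-1)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._kernels import transport_kernel, transport_kernel_homogeneous
from .laser import LaserBeam, _disc_basis
from .materials import InvalidGeometryError, Phantom

__all__ = [
    "TransportSettings",
    "EnergyMap",
    "sample_free_path",
    "choose_interaction",
    "scatter_direction",
    "run_transport",
    "uncertainty_map",
]


@dataclass(frozen=True)
class TransportSettings:
    """Monte Carlo run parameters."""

    n_histories: int = 2_000_000
    seed: int = 0
    max_steps: int = 1_000_000

    def __post_init__(self) -> None:
        if self.n_histories < 1:
            raise ValueError("n_histories must be >= 1")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")


@dataclass
class EnergyMap:
    """Per-voxel deposited optical energy (eV) with absorption counts.

    ``counts`` includes both channels; ``nano_counts`` is the subset absorbed
    through the nano-absorption channel.  Total deposited energy never
    exceeds ``n_histories * e0_ev``.
    """

    energy: np.ndarray
    counts: np.ndarray
    nano_counts: np.ndarray
    pitch: float
    origin: np.ndarray
    e0_ev: float
    n_histories: int
    seed: int
    n_absorbed: int
    n_escaped: int
    n_terminated: int

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.energy.shape)  # type: ignore[return-value]

    @property
    def total_energy_ev(self) -> float:
        return float(self.energy.sum())

    def peak_voxel(self) -> tuple[int, int, int]:
        """Index of the voxel with the largest absorption count."""
        return tuple(int(i) for i in np.unravel_index(np.argmax(self.counts), self.counts.shape))


def sample_free_path(mu_t_per_cm: float, u: float) -> float:
    """Exponential free path s = -ln(u)/mu_t, cm."""
    if mu_t_per_cm <= 0:
        raise ValueError("mu_t must be > 0 (vacuum handled by the transport loop)")
    if not 0.0 < u < 1.0:
        raise ValueError("u must be in (0, 1)")
    return -math.log(u) / mu_t_per_cm


def choose_interaction(
    mu_a_tissue: float, mu_a_nano: float, mu_s: float, u: float
) -> str:
    """Pick the interaction channel with probability proportional to its coefficient."""
    mu_t = mu_a_tissue + mu_a_nano + mu_s
    if mu_t <= 0:
        raise ValueError("all coefficients zero: no interaction to choose")
    xi = u * mu_t
    if xi < mu_a_tissue:
        return "tissue_absorb"
    if xi < mu_a_tissue + mu_a_nano:
        return "nano_absorb"
    return "scatter"


def scatter_direction(
    g_hg: float, incoming: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Sample a Henyey-Greenstein deflection about the incoming unit vector."""
    if abs(g_hg) >= 1:
        raise ValueError("|g| must be < 1")
    u = rng.random()
    if abs(g_hg) < 1e-12:
        ct = 1.0 - 2.0 * u
    else:
        frac = (1.0 - g_hg**2) / (1.0 - g_hg + 2.0 * g_hg * u)
        ct = (1.0 + g_hg**2 - frac**2) / (2.0 * g_hg)
        ct = min(1.0, max(-1.0, ct))
    st = math.sqrt(max(0.0, 1.0 - ct * ct))
    phi = 2.0 * math.pi * rng.random()
    ux, uy, uz = (float(v) for v in incoming)
    cp, sp = math.cos(phi), math.sin(phi)
    if abs(uz) > 0.99999:
        new = np.array([st * cp, st * sp, ct if uz > 0 else -ct])
    else:
        den = math.sqrt(1.0 - uz * uz)
        new = np.array(
            [
                st * (ux * uz * cp - uy * sp) / den + ux * ct,
                st * (uy * uz * cp + ux * sp) / den + uy * ct,
                -st * cp * den + uz * ct,
            ]
        )
    return new / np.linalg.norm(new)


def run_transport(
    phantom: Phantom,
    beam: LaserBeam,
    settings: TransportSettings,
    nano_mu_a_per_cm: dict[str, float] | None = None,
    mu_a_override_per_cm: dict[str, float] | None = None,
) -> EnergyMap:
    """Transport ``settings.n_histories`` photons and score deposited energy.

    ``nano_mu_a_per_cm`` maps material names to the nano-absorption
    coefficient of their nanoparticle load (1/cm); ``mu_a_override_per_cm``
    replaces the *tissue* absorption coefficient of the named materials
    (used when a material row's mu_a already lumps the nanoparticle
    contribution).  Deterministic for fixed (seed, n_histories).
    """
    tip = np.asarray(beam.tip_position_mm, dtype=float)
    if not phantom.contains(tip):
        raise InvalidGeometryError(f"beam tip {tip} outside the world")
    nano = nano_mu_a_per_cm or {}
    override = mu_a_override_per_cm or {}
    n_mat = len(phantom.materials)
    # 1/cm -> 1/mm
    mu_a = np.array(
        [override.get(m.name, m.mu_a) / 10.0 for m in phantom.materials], dtype=np.float64
    )
    mu_n = np.array([nano.get(m.name, 0.0) / 10.0 for m in phantom.materials], dtype=np.float64)
    mu_s = np.array([m.mu_s / 10.0 for m in phantom.materials], dtype=np.float64)
    g = np.array([m.g_hg for m in phantom.materials], dtype=np.float64)
    assert mu_a.shape == (n_mat,)
    energy = np.zeros(phantom.shape, dtype=np.float64)
    counts = np.zeros(phantom.shape, dtype=np.int64)
    nano_counts = np.zeros(phantom.shape, dtype=np.int64)
    d = np.asarray(beam.direction, dtype=float)
    e1, e2 = _disc_basis(d)
    e0 = beam.photon_energy_ev
    lab0 = int(phantom.labels.flat[0])
    if np.all(phantom.labels == lab0):
        # single-material phantom: voxel faces never interrupt a flight
        n_abs, n_esc, n_term = transport_kernel_homogeneous(
            mu_a[lab0],
            mu_n[lab0],
            mu_s[lab0],
            g[lab0],
            phantom.shape[0],
            phantom.shape[1],
            phantom.shape[2],
            phantom.pitch,
            phantom.origin[0],
            phantom.origin[1],
            phantom.origin[2],
            tip[0],
            tip[1],
            tip[2],
            d[0],
            d[1],
            d[2],
            e1[0],
            e1[1],
            e1[2],
            e2[0],
            e2[1],
            e2[2],
            beam.tip_diameter_mm / 2.0,
            e0,
            settings.n_histories,
            settings.seed,
            settings.max_steps,
            energy,
            counts,
            nano_counts,
        )
        return EnergyMap(
            energy=energy,
            counts=counts,
            nano_counts=nano_counts,
            pitch=phantom.pitch,
            origin=phantom.origin.copy(),
            e0_ev=e0,
            n_histories=settings.n_histories,
            seed=settings.seed,
            n_absorbed=int(n_abs),
            n_escaped=int(n_esc),
            n_terminated=int(n_term),
        )
    n_abs, n_esc, n_term = transport_kernel(
        phantom.labels,
        mu_a,
        mu_n,
        mu_s,
        g,
        phantom.pitch,
        phantom.origin[0],
        phantom.origin[1],
        phantom.origin[2],
        tip[0],
        tip[1],
        tip[2],
        d[0],
        d[1],
        d[2],
        e1[0],
        e1[1],
        e1[2],
        e2[0],
        e2[1],
        e2[2],
        beam.tip_diameter_mm / 2.0,
        e0,
        settings.n_histories,
        settings.seed,
        settings.max_steps,
        energy,
        counts,
        nano_counts,
    )
    return EnergyMap(
        energy=energy,
        counts=counts,
        nano_counts=nano_counts,
        pitch=phantom.pitch,
        origin=phantom.origin.copy(),
        e0_ev=e0,
        n_histories=settings.n_histories,
        seed=settings.seed,
        n_absorbed=int(n_abs),
        n_escaped=int(n_esc),
        n_terminated=int(n_term),
    )


def uncertainty_map(emap: EnergyMap) -> np.ndarray:
    """Per-voxel relative statistical uncertainty 1/sqrt(Np(Np-1)).

    Voxels with fewer than two absorbed photons have no defined estimate and
    are flagged NaN.
    """
    np_ = emap.counts.astype(np.float64)
    out = np.full(np_.shape, np.nan)
    ok = np_ >= 2
    out[ok] = 1.0 / np.sqrt(np_[ok] * (np_[ok] - 1.0))
    return out
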