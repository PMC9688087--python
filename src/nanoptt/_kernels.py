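"""Numba kernels for the analog photon random walk.

Single-threaded, seeded through numba's internal ``np.random`` state, so a
run is bit-reproducible for a given (seed, n_histories).  Free paths are
sampled from the current voxel's total attenuation and re-sampled whenever
the photon crosses into a voxel of a *different* material; same-material
voxel faces do not interrupt a flight.  Each photon carries E0 whole and is
deposited in the voxel where an absorption (tissue or nano channel) occurs;
leaving the grid terminates the history (the world boundary absorbs).

Two kernels implement identical physics: a general voxel-marching (DDA)
kernel for mixed-material phantoms, and a fast path for single-material
phantoms, where voxel faces never interrupt a flight and a step needs no
face bookkeeping.  The azimuthal scattering angle is sampled by the
unit-circle rejection trick (cos/sin of a uniform angle without
trigonometric calls).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True, inline="always")
def _rand_azimuth():
    # (cos, sin) of a uniform azimuth via rejection: for (ax, ay) uniform in
    # the unit disc, the doubled angle of (ax, ay) is uniform, and its
    # cos/sin need no sqrt: cos2p = (ax^2-ay^2)/r2, sin2p = 2 ax ay / r2.
    while True:
        ax = 2.0 * np.random.random() - 1.0
        ay = 2.0 * np.random.random() - 1.0
        r2 = ax * ax + ay * ay
        if 1e-12 < r2 <= 1.0:
            return (ax * ax - ay * ay) / r2, 2.0 * ax * ay / r2


@njit(cache=True, fastmath=True, inline="always")
def _scatter(ux: float, uy: float, uz: float, g: float):
    u = np.random.random()
    if abs(g) < 1e-12:
        ct = 1.0 - 2.0 * u
    else:
        frac = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
        ct = (1.0 + g * g - frac * frac) / (2.0 * g)
        if ct > 1.0:
            ct = 1.0
        elif ct < -1.0:
            ct = -1.0
    st = np.sqrt(max(0.0, 1.0 - ct * ct))
    cp, sp = _rand_azimuth()
    if abs(uz) > 0.99999:
        nx = st * cp
        ny = st * sp
        nz = ct if uz > 0.0 else -ct
    else:
        den = np.sqrt(1.0 - uz * uz)
        nx = st * (ux * uz * cp - uy * sp) / den + ux * ct
        ny = st * (uy * uz * cp + ux * sp) / den + uy * ct
        nz = -st * cp * den + uz * ct
    norm = np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True, fastmath=True)
def transport_kernel_homogeneous(
    mu_a,
    mu_n,
    mu_s,
    g_hg,
    nx,
    ny,
    nz,
    pitch,
    ox,
    oy,
    oz,
    tipx,
    tipy,
    tipz,
    dx,
    dy,
    dz,
    e1x,
    e1y,
    e1z,
    e2x,
    e2y,
    e2z,
    tip_radius,
    e0_ev,
    n_photons,
    seed,
    max_steps,
    energy,
    counts,
    nano_counts,
):
    """Fast path for a uniform phantom: a flight ends at its sampled length or
    outside the box; no face marching is needed."""
    np.random.seed(seed)
    inv_pitch = 1.0 / pitch
    xhi = ox + nx * pitch
    yhi = oy + ny * pitch
    zhi = oz + nz * pitch
    mt = mu_a + mu_n + mu_s
    p_abs = (mu_a + mu_n) / mt if mt > 0.0 else 0.0
    p_tissue = mu_a / mt if mt > 0.0 else 0.0
    inv_mt = 1.0 / mt if mt > 0.0 else 0.0
    n_absorbed = 0
    n_escaped = 0
    n_terminated = 0
    for _ in range(n_photons):
        r = tip_radius * np.sqrt(np.random.random())
        cp, sp = _rand_azimuth()
        x = tipx + r * (cp * e1x + sp * e2x)
        y = tipy + r * (cp * e1y + sp * e2y)
        z = tipz + r * (cp * e1z + sp * e2z)
        ux, uy, uz = dx, dy, dz
        if mt <= 0.0:
            n_escaped += 1  # vacuum world: straight through
            continue
        steps = 0
        while True:
            steps += 1
            if steps > max_steps:
                n_terminated += 1
                break
            s = -np.log(np.random.random()) * inv_mt
            x += s * ux
            y += s * uy
            z += s * uz
            if x < ox or x >= xhi or y < oy or y >= yhi or z < oz or z >= zhi:
                n_escaped += 1
                break
            xi = np.random.random()
            if xi < p_abs:
                ix = int((x - ox) * inv_pitch)
                iy = int((y - oy) * inv_pitch)
                iz = int((z - oz) * inv_pitch)
                energy[ix, iy, iz] += e0_ev
                counts[ix, iy, iz] += 1
                if xi >= p_tissue:
                    nano_counts[ix, iy, iz] += 1
                n_absorbed += 1
                break
            ux, uy, uz = _scatter(ux, uy, uz, g_hg)
    return n_absorbed, n_escaped, n_terminated


@njit(cache=True, fastmath=True)
def transport_kernel(
    labels,  # (nx,ny,nz) uint8
    mu_a,  # per-label tissue absorption, 1/mm
    mu_n,  # per-label nano absorption, 1/mm
    mu_s,  # per-label scattering, 1/mm
    g_hg,  # per-label anisotropy
    pitch,
    ox,
    oy,
    oz,
    tipx,
    tipy,
    tipz,
    dx,
    dy,
    dz,
    e1x,
    e1y,
    e1z,
    e2x,
    e2y,
    e2z,
    tip_radius,
    e0_ev,
    n_photons,
    seed,
    max_steps,
    energy,  # (nx,ny,nz) float64, in/out
    counts,  # (nx,ny,nz) int64, in/out
    nano_counts,  # (nx,ny,nz) int64, in/out
):
    np.random.seed(seed)
    nx, ny, nz = labels.shape
    inv_pitch = 1.0 / pitch
    big = 1e30
    n_absorbed = 0
    n_escaped = 0
    n_terminated = 0
    for _ in range(n_photons):
        # launch on the tip disc
        r = tip_radius * np.sqrt(np.random.random())
        ca, sa = _rand_azimuth()
        x = tipx + r * (ca * e1x + sa * e2x)
        y = tipy + r * (ca * e1y + sa * e2y)
        z = tipz + r * (ca * e1z + sa * e2z)
        ux, uy, uz = dx, dy, dz
        inv_ux = big if ux == 0.0 else 1.0 / ux
        inv_uy = big if uy == 0.0 else 1.0 / uy
        inv_uz = big if uz == 0.0 else 1.0 / uz
        ix = int(np.floor((x - ox) * inv_pitch))
        iy = int(np.floor((y - oy) * inv_pitch))
        iz = int(np.floor((z - oz) * inv_pitch))
        if ix < 0 or ix >= nx or iy < 0 or iy >= ny or iz < 0 or iz >= nz:
            n_escaped += 1
            continue
        alive = True
        steps = 0
        while alive:
            steps += 1
            if steps > max_steps:
                n_terminated += 1
                break
            lab = labels[ix, iy, iz]
            ma = mu_a[lab]
            mn = mu_n[lab]
            ms = mu_s[lab]
            mt = ma + mn + ms
            if mt <= 0.0:
                s = big  # vacuum: fly to the next material change or the boundary
            else:
                s = -np.log(np.random.random()) / mt
            # consume the flight, voxel face by voxel face
            interacted = False
            while True:
                # distance to the exit face of voxel (ix,iy,iz)
                if ux > 0.0:
                    tx = ((ix + 1) * pitch + ox - x) * inv_ux
                elif ux < 0.0:
                    tx = (ix * pitch + ox - x) * inv_ux
                else:
                    tx = big
                if uy > 0.0:
                    ty = ((iy + 1) * pitch + oy - y) * inv_uy
                elif uy < 0.0:
                    ty = (iy * pitch + oy - y) * inv_uy
                else:
                    ty = big
                if uz > 0.0:
                    tz = ((iz + 1) * pitch + oz - z) * inv_uz
                elif uz < 0.0:
                    tz = (iz * pitch + oz - z) * inv_uz
                else:
                    tz = big
                tb = tx
                axis = 0
                if ty < tb:
                    tb = ty
                    axis = 1
                if tz < tb:
                    tb = tz
                    axis = 2
                if tb < 0.0:
                    tb = 0.0
                if s <= tb:
                    x += s * ux
                    y += s * uy
                    z += s * uz
                    interacted = mt > 0.0
                    break
                # cross into the next voxel; the index is authoritative
                x += tb * ux
                y += tb * uy
                z += tb * uz
                s -= tb
                if axis == 0:
                    ix += 1 if ux > 0.0 else -1
                elif axis == 1:
                    iy += 1 if uy > 0.0 else -1
                else:
                    iz += 1 if uz > 0.0 else -1
                if ix < 0 or ix >= nx or iy < 0 or iy >= ny or iz < 0 or iz >= nz:
                    alive = False
                    n_escaped += 1
                    break
                if labels[ix, iy, iz] != lab:
                    break  # re-sample the free path in the new material
            if not alive or not interacted:
                continue
            xi = np.random.random() * mt
            if xi < ma + mn:
                energy[ix, iy, iz] += e0_ev
                counts[ix, iy, iz] += 1
                if xi >= ma:
                    nano_counts[ix, iy, iz] += 1
                n_absorbed += 1
                alive = False
            else:
                ux, uy, uz = _scatter(ux, uy, uz, g_hg[lab])
                inv_ux = big if ux == 0.0 else 1.0 / ux
                inv_uy = big if uy == 0.0 else 1.0 / uy
                inv_uz = big if uz == 0.0 else 1.0 / uz
    return n_absorbed, n_escaped, n_terminated
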