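"""Scenario runner, probes, temperature maps and the benchmark error metric.

A *scenario* is a YAML description of one virtual experiment: world and
tumor geometry, material names, nanoparticle load, beam, transport settings,
thermal model, probe positions and output times.  ``run_scenario`` executes
the full chain — phantom build, GNR optics, Monte Carlo transport, heat
conversion, diffusion, probe extraction — and optionally writes all
artifacts (voxel volumes, probe series, a resolved-parameter manifest) to an
output directory.  Two scenarios ship with the package:

* ``pancreas_ptt`` — interstitial 808 nm irradiation at the center of a
  nanorod-loaded tumor embedded in a cubic pancreas phantom;
* ``water_drop`` — contactless surface irradiation of a 0.1 mL nanorod
  suspension drop, the calibration benchmark geometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

from . import bioheat, optics, voxio
from .laser import LaserBeam, flux_scaling_factor
from .materials import (
    InvalidGeometryError,
    Phantom,
    build_world,
    default_material_table,
    embed_cylinder,
    embed_spherical_tumor,
    load_material_table,
)
from .transport import EnergyMap, TransportSettings, run_transport, uncertainty_map

__all__ = [
    "Probe",
    "ScenarioError",
    "RunResult",
    "load_scenario",
    "packaged_scenario_path",
    "probe_series",
    "relative_error",
    "apply_threshold",
    "plane_map",
    "build_scenario_phantom",
    "deposition_rate",
    "run_scenario",
]


class ScenarioError(ValueError):
    """Inconsistent or invalid scenario configuration."""


@dataclass
class Probe:
    """Temperature time series of the voxel containing a world position."""

    name: str
    position_mm: tuple[float, float, float]
    times_s: np.ndarray
    deltaT_c: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.deltaT_c = np.asarray(self.deltaT_c, dtype=float)
        if len(self.times_s) != len(self.deltaT_c):
            raise ScenarioError("probe series lengths differ")
        if (np.diff(self.times_s) <= 0).any():
            raise ScenarioError("probe times must be strictly increasing")

    def at(self, t_s: float) -> float:
        idx = np.nonzero(np.isclose(self.times_s, t_s))[0]
        if len(idx) == 0:
            raise KeyError(f"time {t_s} not in probe series")
        return float(self.deltaT_c[idx[0]])


def probe_series(
    fields: Sequence[bioheat.TemperatureField], position_mm: Sequence[float], name: str = "probe"
) -> Probe:
    """Nearest-voxel (containing-voxel) sampling of a field time series."""
    if not fields:
        raise ScenarioError("no temperature fields to probe")
    ref = fields[0]
    pitch, origin = ref.pitch, ref.origin
    shape = np.array(ref.deltaT.shape)
    idx = np.floor((np.asarray(position_mm, float) - origin) / pitch).astype(int)
    if (idx < 0).any() or (idx >= shape).any():
        raise InvalidGeometryError(f"probe position {position_mm} outside world")
    i, j, k = (int(v) for v in idx)
    return Probe(
        name=name,
        position_mm=tuple(float(v) for v in position_mm),
        times_s=np.array([f.time_s for f in fields]),
        deltaT_c=np.array([f.deltaT[i, j, k] for f in fields]),
    )


def relative_error(experiment: float, simulation: float) -> float:
    """|(experiment - simulation)/experiment| × 100, %."""
    if experiment == 0:
        raise ZeroDivisionError("relative error undefined for a zero reference")
    return abs((experiment - simulation) / experiment) * 100.0


def apply_threshold(probe: Probe, threshold_c: float) -> Probe:
    """Truncate a series at the first sample exceeding the reporting threshold.

    Mirrors the convention of excluding non-physical readings (no phase
    change or carbonization in the model) above a maximum temperature.
    """
    if threshold_c <= 0:
        raise ScenarioError("threshold must be > 0")
    over = np.nonzero(probe.deltaT_c > threshold_c)[0]
    if len(over) == 0:
        return probe
    stop = int(over[0])
    return Probe(
        name=probe.name,
        position_mm=probe.position_mm,
        times_s=probe.times_s[:stop],
        deltaT_c=probe.deltaT_c[:stop],
    )


_AXES = {"x": 0, "y": 1, "z": 2}


def plane_map(field: bioheat.TemperatureField, axis: str, offset_mm: float) -> np.ndarray:
    """2-D ΔT slice perpendicular to ``axis`` at the given world offset."""
    try:
        ax = _AXES[axis]
    except KeyError:
        raise ScenarioError(f"axis must be one of {sorted(_AXES)}") from None
    n = field.deltaT.shape[ax]
    idx = int(np.floor((offset_mm - field.origin[ax]) / field.pitch))
    if not 0 <= idx < n:
        raise InvalidGeometryError(f"offset {offset_mm} mm outside world along {axis}")
    return np.take(field.deltaT, idx, axis=ax)


# -- scenario configuration ---------------------------------------------------


def packaged_scenario_path(name: str) -> Path:
    """Filesystem path of a packaged scenario (``pancreas_ptt`` etc.)."""
    ref = resources.files("nanoptt.scenarios") / f"{name}.yaml"
    with resources.as_file(ref) as p:
        return Path(p)


def load_scenario(source: str | Path | dict[str, Any]) -> dict[str, Any]:
    """Load a scenario config from a dict, a file path, or a packaged name."""
    if isinstance(source, dict):
        return json.loads(json.dumps(source))  # deep copy
    path = Path(source)
    if not path.exists() and not path.suffix:
        path = packaged_scenario_path(str(source))
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ScenarioError(f"{path}: scenario must be a mapping")
    return cfg


def build_scenario_phantom(cfg: dict[str, Any]) -> Phantom:
    """World + optional tumor sphere / drop cylinder from a scenario config."""
    table = (
        load_material_table(cfg["materials_file"])
        if "materials_file" in cfg
        else default_material_table()
    )
    world = cfg["world"]
    phantom = build_world(world["volume_cm3"], world["pitch_mm"], table[world["material"]])
    tumor = cfg.get("tumor")
    if tumor:
        phantom = embed_spherical_tumor(
            phantom,
            tumor["volume_cm3"],
            tumor.get("center_mm", (0.0, 0.0, 0.0)),
            table[tumor["material"]],
            clip=bool(tumor.get("clip", False)),
        )
    drop = cfg.get("drop")
    if drop:
        phantom = embed_cylinder(
            phantom,
            drop["radius_mm"],
            tuple(drop["z_range_mm"]),
            table[drop["material"]],
            axis_xy_mm=tuple(drop.get("axis_xy_mm", (0.0, 0.0))),
        )
    return phantom


def _beam_from_cfg(cfg: dict[str, Any]) -> LaserBeam:
    b = cfg["beam"]
    return LaserBeam(
        wavelength_nm=float(b.get("wavelength_nm", 808.0)),
        power_w=float(b["power_w"]),
        tip_diameter_mm=float(b["tip_diameter_mm"]),
        tip_position_mm=tuple(b.get("tip_position_mm", (0.0, 0.0, 0.0))),
        direction=tuple(b.get("direction", (0.0, 0.0, 1.0))),
        emission_rate=float(b.get("emission_rate", 2.0e6)),
        duration_s=float(b.get("duration_s", 120.0)),
        area_unit=str(b.get("area_unit", "mm2")),
    )


@dataclass
class GNRLoad:
    """Resolved nanoparticle optics of a scenario."""

    spec: optics.GNRSpec
    host_material: str
    permittivity: complex
    host_permittivity: complex
    c_abs_nm2: float
    number_density_m3: float
    mu_a_nano_per_cm: float
    absorption_length_cm: float
    mode: str  # "from_gnr" or "table"
    tissue_mu_a_per_cm: float | None


def resolve_gnr(cfg: dict[str, Any], phantom: Phantom, beam: LaserBeam) -> GNRLoad | None:
    g = cfg.get("gnr")
    if not g:
        return None
    spec = optics.GNRSpec(
        diameter_nm=float(g.get("diameter_nm", 10.0)),
        length_nm=float(g.get("length_nm", 41.0)),
        mass_concentration_ug_ml=float(g.get("concentration_ug_ml", 12.5)),
        bulk_gold_density_g_cm3=float(g.get("bulk_gold_density_g_cm3", 19.3)),
    )
    host = g["host_material"]
    host_eps = phantom.material_table[host].permittivity
    if "permittivity" in g:
        re, im = g["permittivity"]
        eps = complex(float(re), float(im))
    else:
        a_eq = optics.equivalent_radius(spec.diameter_nm, spec.length_nm)
        eps = optics.size_corrected_permittivity(a_eq, beam.wavelength_nm)
    c_abs = optics.absorption_cross_section(spec, eps, host_eps, beam.wavelength_nm)
    n = optics.number_density(spec.mass_concentration_ug_ml, spec)
    mu_nano, l_a = optics.nano_absorption(n, c_abs)
    mode = str(g.get("nano_absorption", "from_gnr"))
    if mode not in ("from_gnr", "table"):
        raise ScenarioError("gnr.nano_absorption must be 'from_gnr' or 'table'")
    tissue_mu_a = g.get("tissue_mu_a_per_cm")
    return GNRLoad(
        spec=spec,
        host_material=host,
        permittivity=eps,
        host_permittivity=host_eps,
        c_abs_nm2=c_abs,
        number_density_m3=n,
        mu_a_nano_per_cm=mu_nano,
        absorption_length_cm=l_a,
        mode=mode,
        tissue_mu_a_per_cm=None if tissue_mu_a is None else float(tissue_mu_a),
    )


def deposition_rate(
    emap: EnergyMap,
    phantom: Phantom,
    beam: LaserBeam,
    gnr: GNRLoad | None,
    heating: str = "energy",
    conductivity_w_mk: float | None = None,
) -> np.ndarray:
    """Physical per-voxel heating rate, °C/s, from a simulated energy map.

    The map is first normalized to one second of simulated emission
    (``emission_rate / n_histories``) and flux-scaled to the physical beam.
    ``heating='energy'`` applies the calorimetric factor F of each voxel's
    material everywhere (default); ``heating='steady'`` instead converts
    nanoparticle-host voxels with the per-voxel steady-state estimate
    ΔT = N R² C_abs I/(2k).
    """
    if heating not in ("energy", "steady"):
        raise ScenarioError("heating must be 'energy' or 'steady'")
    scaling = flux_scaling_factor(beam)
    per_second = beam.emission_rate / emap.n_histories
    voxel_volume_m3 = (phantom.pitch * 1e-3) ** 3
    f_by_label = np.array(
        [
            bioheat.conversion_factor(m.heat_capacity, m.density * voxel_volume_m3)
            for m in phantom.materials
        ]
    )
    rate = emap.energy * f_by_label[phantom.labels] * scaling * per_second
    if heating == "steady":
        if gnr is None:
            raise ScenarioError("steady heating requires a gnr block")
        host_label = phantom.label_of(gnr.host_material)
        host = phantom.materials[host_label]
        k = conductivity_w_mk if conductivity_w_mk is not None else host.thermal_conductivity
        r_m = phantom.pitch / 2.0 * 1e-3
        area_m2 = (phantom.pitch * 1e-3) ** 2
        mask = phantom.labels == host_label
        irr = bioheat.voxel_irradiance(1.0, 1.0, area_m2) * emap.energy[mask] * per_second
        rate[mask] = (
            bioheat.gnr_deltaT(gnr.number_density_m3, r_m, gnr.c_abs_nm2 * 1e-18, 1.0, k)
            * irr
            * scaling
        )
    return rate


@dataclass
class RunResult:
    """Artifacts of one scenario execution."""

    config: dict[str, Any]
    phantom: Phantom
    beam: LaserBeam
    gnr: GNRLoad | None
    emap: EnergyMap
    fields: list[bioheat.TemperatureField]
    probes: dict[str, Probe]
    summary: dict[str, Any] = field(default_factory=dict)


def run_scenario(
    source: str | Path | dict[str, Any],
    seed: int | None = None,
    outdir: str | Path | None = None,
    overrides: dict[str, Any] | None = None,
) -> RunResult:
    """Execute a scenario end to end.

    ``overrides`` maps dotted config keys (e.g. ``beam.power_w``) to
    replacement values.  With the same config and seed the transport stage
    is bit-reproducible and everything downstream is deterministic.
    """
    cfg = load_scenario(source)
    for key, value in (overrides or {}).items():
        node = cfg
        parts = key.split(".")
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        node[parts[-1]] = value
    phantom = build_scenario_phantom(cfg)
    beam = _beam_from_cfg(cfg)
    gnr = resolve_gnr(cfg, phantom, beam)

    tcfg = cfg.get("transport", {})
    settings = TransportSettings(
        n_histories=int(tcfg.get("n_histories", 2_000_000)),
        seed=int(seed if seed is not None else tcfg.get("seed", 0)),
        max_steps=int(tcfg.get("max_steps", 1_000_000)),
    )
    nano = {}
    override_mu = {}
    if gnr is not None and gnr.mode == "from_gnr":
        nano[gnr.host_material] = gnr.mu_a_nano_per_cm
        if gnr.tissue_mu_a_per_cm is not None:
            override_mu[gnr.host_material] = gnr.tissue_mu_a_per_cm
    emap = run_transport(phantom, beam, settings, nano_mu_a_per_cm=nano,
                         mu_a_override_per_cm=override_mu)

    th = cfg.get("thermal", {})
    world_mat = phantom.material_table[cfg["world"]["material"]]
    alpha = float(th.get("alpha_mm2_s", world_mat.thermal_diffusivity))
    hot_mat = phantom.material_table[gnr.host_material] if gnr else world_mat
    model = bioheat.ThermalModel(
        alpha_mm2_s=alpha,
        conductivity_w_mk=float(th.get("conductivity_w_mk", hot_mat.thermal_conductivity)),
        q_b=float(th.get("perfusion_decay", 0.0)),
        baseline_c=float(th.get("baseline_c", 26.0)),
    )
    heating = str(th.get("heating", "energy"))
    rate = deposition_rate(emap, phantom, beam, gnr, heating=heating,
                           conductivity_w_mk=model.conductivity_w_mk)
    times = [float(t) for t in cfg.get("times_s", [beam.duration_s])]
    fields = bioheat.irradiate(
        rate,
        model,
        times,
        phantom.pitch,
        phantom.origin,
        heating_duration_s=beam.duration_s,
        dt_s=float(th.get("dt_s", 1.0)),
    )
    for f in fields:
        f.baseline_c = model.baseline_c

    probes: dict[str, Probe] = {}
    for p in cfg.get("probes", []):
        probes[p["name"]] = probe_series(fields, p["position_mm"], name=p["name"])

    threshold = float(cfg.get("threshold_c", 155.0))
    unc = uncertainty_map(emap)
    peak = emap.peak_voxel()
    summary: dict[str, Any] = {
        "name": cfg.get("name", "scenario"),
        "seed": settings.seed,
        "n_histories": settings.n_histories,
        "n_absorbed": emap.n_absorbed,
        "n_escaped": emap.n_escaped,
        "n_terminated": emap.n_terminated,
        "flux_scaling_factor": flux_scaling_factor(beam),
        "peak_voxel_counts": int(emap.counts[peak]),
        "peak_voxel_uncertainty_pct": float(unc[peak] * 100.0),
        "max_deltaT_c": float(max(f.deltaT.max() for f in fields)),
        "threshold_c": threshold,
        "heating": heating,
        "probes": {
            name: {
                "deltaT_c": pr.deltaT_c.tolist(),
                "times_s": pr.times_s.tolist(),
                "thresholded_times_s": apply_threshold(pr, threshold).times_s.tolist(),
            }
            for name, pr in probes.items()
        },
    }
    if gnr is not None:
        summary["gnr"] = {
            "c_abs_nm2": gnr.c_abs_nm2,
            "number_density_m3": gnr.number_density_m3,
            "mu_a_nano_per_cm": gnr.mu_a_nano_per_cm,
            "absorption_length_cm": gnr.absorption_length_cm,
            "mode": gnr.mode,
        }

    result = RunResult(cfg, phantom, beam, gnr, emap, fields, probes, summary)
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _write_outputs(result: RunResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    emap = result.emap
    voxio.write_map(voxio.VoxelMap(emap.energy, emap.pitch, emap.origin), outdir / "energy_ev")
    voxio.write_map(
        voxio.VoxelMap(emap.counts.astype(np.float64), emap.pitch, emap.origin),
        outdir / "photon_counts",
    )
    final = result.fields[-1]
    voxio.write_map(
        voxio.VoxelMap(final.deltaT, final.pitch, final.origin),
        outdir / f"deltaT_{final.time_s:g}s",
    )
    for name, probe in result.probes.items():
        lines = ["# time_s\tdeltaT_C"] + [
            f"{t:.6g}\t{v:.6g}" for t, v in zip(probe.times_s, probe.deltaT_c)
        ]
        (outdir / f"probe_{name}.tsv").write_text("\n".join(lines) + "\n")
    (outdir / "manifest.json").write_text(json.dumps(result.summary, indent=1, default=str))
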