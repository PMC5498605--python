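"""Pipeline orchestration: one declarative configuration, per-scenario runs.

The whole analysis — phantom generation or label-map ingestion, optional
registration, geometry creation, meshing, per-scenario finite element
solves, strength and RPI computation — runs from a single YAML
configuration.  Every intermediate artifact is written to the output
directory (STL surfaces, legacy VTK meshes, VTP result surfaces, a JSON
summary), each scenario in its own folder, and the run is deterministic for
a fixed configuration and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError
from .fem import (
    DEFAULT_MATERIALS,
    MMHG_TO_MPA,
    Material,
    ScenarioSpec,
    compare_scenarios,
    excluded_peak_sigma1,
    solve_scenario,
    solve_scenarios,
)
from .geometry import build_geometry
from .labelmap import read_labelmap
from .meshing import mesh_regions, quality_report
from .phantom import PhantomSpec, generate_phantom
from .rpi import (
    PatientFactors,
    StrengthModelParams,
    boundary_exclusion,
    diameter_profile,
    nord_field,
    rpi_field,
    wall_strength,
)
from .thickness import load_thickness_annotations, thickness_field

log = logging.getLogger("aaarpi")

__all__ = ["RunConfig", "validate_config", "load_config", "run_pipeline"]

_KNOWN_KEYS = {
    "phantom",
    "aaa_labelmap",
    "lumen_labelmap",
    "register_lumen",
    "wall_thickness_mm",
    "thickness_annotations",
    "pressure",
    "scenarios",
    "n_layers",
    "min_ilt_thickness_mm",
    "element_order",
    "target_edge_mm",
    "materials",
    "exclusion_distance_mm",
    "patient",
    "strength_model",
    "output_dir",
    "seed",
}

_SCENARIOS = ("ilt_pressure", "wall_pressure", "no_ilt")


@dataclass
class RunConfig:
    """Normalized run configuration (units already converted)."""

    phantom: PhantomSpec | None
    aaa_labelmap: str | None
    lumen_labelmap: str | None
    register_lumen: bool
    wall_thickness_mm: float | None
    thickness_annotations: list[str]
    pressure_mpa: float
    scenarios: list[str]
    n_layers: int
    min_ilt_thickness_mm: float
    element_order: int
    target_edge_mm: float
    materials: dict[str, Material]
    exclusion_distance_mm: float
    patient: PatientFactors
    strength_model: StrengthModelParams
    output_dir: str
    seed: int
    applied_defaults: list[str] = field(default_factory=list)


def _parse_pressure(value) -> tuple[float, bool]:
    """Accept a number (mmHg) or strings like '120 mmHg' / '0.016 MPa'."""
    if isinstance(value, (int, float)):
        return float(value) * MMHG_TO_MPA, False
    s = str(value).strip().lower()
    for unit, factor in (("mmhg", MMHG_TO_MPA), ("kpa", 1e-3), ("mpa", 1.0)):
        if s.endswith(unit):
            try:
                return float(s[: -len(unit)].strip()) * factor, False
            except ValueError:
                break
    raise ConfigError(f"cannot parse pressure {value!r} (use e.g. '120 mmHg')")


def validate_config(raw: dict) -> RunConfig:
    """Fill defaults, normalize units, and reject unknown keys.

    Defaults: 120 mmHg pressure, 1.5 mm constant wall thickness, 2 element
    layers across the wall, 1 mm minimum ILT thickness, quadratic elements,
    all three scenarios, 10 mm boundary exclusion.
    """
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a mapping")
    unknown = sorted(set(raw) - _KNOWN_KEYS)
    if unknown:
        raise ConfigError(f"unknown configuration keys: {', '.join(unknown)}")
    applied = []

    def default(key, value):
        applied.append(f"{key} = {value!r}")
        return value

    phantom = None
    if "phantom" in raw:
        ph = raw["phantom"] or {}
        if not isinstance(ph, dict):
            raise ConfigError("phantom must be a mapping of PhantomSpec fields")
        if "voxel_spacing" in ph:
            ph["voxel_spacing"] = tuple(ph["voxel_spacing"])
        phantom = PhantomSpec(**ph)
    aaa_lm = raw.get("aaa_labelmap")
    if phantom is None and aaa_lm is None:
        raise ConfigError("either 'phantom' or 'aaa_labelmap' is required")
    if aaa_lm is not None and not Path(aaa_lm).exists():
        raise ConfigError(f"aaa_labelmap not found: {aaa_lm}")
    lumen_lm = raw.get("lumen_labelmap")
    if lumen_lm is not None and not Path(lumen_lm).exists():
        raise ConfigError(f"lumen_labelmap not found: {lumen_lm}")

    scenarios = raw.get("scenarios")
    if scenarios is None:
        scenarios = default("scenarios", list(_SCENARIOS))
    if not scenarios:
        raise ConfigError("scenario list must not be empty")
    bad = [s for s in scenarios if s not in _SCENARIOS]
    if bad:
        raise ConfigError(f"unknown scenarios: {bad}; valid: {_SCENARIOS}")

    pressure_raw = raw.get("pressure")
    if pressure_raw is None:
        pressure_raw = default("pressure", "120 mmHg")
    pressure_mpa, _ = _parse_pressure(pressure_raw)
    if pressure_mpa <= 0:
        raise ConfigError("pressure must be positive")

    annotations = list(raw.get("thickness_annotations") or [])
    wall_th = raw.get("wall_thickness_mm")
    if wall_th is None and not annotations:
        wall_th = default("wall_thickness_mm", 1.5)
    if wall_th is not None and wall_th <= 0:
        raise ConfigError("wall thickness must be positive")
    for a in annotations:
        if not Path(a).exists():
            raise ConfigError(f"thickness annotation not found: {a}")

    mats = dict(DEFAULT_MATERIALS)
    for region, spec in (raw.get("materials") or {}).items():
        if region not in ("wall", "ilt"):
            raise ConfigError(f"unknown material region {region!r}")
        mats[region] = Material(
            float(spec["youngs_modulus_mpa"]), float(spec["poisson_ratio"])
        )

    pat = raw.get("patient") or {}
    patient = PatientFactors(
        sex=pat.get("sex", "female"),
        family_history=bool(pat.get("family_history", False)),
    )
    sm = StrengthModelParams(**(raw.get("strength_model") or {}))

    order = int(raw.get("element_order") or default("element_order", 2))
    if order not in (1, 2):
        raise ConfigError("element_order must be 1 or 2")

    cfg = RunConfig(
        phantom=phantom,
        aaa_labelmap=aaa_lm,
        lumen_labelmap=lumen_lm,
        register_lumen=bool(raw.get("register_lumen", False)),
        wall_thickness_mm=wall_th,
        thickness_annotations=annotations,
        pressure_mpa=pressure_mpa,
        scenarios=list(scenarios),
        n_layers=int(raw.get("n_layers") or default("n_layers", 2)),
        min_ilt_thickness_mm=float(
            raw.get("min_ilt_thickness_mm")
            or default("min_ilt_thickness_mm", 1.0)
        ),
        element_order=order,
        target_edge_mm=float(
            raw.get("target_edge_mm") or default("target_edge_mm", 3.0)
        ),
        materials=mats,
        exclusion_distance_mm=float(
            raw.get("exclusion_distance_mm")
            or default("exclusion_distance_mm", 10.0)
        ),
        patient=patient,
        strength_model=sm,
        output_dir=str(raw.get("output_dir") or default("output_dir", "aaarpi_out")),
        seed=int(raw.get("seed", 0)),
        applied_defaults=applied,
    )
    if cfg.n_layers < 1:
        raise ConfigError("n_layers must be >= 1")
    for d in applied:
        log.info("default applied: %s", d)
    return cfg


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return validate_config(raw or {})


def _thickness_source(cfg: RunConfig):
    if cfg.thickness_annotations:
        ms = load_thickness_annotations(cfg.thickness_annotations)
        return lambda surf: thickness_field(surf, ms)
    return lambda surf: np.full(surf.n_vertices, cfg.wall_thickness_mm)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run report."""
    from . import vtkio
    from .register import register_rigid, resample_labelmap

    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)

    report: dict = {
        "config": _config_echo(cfg),
        "stages": {},
    }

    # --- stage 1: inputs -------------------------------------------------
    if cfg.phantom is not None:
        aaa, lumen, truth = generate_phantom(cfg.phantom)
        report["stages"]["phantom"] = {
            "truth_max_diameter_mm": truth.max_diameter,
            "truth_neck_diameter_mm": truth.neck_diameter,
            "truth_nord_max": truth.nord_max,
            "truth_max_ilt_thickness_mm": truth.max_ilt_thickness,
        }
    else:
        aaa = read_labelmap(cfg.aaa_labelmap)
        lumen = read_labelmap(cfg.lumen_labelmap) if cfg.lumen_labelmap else None
        if lumen is not None and cfg.register_lumen:
            t = register_rigid(aaa, lumen)
            lumen = resample_labelmap(lumen, t, aaa)
            report["stages"]["registration"] = {
                "rotation_deg": t.rotation_angle_deg(),
                "translation_mm": t.translation.tolist(),
                "centroid_only": t.centroid_only,
            }
    needs_ilt = any(s != "no_ilt" for s in cfg.scenarios)
    if needs_ilt and lumen is None:
        log.info("no lumen label map: ILT scenarios skipped")
        cfg.scenarios = [s for s in cfg.scenarios if s == "no_ilt"]
        if not cfg.scenarios:
            raise ConfigError("no runnable scenario without a lumen label map")

    # --- stage 2: geometry ----------------------------------------------
    geom, sf = build_geometry(
        aaa,
        lumen,
        _thickness_source(cfg),
        target_edge=cfg.target_edge_mm,
        min_ilt_thickness=cfg.min_ilt_thickness_mm,
        n_layers=cfg.n_layers,
    )
    vtkio.write_stl(geom.external_wall, out / "external_wall.stl")
    vtkio.write_stl(geom.internal_wall, out / "internal_wall.stl")
    if geom.has_ilt():
        vtkio.write_stl(geom.ilt_luminal, out / "ilt_luminal.stl")
    report["stages"]["geometry"] = {
        "external_vertices": geom.external_wall.n_vertices,
        "min_ilt_thickness_mm": float(geom.ilt_thickness.min())
        if geom.has_ilt()
        else None,
        "max_ilt_thickness_mm": float(geom.ilt_thickness.max()),
    }

    # --- stage 3: diameters / NORD / strength ----------------------------
    dp = diameter_profile(geom.external_wall)
    nord = nord_field(geom.external_wall, dp)
    strength = wall_strength(
        geom.ilt_thickness, nord, cfg.patient, cfg.strength_model
    )
    log.info(
        "strength model constants: %s", json.dumps(asdict(cfg.strength_model))
    )
    report["stages"]["diameters"] = {
        "max_diameter_mm": dp.max_diameter,
        "neck_diameter_mm": dp.neck_diameter,
        "max_nord": dp.nord_max,
    }

    # --- stage 4: meshing + per-scenario FEM -----------------------------
    with_ilt_scen = [s for s in cfg.scenarios if s != "no_ilt"]
    peaks: dict[str, float] = {}
    peak_rpis: dict[str, float] = {}
    results = {}
    mesh_cache = {}

    def run_mesh(include_ilt: bool):
        key = include_ilt
        if key not in mesh_cache:
            m = mesh_regions(geom, sf, order=cfg.element_order, include_ilt=include_ilt)
            mesh_cache[key] = m
            tag = "wall_ilt" if include_ilt else "wall_only"
            vtkio.write_vtk_mesh(m, out / f"mesh_{tag}.vtk")
            report["stages"][f"mesh_{tag}"] = quality_report(m)
        return mesh_cache[key]

    def postprocess(name: str, mesh, res):
        sdir = out / name
        sdir.mkdir(exist_ok=True)
        excl = boundary_exclusion(mesh.nodes, cfg.exclusion_distance_mm)
        peaks[name] = excluded_peak_sigma1(mesh, res, excl)
        # map stress to the external wall surface vertices (sheet 0 nodes)
        nv = geom.external_wall.n_vertices
        sigma1_surf = res.nodal_sigma1[:nv]
        ilt_for_strength = (
            geom.ilt_thickness if name != "no_ilt" else np.zeros(nv)
        )
        strength_s = wall_strength(
            ilt_for_strength, nord, cfg.patient, cfg.strength_model
        )
        rpi, peak = rpi_field(
            sigma1_surf,
            strength_s,
            boundary_exclusion(geom.external_wall.vertices, cfg.exclusion_distance_mm),
        )
        peak_rpis[name] = peak
        surf = geom.external_wall.copy()
        surf.vertex_fields.update(
            {
                "ilt_thickness_mm": ilt_for_strength,
                "nord": nord,
                "strength_mpa": strength_s,
                "sigma1_mpa": sigma1_surf,
                "rpi": rpi,
            }
        )
        vtkio.write_vtp_surface(surf, sdir / "results.vtp")
        vtkio.write_vtk_mesh(
            mesh, sdir / "mesh_sigma1.vtk", {"sigma1_mpa": res.nodal_sigma1}
        )
        report["stages"][f"scenario_{name}"] = {
            "peak_sigma1_mpa": peaks[name],
            "peak_rpi": peak,
            "equilibrium_residual": res.equilibrium_residual,
        }
        if peak >= 1.0:
            log.warning("%s: peak RPI %.2f >= 1 (theoretical rupture)", name, peak)

    if with_ilt_scen:
        mesh_ilt = run_mesh(True)
        specs = [
            ScenarioSpec.standard(s, cfg.pressure_mpa) for s in with_ilt_scen
        ]
        res_map = solve_scenarios(mesh_ilt, specs, cfg.materials)
        for name, res in res_map.items():
            results[name] = res
            postprocess(name, mesh_ilt, res)
    if "no_ilt" in cfg.scenarios:
        mesh_wall = run_mesh(False)
        res = solve_scenario(
            mesh_wall, ScenarioSpec.standard("no_ilt", cfg.pressure_mpa), cfg.materials
        )
        results["no_ilt"] = res
        postprocess("no_ilt", mesh_wall, res)

    report["comparison"] = compare_scenarios(peaks) if peaks else {}
    report["peak_rpi"] = peak_rpis
    with open(out / "summary.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _config_echo(cfg: RunConfig) -> dict:
    echo = {
        "pressure_mpa": cfg.pressure_mpa,
        "scenarios": cfg.scenarios,
        "n_layers": cfg.n_layers,
        "min_ilt_thickness_mm": cfg.min_ilt_thickness_mm,
        "element_order": cfg.element_order,
        "target_edge_mm": cfg.target_edge_mm,
        "exclusion_distance_mm": cfg.exclusion_distance_mm,
        "wall_thickness_mm": cfg.wall_thickness_mm,
        "patient": {"sex": cfg.patient.sex, "family_history": cfg.patient.family_history},
        "strength_model": asdict(cfg.strength_model),
        "materials": {
            r: {"youngs_modulus_mpa": m.youngs_modulus, "poisson_ratio": m.poisson_ratio}
            for r, m in cfg.materials.items()
        },
        "seed": cfg.seed,
        "applied_defaults": cfg.applied_defaults,
    }
    if cfg.phantom is not None:
        echo["phantom"] = asdict(cfg.phantom)
    return echo
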