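"""Scenario configuration: schema, strict validation, unit normalization.

Configs are written in human-scale units (nm, mm, um, ml/h, hours) in YAML
and converted once, at load time, to SI; everything downstream computes in
meters / seconds / Pascals.  Unknown keys are rejected so a typo cannot
silently fall back to a physics default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .geometry import GeometryConfig
from .pore_theory import VesselWallParameters
from .transport import HOUR, InfusionSchedule

__all__ = ["ScenarioConfig", "load_config", "ml_per_h_to_si"]

ML_PER_H = 1.0e-6 / 3600.0


def ml_per_h_to_si(value: float) -> float:
    """Convert a flow rate in ml/h to m^3/s."""
    return value * ML_PER_H


PLACEMENTS = ("inside", "outside_1mm")


@dataclass(frozen=True)
class ScenarioConfig:
    """Fully validated scenario description (SI units internally)."""

    drug_diameter: float = 1.0e-9
    pore_diameter: float = 100.0e-9
    healthy_pore_diameter: float = 20.0e-9
    tumor_k: float = 2.0e-13
    catheter_placement: str = "inside"
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    schedule: InfusionSchedule = field(default_factory=InfusionSchedule)
    wall: VesselWallParameters = field(default_factory=VesselWallParameters)
    tortuosity: float = 1.6
    hindrance_correlation: str = "bungay-brenner"
    tumor_overrides: dict = field(default_factory=dict)
    healthy_overrides: dict = field(default_factory=dict)
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if min(self.drug_diameter, self.pore_diameter, self.healthy_pore_diameter, self.tumor_k) <= 0:
            raise ValueError("diameters and tumor_k must be positive")
        if self.catheter_placement not in PLACEMENTS:
            raise ValueError(f"catheter_placement must be one of {PLACEMENTS}")

    @property
    def tip_offset(self) -> float:
        if self.catheter_placement == "outside_1mm":
            return self.geometry.tumor_radius + 1.0e-3
        return self.geometry.catheter_tip_offset

    def to_manifest(self) -> dict[str, Any]:
        g, s, w = self.geometry, self.schedule, self.wall
        return {
            "drug_diameter_m": self.drug_diameter,
            "pore_diameter_m": self.pore_diameter,
            "healthy_pore_diameter_m": self.healthy_pore_diameter,
            "tumor_k": self.tumor_k,
            "catheter_placement": self.catheter_placement,
            "catheter_tip_offset_m": self.tip_offset,
            "tumor_radius_m": g.tumor_radius,
            "catheter_radius_m": g.catheter_radius,
            "outer_radius_m": g.outer_radius,
            "mesh_size_tumor_m": g.mesh_size_tumor,
            "mesh_size_far_m": g.mesh_size_far,
            "mode": g.mode,
            "Q_f_m3_s": s.Q_f,
            "infusion_duration_s": s.infusion_duration,
            "total_time_s": s.total_time,
            "dt_infusion_s": s.dt_infusion,
            "dt_post_s": s.dt_post,
            "C_inlet": s.C_inlet,
            "gamma": w.gamma,
            "wall_thickness_m": w.wall_thickness,
            "plasma_viscosity_Pa_s": w.plasma_viscosity,
            "temperature_K": w.temperature,
            "tortuosity": self.tortuosity,
            "hindrance_correlation": self.hindrance_correlation,
            "tumor_overrides": dict(self.tumor_overrides),
            "healthy_overrides": dict(self.healthy_overrides),
            "seed": self.seed,
            "output_dir": self.output_dir,
        }


_TOP_KEYS = {
    "drug_diameter_nm",
    "pore_diameter_nm",
    "healthy_pore_diameter_nm",
    "tumor_k",
    "catheter_placement",
    "flow_rate_ml_h",
    "infusion_duration_h",
    "total_time_h",
    "dt_infusion_s",
    "dt_post_s",
    "c_inlet",
    "snapshot_times_h",
    "tortuosity",
    "hindrance_correlation",
    "geometry",
    "vessel_wall",
    "tumor_properties",
    "healthy_properties",
    "seed",
    "output_dir",
}
_GEOM_KEYS = {
    "tumor_radius_mm",
    "catheter_radius_mm",
    "outer_radius_mm",
    "catheter_tip_offset_mm",
    "mesh_size_tumor_mm",
    "mesh_size_far_mm",
    "mode",
}
_WALL_KEYS = {"gamma", "wall_thickness_um", "plasma_viscosity", "temperature_k"}
_PROP_KEYS = {"k", "epsilon_p", "mu_i", "rho", "Lp_Sv", "p_v", "Lpl_Svl", "p_l", "S_v", "k_d", "k_l"}


def _check_keys(d: dict, allowed: set[str], where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown config key(s) in {where}: {sorted(unknown)}")


def _positive(name: str, value: float) -> float:
    value = float(value)
    if value <= 0:
        raise ValueError(f"config key {name} must be positive, got {value}")
    return value


def from_dict(raw: dict[str, Any]) -> ScenarioConfig:
    """Build a validated ScenarioConfig from a plain (human-units) mapping."""
    raw = dict(raw or {})
    _check_keys(raw, _TOP_KEYS, "scenario")

    geom_raw = dict(raw.get("geometry") or {})
    _check_keys(geom_raw, _GEOM_KEYS, "geometry")
    geom_kwargs: dict[str, Any] = {}
    for key, target in [
        ("tumor_radius_mm", "tumor_radius"),
        ("catheter_radius_mm", "catheter_radius"),
        ("outer_radius_mm", "outer_radius"),
        ("mesh_size_tumor_mm", "mesh_size_tumor"),
        ("mesh_size_far_mm", "mesh_size_far"),
    ]:
        if key in geom_raw:
            geom_kwargs[target] = _positive(key, geom_raw[key]) * 1.0e-3
    if "catheter_tip_offset_mm" in geom_raw:
        geom_kwargs["catheter_tip_offset"] = float(geom_raw["catheter_tip_offset_mm"]) * 1.0e-3
    if "mode" in geom_raw:
        geom_kwargs["mode"] = str(geom_raw["mode"])
    geometry = GeometryConfig(**geom_kwargs)

    wall_raw = dict(raw.get("vessel_wall") or {})
    _check_keys(wall_raw, _WALL_KEYS, "vessel_wall")
    wall_kwargs: dict[str, Any] = {}
    if "gamma" in wall_raw:
        wall_kwargs["gamma"] = _positive("gamma", wall_raw["gamma"])
    if "wall_thickness_um" in wall_raw:
        wall_kwargs["wall_thickness"] = _positive("wall_thickness_um", wall_raw["wall_thickness_um"]) * 1.0e-6
    if "plasma_viscosity" in wall_raw:
        wall_kwargs["plasma_viscosity"] = _positive("plasma_viscosity", wall_raw["plasma_viscosity"])
    if "temperature_k" in wall_raw:
        wall_kwargs["temperature"] = _positive("temperature_k", wall_raw["temperature_k"])
    wall = VesselWallParameters(**wall_kwargs)

    sched_kwargs: dict[str, Any] = {}
    if "flow_rate_ml_h" in raw:
        q = float(raw["flow_rate_ml_h"])
        if q < 0:
            raise ValueError("flow_rate_ml_h must be non-negative")
        sched_kwargs["Q_f"] = ml_per_h_to_si(q)
    if "infusion_duration_h" in raw:
        sched_kwargs["infusion_duration"] = _positive("infusion_duration_h", raw["infusion_duration_h"]) * HOUR
    if "total_time_h" in raw:
        sched_kwargs["total_time"] = _positive("total_time_h", raw["total_time_h"]) * HOUR
    if "dt_infusion_s" in raw:
        sched_kwargs["dt_infusion"] = _positive("dt_infusion_s", raw["dt_infusion_s"])
    if "dt_post_s" in raw:
        sched_kwargs["dt_post"] = _positive("dt_post_s", raw["dt_post_s"])
    if "c_inlet" in raw:
        sched_kwargs["C_inlet"] = float(raw["c_inlet"])
    if "snapshot_times_h" in raw:
        sched_kwargs["snapshot_times"] = tuple(float(h) * HOUR for h in raw["snapshot_times_h"])
    schedule = InfusionSchedule(**sched_kwargs)

    for section in ("tumor_properties", "healthy_properties"):
        _check_keys(dict(raw.get(section) or {}), _PROP_KEYS, section)

    kwargs: dict[str, Any] = {
        "geometry": geometry,
        "schedule": schedule,
        "wall": wall,
        "tumor_overrides": dict(raw.get("tumor_properties") or {}),
        "healthy_overrides": dict(raw.get("healthy_properties") or {}),
    }
    if "drug_diameter_nm" in raw:
        kwargs["drug_diameter"] = _positive("drug_diameter_nm", raw["drug_diameter_nm"]) * 1.0e-9
    if "pore_diameter_nm" in raw:
        kwargs["pore_diameter"] = _positive("pore_diameter_nm", raw["pore_diameter_nm"]) * 1.0e-9
    if "healthy_pore_diameter_nm" in raw:
        kwargs["healthy_pore_diameter"] = _positive("healthy_pore_diameter_nm", raw["healthy_pore_diameter_nm"]) * 1.0e-9
    if "tumor_k" in raw:
        kwargs["tumor_k"] = _positive("tumor_k", raw["tumor_k"])
    if "catheter_placement" in raw:
        kwargs["catheter_placement"] = str(raw["catheter_placement"])
    if "tortuosity" in raw:
        kwargs["tortuosity"] = float(raw["tortuosity"])
    if "hindrance_correlation" in raw:
        kwargs["hindrance_correlation"] = str(raw["hindrance_correlation"])
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    if "output_dir" in raw:
        kwargs["output_dir"] = str(raw["output_dir"])
    return ScenarioConfig(**kwargs)


def load_config(path: str | Path) -> ScenarioConfig:
    """Load and validate a YAML scenario configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level of a scenario config must be a mapping")
    return from_dict(raw)
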