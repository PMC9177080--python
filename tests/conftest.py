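"""Shared fixtures: coarse meshes for unit tests and a session-scoped
cache of full-resolution study scenarios used by the acceptance tests."""

from __future__ import annotations

from dataclasses import replace as dc_replace

import pytest

from cedsim import GeometryConfig, InfusionSchedule, ScenarioConfig, build_domain
from cedsim.scenarios import ScenarioResult, run_scenario

HOUR = 3600.0


@pytest.fixture(scope="session")
def coarse_geometry() -> GeometryConfig:
    return GeometryConfig(mesh_size_tumor=0.5e-3, mesh_size_far=3.0e-3)


@pytest.fixture(scope="session")
def coarse_mesh(coarse_geometry):
    return build_domain(coarse_geometry)


@pytest.fixture(scope="session")
def quick_schedule() -> InfusionSchedule:
    """One-hour infusion, two-hour horizon; keeps transport unit tests fast."""
    return InfusionSchedule(
        infusion_duration=1.0 * HOUR,
        total_time=2.0 * HOUR,
        dt_infusion=60.0,
        dt_post=120.0,
        snapshot_times=(0.0, 0.5 * HOUR, 1.0 * HOUR, 1.5 * HOUR, 2.0 * HOUR),
    )


@pytest.fixture(scope="session")
def quick_config(coarse_geometry, quick_schedule) -> ScenarioConfig:
    return ScenarioConfig(geometry=coarse_geometry, schedule=quick_schedule)


class StudyCache:
    """Runs full-resolution study scenarios once and memoizes the results."""

    def __init__(self) -> None:
        self._cache: dict[tuple, ScenarioResult] = {}

    def get(
        self,
        drug_nm: float = 1.0,
        pore_nm: float = 100.0,
        tumor_k: float = 2.0e-13,
        placement: str = "inside",
    ) -> ScenarioResult:
        key = (drug_nm, pore_nm, tumor_k, placement)
        if key not in self._cache:
            cfg = ScenarioConfig(
                drug_diameter=drug_nm * 1e-9,
                pore_diameter=pore_nm * 1e-9,
                tumor_k=tumor_k,
                catheter_placement=placement,
            )
            self._cache[key] = run_scenario(cfg)
        return self._cache[key]


@pytest.fixture(scope="session")
def study() -> StudyCache:
    return StudyCache()
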