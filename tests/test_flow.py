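"""Interstitial flow solver: oracle match, conservation, parameter response."""

import numpy as np
import pytest

from cedsim import (
    GeometryConfig,
    RegionProperties,
    analytic_radial_ifp,
    build_domain,
    default_region_properties,
    inlet_velocity,
    solve_flow,
    starling_source,
)
from cedsim.geometry import REGION_HEALTHY

ML_H = 1.0e-6 / 3600.0


def leaky_sphere_props(k=2e-13, alpha=2.0, R=6e-3, p_v=3330.0):
    """Leaky tumor in a non-leaky, highly conductive surrounding, so the
    analytic zero-edge-pressure radial profile applies inside the tumor."""
    LpSv = k * (alpha / R) ** 2
    return {
        "tumor": RegionProperties(k=k, epsilon_p=0.3, Lp_Sv=LpSv, p_v=p_v, S_v=2e4),
        "healthy": RegionProperties(k=k * 1e3, epsilon_p=0.2, Lp_Sv=0.0, p_v=0.0, S_v=7e3),
    }


def oracle_error(mesh_size, alpha=2.0):
    k, R, p_v = 2e-13, 6e-3, 3330.0
    props = leaky_sphere_props(k=k, alpha=alpha)
    # tip parked far outside the tumor so the cavity does not perturb it
    cfg = GeometryConfig(catheter_tip_offset=20e-3, mesh_size_tumor=mesh_size)
    mesh = build_domain(cfg)
    ff = solve_flow(mesh, props, infusion_on=False)
    r = np.hypot(mesh.points[:, 0], mesh.points[:, 1])
    inside = r < R * 0.999
    exact = analytic_radial_ifp(r[inside], R, k, props["tumor"].Lp_Sv, p_v)
    return np.linalg.norm(ff.p[inside] - exact) / np.linalg.norm(exact)


class TestAnalyticOracle:
    def test_center_value_alpha_one(self):
        # p(0) = p_v (1 - alpha / sinh(alpha))
        assert analytic_radial_ifp(0.0, 6e-3, 2e-13, 2e-13 / 36e-6, 1.0) == pytest.approx(
            1.0 - 1.0 / np.sinh(1.0), rel=1e-9
        )

    def test_small_r_limit_continuous(self):
        p0 = analytic_radial_ifp(0.0, 6e-3, 2e-13, 5e-8, 3330.0)
        p_eps = analytic_radial_ifp(1e-7, 6e-3, 2e-13, 5e-8, 3330.0)
        assert p0 == pytest.approx(p_eps, rel=1e-4)

    def test_large_alpha_plateaus_at_vascular_pressure(self):
        # alpha -> inf: interior pressure approaches p_v
        p = analytic_radial_ifp(1e-3, 6e-3, 2e-16, 1e-6, 3330.0)
        assert p == pytest.approx(3330.0, rel=1e-6)

    def test_coarse_fe_solution_tracks_oracle(self):
        assert oracle_error(0.5e-3) < 0.05


class TestSolveFlow:
    def test_no_sources_no_infusion_gives_zero_field(self, coarse_mesh):
        props = {
            "tumor": RegionProperties(k=2e-13, epsilon_p=0.3, Lp_Sv=0.0, p_v=0.0, S_v=2e4),
            "healthy": RegionProperties(k=2e-12, epsilon_p=0.2, Lp_Sv=0.0, p_v=0.0, S_v=7e3),
        }
        ff = solve_flow(coarse_mesh, props, infusion_on=False)
        assert np.allclose(ff.p, 0.0, atol=1e-10)
        assert np.allclose(ff.u, 0.0, atol=1e-20)

    def test_fluid_balance_closes_with_infusion(self, coarse_mesh):
        props = default_region_properties()
        U0 = inlet_velocity(0.5 * ML_H, 1.5e-3)
        ff = solve_flow(coarse_mesh, props, infusion_on=True, U_0=U0)
        assert abs(ff.balance["residual"]) < 0.005 * ff.balance["inflow"]

    def test_pressure_bounded_by_vascular_without_infusion(self, coarse_mesh):
        # uniform properties, no infusion: p_i cannot exceed p_v anywhere
        same = RegionProperties(k=2e-13, epsilon_p=0.3, Lp_Sv=1e-7, p_v=3000.0, S_v=2e4)
        ff = solve_flow(coarse_mesh, {"tumor": same, "healthy": same}, infusion_on=False)
        assert ff.p.max() <= 3000.0 * (1 + 1e-9)
        assert ff.p.min() >= -1e-9

    def test_lower_tumor_k_raises_center_ifp_and_lowers_speed(self, coarse_mesh):
        center = np.argmin(np.hypot(coarse_mesh.points[:, 0], coarse_mesh.points[:, 1]))
        tumor_cells = coarse_mesh.region == 1
        p_c, u_med = [], []
        for k in (2e-12, 2e-13, 2e-14):
            ff = solve_flow(coarse_mesh, default_region_properties(tumor_k=k), infusion_on=False)
            p_c.append(ff.p[center])
            u_med.append(np.median(ff.speed[tumor_cells]))
        assert p_c[0] < p_c[1] < p_c[2]
        assert u_med[0] > u_med[1] > u_med[2]

    def test_wider_pores_raise_interior_plateau(self, coarse_mesh):
        from cedsim.pore_theory import VesselWallParameters, wall_hydraulic_conductivity

        center = np.argmin(np.hypot(coarse_mesh.points[:, 0], coarse_mesh.points[:, 1]))
        wall = VesselWallParameters()
        p_c = []
        for pore in (50e-9, 100e-9, 150e-9):
            Lp = wall_hydraulic_conductivity(wall, pore / 2)
            ff = solve_flow(coarse_mesh, default_region_properties(tumor_Lp=Lp), infusion_on=False)
            p_c.append(ff.p[center])
        assert p_c[0] < p_c[1] < p_c[2]

    def test_healthy_interstitial_speed_in_reported_band(self, coarse_mesh):
        # brain-tissue interstitial velocities are 1e-7..1e-6 m/s
        U0 = inlet_velocity(0.5 * ML_H, 1.5e-3)
        ff = solve_flow(coarse_mesh, default_region_properties(), infusion_on=True, U_0=U0)
        cen = coarse_mesh.points[coarse_mesh.cells].mean(axis=1)
        r = np.hypot(cen[:, 0], cen[:, 1])
        shell = (coarse_mesh.region == REGION_HEALTHY) & (r > 7.2e-3) & (r < 12e-3)
        med = np.median(ff.speed[shell])
        assert 1e-7 < med < 1.5e-6

    def test_negative_inlet_velocity_rejected(self, coarse_mesh):
        with pytest.raises(ValueError):
            solve_flow(coarse_mesh, default_region_properties(), infusion_on=True, U_0=-1.0)


class TestStarlingSource:
    def test_equilibrium_gives_zero(self, coarse_mesh):
        props = {
            "tumor": RegionProperties(k=2e-13, epsilon_p=0.3, Lp_Sv=1e-7, p_v=2000.0, S_v=2e4),
            "healthy": RegionProperties(k=2e-12, epsilon_p=0.2, Lp_Sv=1e-8, p_v=2000.0, S_v=7e3,
                                        Lpl_Svl=1e-8, p_l=2000.0),
        }
        p_cell = np.full(len(coarse_mesh.cells), 2000.0)
        assert np.allclose(starling_source(p_cell, coarse_mesh, props), 0.0)

    def test_direct_evaluation_in_tumor(self, coarse_mesh):
        props = {
            "tumor": RegionProperties(k=2e-13, epsilon_p=0.3, Lp_Sv=1e-7, p_v=3330.0, S_v=2e4),
            "healthy": RegionProperties(k=2e-12, epsilon_p=0.2, Lp_Sv=0.0, p_v=0.0, S_v=7e3),
        }
        q = starling_source(np.zeros(len(coarse_mesh.cells)), coarse_mesh, props)
        interior = coarse_mesh.tumor_fraction == 1.0
        assert np.allclose(q[interior], 1e-7 * 3330.0)
        assert q[interior][0] == pytest.approx(3.33e-4)

    def test_drainage_sign_when_pressure_exceeds_sources(self, coarse_mesh):
        props = {
            "tumor": RegionProperties(k=2e-13, epsilon_p=0.3, Lp_Sv=1e-7, p_v=3330.0, S_v=2e4),
            "healthy": RegionProperties(k=2e-12, epsilon_p=0.2, Lp_Sv=1e-8, p_v=2080.0, S_v=7e3,
                                        Lpl_Svl=1e-8, p_l=0.0),
        }
        q = starling_source(np.full(len(coarse_mesh.cells), 5000.0), coarse_mesh, props)
        assert np.all(q < 0.0)


class TestInletVelocity:
    def test_matches_flow_rate_over_area(self):
        # 0.5 ml/h through a 1.5 mm radius catheter
        assert inlet_velocity(0.5 * ML_H, 1.5e-3) == pytest.approx(1.96e-5, rel=5e-3)

    def test_zero_rate_and_area_scaling(self):
        assert inlet_velocity(0.0, 1.5e-3) == 0.0
        assert inlet_velocity(1.0 * ML_H, 3e-3) == pytest.approx(inlet_velocity(1.0 * ML_H, 1.5e-3) / 4)


class TestFull3DFlow:
    def test_coarse_3d_matches_axisymmetric_on_axis(self):
        props = leaky_sphere_props(alpha=2.0)
        axi = build_domain(GeometryConfig(catheter_tip_offset=20e-3, mesh_size_tumor=0.5e-3))
        ff2 = solve_flow(axi, props, infusion_on=False)
        m3 = build_domain(
            GeometryConfig(catheter_tip_offset=20e-3, mode="full_3d", mesh_size_tumor=1.0e-3, mesh_size_far=8e-3)
        )
        ff3 = solve_flow(m3, props, infusion_on=False)
        # compare pressures at matched points along the catheter axis
        zs = np.linspace(-4e-3, 4e-3, 9)
        for z in zs:
            i2 = np.argmin((axi.points[:, 0]) ** 2 + (axi.points[:, 1] - z) ** 2)
            i3 = np.argmin((m3.points[:, 0]) ** 2 + (m3.points[:, 1]) ** 2 + (m3.points[:, 2] - z) ** 2)
            assert ff3.p[i3] == pytest.approx(ff2.p[i2], rel=0.10, abs=30.0)
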