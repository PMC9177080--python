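"""Hindered pore-transport coefficients: formulas, limits, monotonicity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cedsim.pore_theory import (
    BOLTZMANN,
    PoreDrugGeometry,
    VesselWallParameters,
    convective_hindrance,
    free_diffusivity,
    hindrance_factor,
    reflection_coefficient,
    tissue_diffusivity,
    transport_coefficients,
    wall_hydraulic_conductivity,
    wall_permeability,
)

CORRELATIONS = ("bungay-brenner", "renkin")


class TestFreeDiffusivity:
    def test_stokes_einstein_value(self):
        # K_b T / (6 pi mu r_s) for a 0.5 nm radius sphere in plasma at 310 K
        expected = BOLTZMANN * 310.0 / (6.0 * math.pi * 1.0e-3 * 0.5e-9)
        assert free_diffusivity(0.5e-9, 310.0, 1.0e-3) == pytest.approx(expected)
        assert expected == pytest.approx(4.54e-10, rel=1e-3)

    def test_inverse_radius_scaling(self):
        assert free_diffusivity(1.0e-9) == pytest.approx(free_diffusivity(0.5e-9) / 2.0)

    @pytest.mark.parametrize("bad", [dict(r_s=0.0), dict(r_s=1e-9, T=0.0), dict(r_s=1e-9, mu=-1.0)])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            free_diffusivity(**bad)


class TestHindranceFactor:
    @pytest.mark.parametrize("correlation", CORRELATIONS)
    def test_limits(self, correlation):
        assert hindrance_factor(0.0, correlation) == pytest.approx(1.0, abs=1e-4)
        assert hindrance_factor(1e-6, correlation) == pytest.approx(1.0, abs=1e-3)
        assert hindrance_factor(1.0, correlation) == 0.0
        assert hindrance_factor(1.0 - 1e-6, correlation) == pytest.approx(0.0, abs=1e-3)
        assert hindrance_factor(1.7, correlation) == 0.0

    def test_renkin_polynomial_value(self):
        # direct evaluation of the centerline polynomial at lambda = 0.2
        lam = 0.2
        expected = (1 - lam) ** 2 * (1 - 2.1044 * lam + 2.089 * lam**3 - 0.948 * lam**5)
        assert hindrance_factor(lam, "renkin") == pytest.approx(expected)
        assert expected == pytest.approx(0.381, abs=2e-3)

    @pytest.mark.parametrize("correlation", CORRELATIONS)
    def test_monotone_decreasing_1000_grid(self, correlation):
        lam = np.linspace(1e-4, 1 - 1e-4, 1000)
        H = np.array([hindrance_factor(x, correlation) for x in lam])
        assert np.all(np.diff(H) < 0)
        assert np.all((H >= 0) & (H <= 1))

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            hindrance_factor(-0.1)


class TestReflectionCoefficient:
    @pytest.mark.parametrize("correlation", CORRELATIONS)
    def test_limits(self, correlation):
        assert reflection_coefficient(0.0, correlation) == pytest.approx(0.0, abs=1e-4)
        assert reflection_coefficient(1.0, correlation) == 1.0
        assert reflection_coefficient(1e-6, correlation) == pytest.approx(0.0, abs=1e-3)
        assert reflection_coefficient(1.0 - 1e-6, correlation) == pytest.approx(1.0, abs=1e-3)

    def test_equals_one_minus_convective_hindrance(self):
        # independent tabulation of the Bungay-Brenner correlation at 0.5
        lam = 0.5
        one = 1.0 - lam
        pref = 2.25 * math.pi**2 * math.sqrt(2.0) * one ** (-2.5)
        Kt = pref * (1 - (73 / 60) * one + (77293 / 50400) * one**2)
        Kt += -22.5083 - 5.6117 * lam - 0.3363 * lam**2 - 1.216 * lam**3 + 1.647 * lam**4
        Ks = pref * (1 + (7 / 60) * one - (2227 / 50400) * one**2)
        Ks += 4.0180 - 3.9788 * lam - 1.9215 * lam**2 + 4.392 * lam**3 + 5.006 * lam**4
        phi = one**2
        W = phi * (2 - phi) * Ks / (2 * Kt)
        assert reflection_coefficient(lam) == pytest.approx(1.0 - W, rel=1e-12)
        assert convective_hindrance(lam) == pytest.approx(W, rel=1e-12)

    @pytest.mark.parametrize("correlation", CORRELATIONS)
    def test_monotone_increasing_1000_grid(self, correlation):
        lam = np.linspace(1e-4, 1 - 1e-4, 1000)
        s = np.array([reflection_coefficient(x, correlation) for x in lam])
        assert np.all(np.diff(s) > 0)
        assert np.all((s >= 0) & (s <= 1))


class TestWallCoefficients:
    def test_hydraulic_conductivity_value(self):
        wall = VesselWallParameters(gamma=1e-3, wall_thickness=5e-6, plasma_viscosity=1e-3)
        assert wall_hydraulic_conductivity(wall, 50e-9) == pytest.approx(6.25e-11, rel=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(c=st.floats(0.01, 100.0), r0=st.floats(1e-9, 1e-6))
    def test_quadratic_scaling_exact(self, c, r0):
        wall = VesselWallParameters()
        assert wall_hydraulic_conductivity(wall, c * r0) == pytest.approx(
            c**2 * wall_hydraulic_conductivity(wall, r0), rel=1e-12
        )

    def test_pore_size_ratio_independent_of_wall(self):
        for wall in [VesselWallParameters(), VesselWallParameters(gamma=0.01, wall_thickness=1e-6)]:
            ratio = wall_hydraulic_conductivity(wall, 75e-9) / wall_hydraulic_conductivity(wall, 25e-9)
            assert ratio == pytest.approx(9.0, rel=1e-12)

    def test_permeability_reduction_98_percent(self):
        wall = VesselWallParameters()
        P1 = wall_permeability(wall, PoreDrugGeometry(0.5e-9, 50e-9))
        P20 = wall_permeability(wall, PoreDrugGeometry(10e-9, 50e-9))
        assert 100.0 * (1.0 - P20 / P1) == pytest.approx(98.0, abs=1.0)

    def test_exclusion_gives_zero_permeability(self):
        wall = VesselWallParameters()
        assert wall_permeability(wall, PoreDrugGeometry(30e-9, 25e-9)) == 0.0

    def test_permeability_monotone_in_pore_diameter(self):
        wall = VesselWallParameters()
        P = [wall_permeability(wall, PoreDrugGeometry(10e-9, d / 2)) for d in (50e-9, 100e-9, 150e-9)]
        assert P[0] < P[1] < P[2]


class TestTissueDiffusivity:
    def test_identity_and_tortuosity(self):
        assert tissue_diffusivity(1e-10, 1.0) == 1e-10
        assert tissue_diffusivity(1e-10, 1.6) == pytest.approx(1e-10 / 2.56)

    def test_tortuosity_below_one_rejected(self):
        with pytest.raises(ValueError):
            tissue_diffusivity(1e-10, 0.9)


class TestTransportCoefficients:
    def test_bundle_consistency_small_drug(self):
        c = transport_coefficients(1e-9, 100e-9)
        assert c.lam == pytest.approx(0.01)
        assert c.H == pytest.approx(0.96, abs=0.03)
        assert c.sigma_f == pytest.approx(0.0, abs=1e-3)
        assert c.D_tissue == pytest.approx(c.D_free / 1.6**2)
        assert c.D_tissue <= c.D_free

    def test_total_exclusion(self):
        c = transport_coefficients(60e-9, 50e-9)
        assert c.lam == pytest.approx(1.2)
        assert c.P == 0.0
        assert c.sigma_f == 1.0

    def test_lambda_exact_ratio(self):
        assert transport_coefficients(20e-9, 100e-9).lam == pytest.approx(0.2, rel=1e-12)

    def test_unit_round_trip(self):
        # nm-scale inputs converted to SI give the same coefficients
        a = transport_coefficients(20e-9, 100e-9)
        b = transport_coefficients(20 * 1e-9, 100 * 1e-9)
        for field in ("lam", "H", "sigma_f", "D_free", "D_tissue", "L_p", "P"):
            assert getattr(a, field) == pytest.approx(getattr(b, field), rel=1e-9)

    def test_invalid_diameters(self):
        with pytest.raises(ValueError):
            transport_coefficients(-1e-9, 100e-9)
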