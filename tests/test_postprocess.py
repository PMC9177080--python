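"""Reported metrics: averages, threshold fractions, heterogeneity, exports."""

import json
import math

import numpy as np
import pandas as pd
import pytest

from cedsim import (
    ConcentrationSeries,
    average_tumor_concentration,
    directional_profiles,
    export_results,
    region_volume,
    volume_fraction_above,
)
from cedsim.postprocess import ScalarTimeSeries, _triangle_fraction_above
from cedsim.vtkio import read_vtu, write_vtu

HOUR = 3600.0


def series_from_field(mesh, field):
    return ConcentrationSeries(times=np.array([0.0]), fields=field[None, :])


class TestAverageTumorConcentration:
    def test_constant_field_average_is_constant(self, coarse_mesh):
        s = series_from_field(coarse_mesh, np.full(coarse_mesh.n_points, 0.37))
        avg = average_tumor_concentration(s, coarse_mesh)
        assert avg.values[0] == pytest.approx(0.37, rel=1e-9)

    def test_linear_field_matches_closed_form(self, coarse_mesh):
        # C = z: sphere integral vanishes, the catheter cavity contributes
        # a closed-form deficit
        cfg = coarse_mesh.config
        R, a, z0 = cfg.tumor_radius, cfg.catheter_radius, cfg.catheter_tip_offset
        z1 = math.sqrt(R**2 - a**2)
        cavity_moment = math.pi * (a**2 * (z1**2 - z0**2) / 2.0 + (R**2 * (R**2 - z1**2) / 2.0 - (R**4 - z1**4) / 4.0))
        V = region_volume(coarse_mesh, "tumor")
        expected = -cavity_moment / V
        s = series_from_field(coarse_mesh, coarse_mesh.points[:, 1].copy())
        avg = average_tumor_concentration(s, coarse_mesh)
        assert avg.values[0] == pytest.approx(expected, rel=0.02)

    def test_strictly_increasing_times_required(self):
        with pytest.raises(ValueError):
            ScalarTimeSeries(np.array([0.0, 0.0]), np.array([1.0, 2.0]))


class TestVolumeFractionAbove:
    def test_trivial_thresholds(self, coarse_mesh):
        s = series_from_field(coarse_mesh, np.full(coarse_mesh.n_points, 0.5))
        assert volume_fraction_above(s, coarse_mesh, 0.0, 0.0) == pytest.approx(1.0)
        assert volume_fraction_above(s, coarse_mesh, 2.0, 0.0) == 0.0

    def test_radial_field_fraction_matches_geometry(self, coarse_mesh):
        # C = 1 - r_sph/R exceeds 0.5 exactly inside radius R/2
        R = coarse_mesh.config.tumor_radius
        r_sph = np.linalg.norm(coarse_mesh.points, axis=1)
        s = series_from_field(coarse_mesh, 1.0 - r_sph / R)
        expected = (4.0 / 3.0) * math.pi * (R / 2) ** 3 / region_volume(coarse_mesh, "tumor")
        assert volume_fraction_above(s, coarse_mesh, 0.5, 0.0) == pytest.approx(expected, rel=0.02)

    def test_non_increasing_in_threshold(self, coarse_mesh):
        rng = np.random.default_rng(7)
        s = series_from_field(coarse_mesh, rng.random(coarse_mesh.n_points))
        fracs = [volume_fraction_above(s, coarse_mesh, thr, 0.0) for thr in np.linspace(0, 1, 11)]
        assert np.all(np.diff(fracs) <= 1e-12)

    def test_exact_linear_cut_on_single_triangle(self):
        # hand-computed area fractions of a linear field on one triangle
        vals = np.array([[0.0, 0.0, 1.0]])
        assert _triangle_fraction_above(vals, 0.5)[0] == pytest.approx(0.25)
        assert _triangle_fraction_above(vals, -0.1)[0] == 1.0
        assert _triangle_fraction_above(vals, 1.1)[0] == 0.0

    def test_missing_snapshot_rejected(self, coarse_mesh):
        s = series_from_field(coarse_mesh, np.zeros(coarse_mesh.n_points))
        with pytest.raises(ValueError):
            volume_fraction_above(s, coarse_mesh, 0.2, 999.0)


class TestDirectionalProfiles:
    def test_symmetric_field_has_zero_standard_error(self, coarse_mesh):
        r_sph = np.linalg.norm(coarse_mesh.points, axis=1)
        s = series_from_field(coarse_mesh, np.exp(-((r_sph / 3e-3) ** 2)))
        prof = directional_profiles(s, coarse_mesh, 0.0)
        # residual SE is pure linear-interpolation noise on the coarse mesh
        assert prof.se.max() == pytest.approx(0.0, abs=5e-3)
        assert prof.r_over_R[0] == 0.0 and prof.r_over_R[-1] == pytest.approx(1.0)

    def test_rays_share_origin_sample(self, coarse_mesh):
        rng = np.random.default_rng(3)
        s = series_from_field(coarse_mesh, rng.random(coarse_mesh.n_points))
        prof = directional_profiles(s, coarse_mesh, 0.0)
        assert prof.se[0] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(prof.samples[:, 0], prof.samples[0, 0])

    def test_standard_error_formula(self, coarse_mesh):
        # SE of {0,0,0,4} is sd/sqrt(4) = 1
        samples = np.array([0.0, 0.0, 0.0, 4.0])
        assert samples.std(ddof=1) / 2.0 == pytest.approx(1.0)
        # the profile statistic uses the same estimator
        C = np.where(coarse_mesh.points[:, 1] > 0, 4.0, 0.0)
        s = series_from_field(coarse_mesh, C)
        prof = directional_profiles(s, coarse_mesh, 0.0, angles_deg=(30.0, 60.0, 120.0, 150.0))
        mid = len(prof.r_over_R) // 2
        expected = prof.samples[:, mid].std(ddof=1) / 2.0
        assert prof.se[mid] == pytest.approx(expected, rel=1e-9)


class TestExportAndVTU:
    def test_vtu_round_trip(self, coarse_mesh, tmp_path):
        rng = np.random.default_rng(0)
        pdata = {"concentration": rng.random(coarse_mesh.n_points)}
        cdata = {"region": coarse_mesh.region.astype(float)}
        path = tmp_path / "snap.vtu"
        write_vtu(path, coarse_mesh, point_data=pdata, cell_data=cdata)
        pts, cells, pd_read, cd_read = read_vtu(path)
        assert pts.shape == (coarse_mesh.n_points, 3)
        assert np.array_equal(cells, coarse_mesh.cells)
        assert np.array_equal(pd_read["concentration"], pdata["concentration"])
        assert np.array_equal(cd_read["region"], cdata["region"])

    def test_export_results_writes_all_artifacts(self, coarse_mesh, tmp_path):
        times = np.array([0.0, HOUR])
        fields = np.zeros((2, coarse_mesh.n_points))
        fields[1] = 0.25
        from cedsim.transport import InfusionSchedule

        series = ConcentrationSeries(times=times, fields=fields, metadata={"schedule": InfusionSchedule()})
        avg = average_tumor_concentration(series, coarse_mesh)
        manifest = {"config": {"drug_diameter_m": 1e-9}, "seed": 0}
        written = export_results(tmp_path, coarse_mesh, series, avg=avg, manifest=manifest)
        assert len(written["vtu"]) == 2
        df = pd.read_csv(written["csv"][0])
        assert list(df.columns) == ["time_s", "avg_conc"]
        assert df["avg_conc"].values == pytest.approx(avg.values)
        loaded = json.loads((tmp_path / "manifest.json").read_text())
        assert set(manifest) <= set(loaded)
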