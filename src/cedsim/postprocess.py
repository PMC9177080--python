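"""Reported metrics: tumor averages, coverage fractions, heterogeneity profiles.

* ``average_tumor_concentration`` -- the volume integral of the relative
  concentration over the tumor region divided by the tumor volume, per
  stored snapshot.
* ``volume_fraction_above`` -- fraction of tumor volume where the
  concentration exceeds a threshold (exact linear cut within each cell).
* ``directional_profiles`` -- concentration sampled along four coplanar
  rays from the tumor center, with the mean and standard error across the
  rays quantifying the heterogeneity of the distribution.
* ``export_results`` -- VTU snapshots, CSV series/profiles and a JSON run
  manifest.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator

from . import geometry as geo
from .fem import P1Basis
from .geometry import Mesh, region_volume
from .transport import ConcentrationSeries

__all__ = [
    "ScalarTimeSeries",
    "DirectionalProfile",
    "average_tumor_concentration",
    "volume_fraction_above",
    "directional_profiles",
    "export_results",
]


@dataclass
class ScalarTimeSeries:
    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    def at_time(self, t: float) -> float:
        i = np.where(np.isclose(self.times, t, rtol=0, atol=0.5))[0]
        if len(i) == 0:
            raise ValueError(f"time {t} not in series")
        return float(self.values[i[0]])


@dataclass
class DirectionalProfile:
    """Per-radius concentration statistics across rays from the tumor center."""

    r_over_R: np.ndarray  # (n_samples,)
    samples: np.ndarray  # (n_rays, n_samples)
    mean: np.ndarray
    se: np.ndarray
    angles_deg: tuple[float, ...]


def _tumor_volume_weights(mesh: Mesh, basis: P1Basis) -> np.ndarray:
    """Nodal weights for integrals over the tumor: cut cells contribute by
    their tumor volume fraction (consistent with region_volume)."""
    scale = 2.0 * np.pi if mesh.dim == 2 else 1.0
    w = np.zeros(mesh.n_points)
    np.add.at(w, mesh.cells, scale * basis.lump * mesh.tumor_fraction[:, None])
    return w


def average_tumor_concentration(series: ConcentrationSeries, mesh: Mesh, basis: P1Basis | None = None) -> ScalarTimeSeries:
    """Tumor-averaged relative concentration for every stored snapshot."""
    basis = basis or P1Basis(mesh)
    if not (mesh.region == geo.REGION_TUMOR).any():
        raise ValueError("mesh has no tumor region")
    w = _tumor_volume_weights(mesh, basis)
    V = region_volume(mesh, "tumor")
    vals = series.fields @ w / V
    return ScalarTimeSeries(series.times, vals, label="tumor_average_concentration")


def _triangle_fraction_above(vals: np.ndarray, thr: float) -> np.ndarray:
    """Exact area fraction of each triangle where the linear field > thr."""
    v = np.sort(vals, axis=1)
    v1, v2, v3 = v[:, 0], v[:, 1], v[:, 2]
    frac = np.zeros(len(v))
    frac[v1 > thr] = 1.0
    mid = (v1 <= thr) & (v3 > thr)
    # upper corner: thr between v2 and v3
    hi = mid & (v2 <= thr)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_hi = (v3 - thr) ** 2 / ((v3 - v1) * (v3 - v2))
        f_lo = 1.0 - (thr - v1) ** 2 / ((v2 - v1) * (v3 - v1))
    frac[hi] = np.nan_to_num(f_hi, nan=0.0, posinf=1.0)[hi]
    lo = mid & (v2 > thr)
    frac[lo] = np.nan_to_num(f_lo, nan=1.0, posinf=1.0)[lo]
    return np.clip(frac, 0.0, 1.0)


def volume_fraction_above(
    series: ConcentrationSeries, mesh: Mesh, threshold: float, t: float
) -> float:
    """Fraction of the tumor volume with C_i > threshold at snapshot ``t``."""
    if not (0.0 <= threshold):
        raise ValueError("threshold must be non-negative")
    if mesh.dim != 2:
        raise NotImplementedError("volume_fraction_above is implemented for axisymmetric meshes")
    C = series.at_time(t)
    in_tumor = mesh.tumor_fraction > 0
    vals = C[mesh.cells[in_tumor]]
    frac = _triangle_fraction_above(vals, threshold)
    vols = mesh.cell_volumes[in_tumor] * mesh.tumor_fraction[in_tumor]
    return float((frac * vols).sum() / vols.sum())


def directional_profiles(
    series: ConcentrationSeries,
    mesh: Mesh,
    t: float,
    angles_deg: tuple[float, ...] = (45.0, 135.0, -45.0, -135.0),
    n_samples: int = 64,
) -> DirectionalProfile:
    """Sample C_i along rays from the tumor center in the sagittal plane.

    Angles are measured from the catheter (+z) axis.  In the axisymmetric
    model a ray at angle theta maps to (r, z) = (|sin theta|, cos theta) s.
    Returns the per-radius mean and standard error (sd / sqrt(n_rays)).
    """
    if mesh.dim != 2:
        raise NotImplementedError("directional_profiles is implemented for axisymmetric meshes")
    C = series.at_time(t)
    R = mesh.config.tumor_radius if mesh.config else 6.0e-3
    interp = LinearNDInterpolator(mesh.points, C)
    nearest = NearestNDInterpolator(mesh.points, C)
    s = np.linspace(0.0, R, n_samples)
    samples = np.empty((len(angles_deg), n_samples))
    for i, ang in enumerate(angles_deg):
        th = np.deg2rad(ang)
        pts = np.column_stack([np.abs(np.sin(th)) * s, np.cos(th) * s])
        vals = interp(pts)
        bad = ~np.isfinite(vals)
        if bad.any():
            warnings.warn("ray samples outside the mesh were clipped to nearest values")
            vals[bad] = nearest(pts[bad])
        samples[i] = vals
    mean = samples.mean(axis=0)
    se = samples.std(axis=0, ddof=1) / np.sqrt(len(angles_deg))
    return DirectionalProfile(s / R, samples, mean, se, tuple(angles_deg))


def export_results(
    out_dir: str | Path,
    mesh: Mesh,
    series: ConcentrationSeries,
    avg: ScalarTimeSeries | None = None,
    profiles: dict[float, DirectionalProfile] | None = None,
    manifest: dict | None = None,
    flow_fields: dict | None = None,
) -> dict[str, list[str]]:
    """Write VTU snapshots, CSV summaries and a JSON manifest to ``out_dir``."""
    from .vtkio import write_vtu

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, list[str]] = {"vtu": [], "csv": [], "json": []}

    for i, t in enumerate(series.times):
        point_data = {"concentration": series.fields[i]}
        cell_data = {"region": mesh.region.astype(float)}
        if flow_fields:
            phase = "infusion" if t <= series.metadata["schedule"].infusion_duration else "post"
            ff = flow_fields.get(phase)
            if ff is not None:
                point_data["pressure"] = ff.p
                cell_data["velocity"] = ff.u
        path = out / f"concentration_{int(round(t))}s.vtu"
        write_vtu(path, mesh, point_data=point_data, cell_data=cell_data)
        written["vtu"].append(str(path))

    if avg is not None:
        df = pd.DataFrame({"time_s": avg.times, "avg_conc": avg.values})
        p = out / "tumor_average_concentration.csv"
        df.to_csv(p, index=False)
        written["csv"].append(str(p))

    if profiles:
        for t, prof in profiles.items():
            cols = {"r_over_R": prof.r_over_R, "mean": prof.mean, "se": prof.se}
            for j in range(prof.samples.shape[0]):
                cols[f"c{j + 1}"] = prof.samples[j]
            p = out / f"directional_profile_{int(round(t))}s.csv"
            pd.DataFrame(cols).to_csv(p, index=False)
            written["csv"].append(str(p))

    if manifest is not None:
        p = out / "manifest.json"
        with open(p, "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        written["json"].append(str(p))
    return written
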