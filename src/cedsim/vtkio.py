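"""Minimal ASCII VTU (VTK XML UnstructuredGrid) writer and reader.

Writes triangle (axisymmetric (r, z) plane embedded at z=0 as (x, y)) and
tetrahedral meshes with point and cell data so fields load in standard
viewers; the reader parses the same ASCII layout back for round-trip
verification and lightweight re-analysis.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .geometry import Mesh

_CELL_TYPE = {2: 5, 3: 10}  # triangle, tetrahedron


def _fmt(arr: np.ndarray) -> str:
    return " ".join(repr(float(x)) for x in np.asarray(arr, dtype=float).ravel())


def write_vtu(
    path: str | Path,
    mesh: Mesh,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
) -> None:
    pts = mesh.points
    if mesh.dim == 2:
        pts = np.column_stack([pts, np.zeros(len(pts))])
    n_pts, n_cells = len(pts), len(mesh.cells)
    nv = mesh.dim + 1

    root = ET.Element("VTKFile", type="UnstructuredGrid", version="0.1", byte_order="LittleEndian")
    grid = ET.SubElement(root, "UnstructuredGrid")
    piece = ET.SubElement(grid, "Piece", NumberOfPoints=str(n_pts), NumberOfCells=str(n_cells))

    xp = ET.SubElement(piece, "Points")
    da = ET.SubElement(xp, "DataArray", type="Float64", NumberOfComponents="3", format="ascii")
    da.text = _fmt(pts)

    xc = ET.SubElement(piece, "Cells")
    conn = ET.SubElement(xc, "DataArray", type="Int64", Name="connectivity", format="ascii")
    conn.text = " ".join(str(int(i)) for i in mesh.cells.ravel())
    offs = ET.SubElement(xc, "DataArray", type="Int64", Name="offsets", format="ascii")
    offs.text = " ".join(str(nv * (i + 1)) for i in range(n_cells))
    types = ET.SubElement(xc, "DataArray", type="UInt8", Name="types", format="ascii")
    types.text = " ".join(str(_CELL_TYPE[mesh.dim]) for _ in range(n_cells))

    for tag, data in (("PointData", point_data), ("CellData", cell_data)):
        sec = ET.SubElement(piece, tag)
        for name, arr in (data or {}).items():
            arr = np.asarray(arr, dtype=float)
            ncomp = 1 if arr.ndim == 1 else arr.shape[1]
            if ncomp == 2:  # pad plane vectors to 3D
                arr = np.column_stack([arr, np.zeros(len(arr))])
                ncomp = 3
            d = ET.SubElement(sec, "DataArray", type="Float64", Name=name, NumberOfComponents=str(ncomp), format="ascii")
            d.text = _fmt(arr)

    ET.ElementTree(root).write(path, xml_declaration=True)


def read_vtu(path: str | Path):
    """Read an ASCII VTU written by :func:`write_vtu`.

    Returns (points, cells, point_data, cell_data); points keep all three
    coordinates as stored in the file.
    """
    piece = ET.parse(path).getroot().find("UnstructuredGrid/Piece")
    if piece is None:
        raise ValueError(f"{path} is not an UnstructuredGrid VTU file")

    def _floats(el):
        return np.array(el.text.split(), dtype=float)

    pts = _floats(piece.find("Points/DataArray")).reshape(-1, 3)
    arrays = {el.get("Name"): el for el in piece.findall("Cells/DataArray")}
    conn = np.array(arrays["connectivity"].text.split(), dtype=np.int64)
    offsets = np.array(arrays["offsets"].text.split(), dtype=np.int64)
    nv = offsets[0]
    cells = conn.reshape(-1, nv)

    def _section(tag):
        out = {}
        sec = piece.find(tag)
        for el in sec.findall("DataArray") if sec is not None else []:
            ncomp = int(el.get("NumberOfComponents", "1"))
            arr = _floats(el)
            out[el.get("Name")] = arr if ncomp == 1 else arr.reshape(-1, ncomp)
        return out

    return pts, cells, _section("PointData"), _section("CellData")
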