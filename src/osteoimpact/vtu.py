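"""Minimal ASCII VTU (VTK XML UnstructuredGrid) writer and reader.

Covers exactly what the snapshot pipeline needs: one unstructured grid of
hex/tet cells, point data and cell data as scalar or 3-vector float arrays,
ASCII encoding.  The reader exists for round-trip verification of written
snapshots; it is not a general VTK parser.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

VTK_HEX = 12
VTK_TET = 10

__all__ = ["write_vtu", "read_vtu"]


def _data_array(name: str, arr: np.ndarray) -> str:
    arr = np.asarray(arr)
    ncomp = 1 if arr.ndim == 1 else arr.shape[1]
    flat = arr.reshape(-1)
    if np.issubdtype(arr.dtype, np.integer) or arr.dtype == bool:
        dtype, fmt = "Int64", "%d"
        flat = flat.astype(np.int64)
    else:
        dtype, fmt = "Float64", "%.12g"
    body = " ".join(fmt % v for v in flat)
    comp = f' NumberOfComponents="{ncomp}"' if ncomp > 1 else ""
    return f'<DataArray type="{dtype}" Name="{name}"{comp} format="ascii">\n{body}\n</DataArray>'


def write_vtu(path, nodes, hexes=None, tets=None, point_data=None, cell_data=None) -> None:
    """Write one unstructured grid with named point/cell arrays (ASCII)."""
    nodes = np.asarray(nodes, dtype=float)
    hexes = np.zeros((0, 8), dtype=np.int64) if hexes is None else np.asarray(hexes, dtype=np.int64)
    tets = np.zeros((0, 4), dtype=np.int64) if tets is None else np.asarray(tets, dtype=np.int64)
    ncell = len(hexes) + len(tets)
    conn = np.concatenate([hexes.ravel(), tets.ravel()])
    offsets = np.concatenate(
        [8 * (np.arange(len(hexes)) + 1), 8 * len(hexes) + 4 * (np.arange(len(tets)) + 1)]
    )
    types = np.concatenate([np.full(len(hexes), VTK_HEX), np.full(len(tets), VTK_TET)])

    parts = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{len(nodes)}" NumberOfCells="{ncell}">',
        "<Points>",
        _data_array("Points", nodes.reshape(-1, 3)),
        "</Points>",
        "<Cells>",
        _data_array("connectivity", conn),
        _data_array("offsets", offsets),
        _data_array("types", types),
        "</Cells>",
    ]
    if point_data:
        parts.append("<PointData>")
        for name, arr in point_data.items():
            parts.append(_data_array(name, arr))
        parts.append("</PointData>")
    if cell_data:
        parts.append("<CellData>")
        for name, arr in cell_data.items():
            parts.append(_data_array(name, arr))
        parts.append("</CellData>")
    parts += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    Path(path).write_text("\n".join(parts))


def _parse_array(elem: ET.Element) -> np.ndarray:
    text = (elem.text or "").split()
    dtype = float if elem.get("type", "").startswith("Float") else np.int64
    arr = np.asarray(text, dtype=dtype)
    ncomp = int(elem.get("NumberOfComponents", "1"))
    return arr.reshape(-1, ncomp) if ncomp > 1 else arr


def read_vtu(path):
    """Read back a file written by :func:`write_vtu`.

    Returns ``(nodes, hexes, tets, point_data, cell_data)``.
    """
    root = ET.parse(str(path)).getroot()
    piece = root.find(".//Piece")
    points = _parse_array(piece.find("Points/DataArray"))
    cells = {e.get("Name"): _parse_array(e) for e in piece.findall("Cells/DataArray")}
    types = cells["types"].astype(int)
    offsets = cells["offsets"].astype(int)
    conn = cells["connectivity"].astype(np.int64)
    hexes, tets = [], []
    start = 0
    for t, off in zip(types, offsets):
        cell = conn[start:off]
        (hexes if t == VTK_HEX else tets).append(cell)
        start = off
    point_data = {e.get("Name"): _parse_array(e) for e in piece.findall("PointData/DataArray")}
    cell_data = {e.get("Name"): _parse_array(e) for e in piece.findall("CellData/DataArray")}
    return (
        np.asarray(points, dtype=float).reshape(-1, 3),
        np.asarray(hexes, dtype=np.int64).reshape(-1, 8) if hexes else np.zeros((0, 8), np.int64),
        np.asarray(tets, dtype=np.int64).reshape(-1, 4) if tets else np.zeros((0, 4), np.int64),
        point_data,
        cell_data,
    )
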