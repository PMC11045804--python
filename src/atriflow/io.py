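"""File-format plumbing: ASCII VTU meshes with point/cell data, JSON
sidecars for tags and phenotype records, case read/write round-trips.

All floating-point values are written with 17 significant digits so a
write/read round-trip is bit-identical for float64.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .cohort import (
    TAG_LEGEND, ChamberGeometry, FrameSet, GeometryParams, PhenotypeParams,
)
from .errors import FormatError

__all__ = [
    "write_vtu", "read_vtu", "write_case", "read_case",
    "write_frameset", "read_frameset",
]

_VTK_TETRA = 10
_VTK_TRIANGLE = 5


def _fmt_floats(arr) -> str:
    return " ".join(np.format_float_scientific(v, precision=16) for v in np.ravel(arr))


def _fmt_ints(arr) -> str:
    return " ".join(str(int(v)) for v in np.ravel(arr))


def write_vtu(path, points, tetra=None, triangles=None, point_data=None, cell_data=None):
    """Write an ASCII VTU unstructured grid (tets first, then triangles)."""
    points = np.asarray(points, dtype=float)
    tetra = np.zeros((0, 4), dtype=int) if tetra is None else np.asarray(tetra)
    triangles = np.zeros((0, 3), dtype=int) if triangles is None else np.asarray(triangles)
    n_cells = len(tetra) + len(triangles)
    conn = np.concatenate([tetra.ravel(), triangles.ravel()])
    offsets = np.concatenate(
        [4 * (np.arange(len(tetra)) + 1), 4 * len(tetra) + 3 * (np.arange(len(triangles)) + 1)]
    )
    types = np.concatenate(
        [np.full(len(tetra), _VTK_TETRA), np.full(len(triangles), _VTK_TRIANGLE)]
    )

    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{len(points)}" NumberOfCells="{n_cells}">',
        "<Points>",
        '<DataArray type="Float64" Name="Points" NumberOfComponents="3" format="ascii">',
        _fmt_floats(points),
        "</DataArray>",
        "</Points>",
        "<Cells>",
        '<DataArray type="Int64" Name="connectivity" format="ascii">',
        _fmt_ints(conn),
        "</DataArray>",
        '<DataArray type="Int64" Name="offsets" format="ascii">',
        _fmt_ints(offsets),
        "</DataArray>",
        '<DataArray type="UInt8" Name="types" format="ascii">',
        _fmt_ints(types),
        "</DataArray>",
        "</Cells>",
    ]
    lines.append("<PointData>")
    for name, arr in (point_data or {}).items():
        arr = np.asarray(arr)
        ncomp = 1 if arr.ndim == 1 else arr.shape[1]
        lines += [
            f'<DataArray type="Float64" Name="{name}" NumberOfComponents="{ncomp}" format="ascii">',
            _fmt_floats(arr),
            "</DataArray>",
        ]
    lines.append("</PointData>")
    lines.append("<CellData>")
    for name, arr in (cell_data or {}).items():
        arr = np.asarray(arr)
        kind = "Int64" if np.issubdtype(arr.dtype, np.integer) else "Float64"
        body = _fmt_ints(arr) if kind == "Int64" else _fmt_floats(arr)
        lines += [
            f'<DataArray type="{kind}" Name="{name}" NumberOfComponents="1" format="ascii">',
            body,
            "</DataArray>",
        ]
    lines.append("</CellData>")
    lines += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    Path(path).write_text("\n".join(lines))


def read_vtu(path):
    """Read an ASCII VTU file written by :func:`write_vtu` (or compatible).

    Returns ``(points, tetra, triangles, point_data, cell_data)``.
    """
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise FormatError(f"{path}: not a valid VTU/XML file ({exc})") from None
    piece = tree.getroot().find(".//Piece")
    if piece is None:
        raise FormatError(f"{path}: no <Piece> element")

    def arr_of(parent, name, dtype=float):
        for da in parent.iter("DataArray"):
            if da.get("Name") == name:
                text = da.text or ""
                return np.fromstring(text, sep=" ", dtype=dtype)
        raise FormatError(f"{path}: missing DataArray '{name}'")

    pts = arr_of(piece.find("Points"), "Points").reshape(-1, 3)
    cells = piece.find("Cells")
    conn = arr_of(cells, "connectivity", dtype=int)
    types = arr_of(cells, "types", dtype=int)
    offsets = arr_of(cells, "offsets", dtype=int)
    starts = np.concatenate([[0], offsets[:-1]])
    tets, tris = [], []
    for s, e, ty in zip(starts, offsets, types):
        if ty == _VTK_TETRA:
            tets.append(conn[s:e])
        elif ty == _VTK_TRIANGLE:
            tris.append(conn[s:e])
        else:
            raise FormatError(f"{path}: unsupported VTK cell type {ty}")
    tetra = np.array(tets, dtype=int).reshape(-1, 4) if tets else np.zeros((0, 4), int)
    triangles = np.array(tris, dtype=int).reshape(-1, 3) if tris else np.zeros((0, 3), int)

    point_data = {}
    pd = piece.find("PointData")
    if pd is not None:
        for da in pd.iter("DataArray"):
            ncomp = int(da.get("NumberOfComponents", "1"))
            a = np.fromstring(da.text or "", sep=" ")
            point_data[da.get("Name")] = a.reshape(-1, ncomp) if ncomp > 1 else a
    cell_data = {}
    cd = piece.find("CellData")
    if cd is not None:
        for da in cd.iter("DataArray"):
            dtype = int if da.get("type") == "Int64" else float
            cell_data[da.get("Name")] = np.fromstring(da.text or "", sep=" ", dtype=dtype)
    return pts, tetra, triangles, point_data, cell_data


# ----------------------------------------------------------------------
# case artifacts
# ----------------------------------------------------------------------

def write_case(case_dir, geom: ChamberGeometry, frames: FrameSet | None = None,
               phenotype: PhenotypeParams | None = None):
    """Persist a case: mesh + tags VTU, per-frame displacement VTUs, sidecar."""
    case_dir = Path(case_dir)
    case_dir.mkdir(parents=True, exist_ok=True)
    n_tet = len(geom.tetrahedra)
    cell_tags = np.concatenate([np.full(n_tet, -1, dtype=int), geom.facet_tags])
    write_vtu(
        case_dir / "mesh.vtu", geom.vertices, tetra=geom.tetrahedra,
        triangles=geom.boundary_facets, cell_data={"region_tag": cell_tags},
    )
    sidecar = {
        "tags_legend": {str(k): v for k, v in TAG_LEGEND.items()},
        "laa_wall_vertices": geom.laa_wall_vertices.tolist(),
        "laa_cells": geom.laa_cells.tolist(),
        "ostium_ring": geom.ostium_ring.tolist(),
    }
    if phenotype is not None:
        sidecar["phenotype"] = asdict(phenotype)
    if frames is not None:
        sidecar["frames"] = {
            "period": frames.period,
            "frame_times": [float(t) for t in frames.frame_times],
            "wall_vertex_ids": frames.wall_vertex_ids.tolist(),
            "n_frames": int(len(frames.frame_times)),
        }
        for i in range(len(frames.frame_times)):
            d = frames.full_displacement(i, len(geom.vertices))
            write_vtu(
                case_dir / f"frame_{i:03d}.vtu", geom.vertices,
                tetra=geom.tetrahedra, point_data={"displacement": d},
            )
    (case_dir / "case.json").write_text(json.dumps(sidecar, indent=1))


def read_case(case_dir):
    """Load a case directory; returns ``(geom, frames_or_None, phenotype_or_None)``."""
    case_dir = Path(case_dir)
    mesh_path = case_dir / "mesh.vtu"
    side_path = case_dir / "case.json"
    if not mesh_path.exists():
        raise FormatError(f"{mesh_path}: missing mesh file")
    if not side_path.exists():
        raise FormatError(f"{side_path}: missing sidecar (tags legend)")
    pts, tets, tris, _, cell_data = read_vtu(mesh_path)
    if "region_tag" not in cell_data:
        raise FormatError(f"{mesh_path}: missing 'region_tag' cell data")
    side = json.loads(side_path.read_text())
    if "tags_legend" not in side:
        raise FormatError(f"{side_path}: missing tags legend")
    tags = np.asarray(cell_data["region_tag"], dtype=int)[len(tets):]
    geom = ChamberGeometry(
        vertices=pts, tetrahedra=tets, boundary_facets=tris, facet_tags=tags,
        laa_wall_vertices=np.asarray(side.get("laa_wall_vertices", []), dtype=int),
        laa_cells=np.asarray(side.get("laa_cells", []), dtype=int),
        ostium_ring=np.asarray(side.get("ostium_ring", []), dtype=int),
    )
    frames = None
    if "frames" in side:
        meta = side["frames"]
        wall_ids = np.asarray(meta["wall_vertex_ids"], dtype=int)
        n = meta["n_frames"]
        disps = []
        for i in range(n):
            _, _, _, pdata, _ = read_vtu(case_dir / f"frame_{i:03d}.vtu")
            disps.append(pdata["displacement"][wall_ids])
        frames = FrameSet(
            frame_times=np.asarray(meta["frame_times"], dtype=float),
            wall_vertex_ids=wall_ids,
            boundary_displacements=np.stack(disps),
            period=float(meta["period"]),
        )
    phen = None
    if "phenotype" in side:
        phen = PhenotypeParams(**side["phenotype"])
    return geom, frames, phen


def write_frameset(path, frames: FrameSet):
    """Single-file JSON serialization of a FrameSet (bit-exact round-trip)."""
    payload = {
        "period": frames.period.hex() if isinstance(frames.period, float) else frames.period,
        "frame_times": [t.hex() for t in map(float, frames.frame_times)],
        "wall_vertex_ids": frames.wall_vertex_ids.tolist(),
        "displacements": [v.hex() for v in frames.boundary_displacements.ravel()],
        "shape": list(frames.boundary_displacements.shape),
    }
    Path(path).write_text(json.dumps(payload))


def read_frameset(path) -> FrameSet:
    payload = json.loads(Path(path).read_text())
    disp = np.array([float.fromhex(v) for v in payload["displacements"]])
    return FrameSet(
        frame_times=np.array([float.fromhex(t) for t in payload["frame_times"]]),
        wall_vertex_ids=np.asarray(payload["wall_vertex_ids"], dtype=int),
        boundary_displacements=disp.reshape(payload["shape"]),
        period=float.fromhex(payload["period"])
        if isinstance(payload["period"], str) else float(payload["period"]),
    )
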