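"""Mesh and field I/O: ASCII VTU (read/write) and Gmsh MSH (read).

VTU files are XML `UnstructuredGrid` pieces with triangle cells only;
floats are written with 17 significant digits so a write→read round
trip is bit-exact.  Region tags travel as the integer cell-data array
``region`` (codes = :class:`~hosim.materials.TissueClass` values);
named boundary-edge and node sets travel in ``FieldData`` so a
generated stump survives a round trip intact.
"""

from __future__ import annotations

import json
import os
import xml.etree.ElementTree as ET

import numpy as np

from hosim.geometry import StumpMesh
from hosim.materials import TissueClass

__all__ = ["read_mesh", "write_mesh", "read_vtu", "write_vtu", "read_msh", "SeriesWriter"]

VTK_TRIANGLE = 5

#: cell-data integer code table for region tags
REGION_CODES = {cls.name: int(cls) for cls in TissueClass}


class MeshIOError(ValueError):
    pass


def _fmt_floats(arr: np.ndarray) -> str:
    return " ".join(np.format_float_scientific(v, precision=16) for v in np.ravel(arr))


def _fmt_ints(arr: np.ndarray) -> str:
    return " ".join(str(int(v)) for v in np.ravel(arr))


def write_vtu(
    path: str,
    nodes: np.ndarray,
    triangles: np.ndarray,
    cell_data: dict[str, np.ndarray] | None = None,
    point_data: dict[str, np.ndarray] | None = None,
    field_data: dict[str, np.ndarray] | None = None,
) -> None:
    n, m = len(nodes), len(triangles)
    parts = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
    ]
    if field_data:
        parts.append("<FieldData>")
        for name, arr in field_data.items():
            arr = np.asarray(arr)
            if np.issubdtype(arr.dtype, np.integer):
                parts.append(
                    f'<DataArray type="Int64" Name="{name}" '
                    f'NumberOfTuples="{arr.size}" format="ascii">{_fmt_ints(arr)}</DataArray>'
                )
            else:
                parts.append(
                    f'<DataArray type="Float64" Name="{name}" '
                    f'NumberOfTuples="{arr.size}" format="ascii">{_fmt_floats(arr)}</DataArray>'
                )
        parts.append("</FieldData>")
    parts.append(f'<Piece NumberOfPoints="{n}" NumberOfCells="{m}">')
    pts3 = np.column_stack([nodes, np.zeros(len(nodes))])
    parts.append(
        '<Points><DataArray type="Float64" NumberOfComponents="3" format="ascii">'
        f"{_fmt_floats(pts3)}</DataArray></Points>"
    )
    parts.append("<Cells>")
    parts.append(
        f'<DataArray type="Int64" Name="connectivity" format="ascii">{_fmt_ints(triangles)}</DataArray>'
    )
    offsets = 3 * np.arange(1, m + 1)
    parts.append(
        f'<DataArray type="Int64" Name="offsets" format="ascii">{_fmt_ints(offsets)}</DataArray>'
    )
    parts.append(
        f'<DataArray type="UInt8" Name="types" format="ascii">{_fmt_ints(np.full(m, VTK_TRIANGLE))}</DataArray>'
    )
    parts.append("</Cells>")
    for tag, data in (("CellData", cell_data), ("PointData", point_data)):
        if data:
            parts.append(f"<{tag}>")
            for name, arr in data.items():
                arr = np.asarray(arr)
                if np.issubdtype(arr.dtype, np.integer):
                    parts.append(
                        f'<DataArray type="Int64" Name="{name}" format="ascii">{_fmt_ints(arr)}</DataArray>'
                    )
                else:
                    parts.append(
                        f'<DataArray type="Float64" Name="{name}" format="ascii">{_fmt_floats(arr)}</DataArray>'
                    )
            parts.append(f"</{tag}>")
    parts.append("</Piece></UnstructuredGrid></VTKFile>")
    with open(path, "w") as fh:
        fh.write("\n".join(parts))


def _parse_data_array(el: ET.Element) -> np.ndarray:
    tokens = (el.text or "").split()
    if el.get("type") in ("Int64", "Int32", "UInt8", "UInt32"):
        return np.array(tokens, dtype=np.int64)
    return np.array(tokens, dtype=np.float64)


def read_vtu(path: str):
    """Read an ASCII VTU → (nodes, triangles, cell_data, point_data, field_data)."""
    root = ET.parse(path).getroot()
    piece = root.find(".//Piece")
    if piece is None:
        raise MeshIOError(f"{path}: no UnstructuredGrid Piece found")
    pts = _parse_data_array(piece.find("Points/DataArray")).reshape(-1, 3)[:, :2]
    cells = {da.get("Name"): da for da in piece.findall("Cells/DataArray")}
    types = _parse_data_array(cells["types"])
    bad = np.unique(types[types != VTK_TRIANGLE])
    if bad.size:
        names = {1: "vertex", 3: "line", 8: "pixel", 9: "quad", 10: "tetra"}
        kinds = ", ".join(names.get(int(t), f"VTK type {int(t)}") for t in bad)
        raise MeshIOError(f"{path}: unsupported cell types ({kinds}); triangles only")
    conn = _parse_data_array(cells["connectivity"]).reshape(-1, 3)
    cell_data = {
        da.get("Name"): _parse_data_array(da) for da in piece.findall("CellData/DataArray")
    }
    point_data = {
        da.get("Name"): _parse_data_array(da) for da in piece.findall("PointData/DataArray")
    }
    field_data = {
        da.get("Name"): _parse_data_array(da) for da in root.findall(".//FieldData/DataArray")
    }
    return pts, conn, cell_data, point_data, field_data


def write_mesh(mesh: StumpMesh, path: str, cell_data: dict | None = None) -> None:
    """Write a stump mesh (region tags + named sets included) to VTU."""
    cd = {"region": mesh.element_region.astype(np.int64)}
    if cell_data:
        cd.update(cell_data)
    fd: dict[str, np.ndarray] = {}
    for name, edges in mesh.boundary_edges.items():
        fd[f"edgeset:{name}"] = np.asarray(edges, dtype=np.int64).ravel()
    for name, nodes in mesh.node_sets.items():
        fd[f"nodeset:{name}"] = np.asarray(nodes, dtype=np.int64)
    fd["femoral_axis"] = np.asarray(mesh.femoral_axis, dtype=float)
    fd["medial_lateral_axis"] = np.asarray(mesh.medial_lateral_axis, dtype=float)
    write_vtu(path, mesh.nodes, mesh.triangles, cell_data=cd, field_data=fd)


def read_mesh(path: str) -> StumpMesh:
    """Read a VTU or Gmsh MSH file into a :class:`StumpMesh`.

    Elements without a ``region`` cell-data array default to SOFT.
    """
    ext = os.path.splitext(path)[1].lower()
    if ext == ".msh":
        nodes, tris = read_msh(path)
        cell_data, field_data = {}, {}
    else:
        nodes, tris, cell_data, _pd, field_data = read_vtu(path)
    region = cell_data.get(
        "region", np.full(len(tris), int(TissueClass.SOFT), dtype=np.int64)
    ).astype(int)
    mesh = StumpMesh(nodes=nodes, triangles=tris.astype(int), element_region=region)
    for name, arr in field_data.items():
        if name.startswith("edgeset:"):
            mesh.boundary_edges[name.split(":", 1)[1]] = arr.astype(int).reshape(-1, 2)
        elif name.startswith("nodeset:"):
            mesh.node_sets[name.split(":", 1)[1]] = arr.astype(int)
        elif name == "femoral_axis":
            mesh.femoral_axis = arr.astype(float)
        elif name == "medial_lateral_axis":
            mesh.medial_lateral_axis = arr.astype(float)
    return mesh


def read_msh(path: str) -> tuple[np.ndarray, np.ndarray]:
    """Read a Gmsh MSH v2 or v4 ASCII file (triangles only)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    try:
        ver = float(lines[lines.index("$MeshFormat") + 1].split()[0])
    except (ValueError, IndexError) as exc:
        raise MeshIOError(f"{path}: not a Gmsh MSH file") from exc
    if ver < 4:
        return _read_msh2(path, lines)
    return _read_msh4(path, lines)


_MSH_TYPE_NAMES = {1: "line", 3: "quad", 4: "tetra", 15: "point"}


def _read_msh2(path, lines):
    i = lines.index("$Nodes") + 1
    n = int(lines[i])
    ids, coords = [], []
    for row in lines[i + 1 : i + 1 + n]:
        parts = row.split()
        ids.append(int(parts[0]))
        coords.append((float(parts[1]), float(parts[2])))
    remap = {nid: k for k, nid in enumerate(ids)}
    j = lines.index("$Elements") + 1
    m = int(lines[j])
    tris = []
    for row in lines[j + 1 : j + 1 + m]:
        parts = row.split()
        etype = int(parts[1])
        if etype in (1, 15):
            continue  # embedded lower-dimensional entities are ignored
        if etype != 2:
            name = _MSH_TYPE_NAMES.get(etype, f"type {etype}")
            raise MeshIOError(f"{path}: unsupported cell type ({name}); triangles only")
        ntags = int(parts[2])
        tris.append([remap[int(v)] for v in parts[3 + ntags : 6 + ntags]])
    return np.array(coords), np.array(tris, dtype=int)


def _read_msh4(path, lines):
    i = lines.index("$Nodes") + 1
    num_blocks = int(lines[i].split()[0])
    row = i + 1
    ids, coords = [], []
    for _ in range(num_blocks):
        _dim, _tag, _param, n = (int(v) for v in lines[row].split())
        row += 1
        block_ids = [int(lines[row + k]) for k in range(n)]
        row += n
        for k in range(n):
            x, y, _z = (float(v) for v in lines[row + k].split()[:3])
            coords.append((x, y))
        ids.extend(block_ids)
        row += n
    remap = {nid: k for k, nid in enumerate(ids)}
    j = lines.index("$Elements") + 1
    num_blocks = int(lines[j].split()[0])
    row = j + 1
    tris = []
    for _ in range(num_blocks):
        _dim, _tag, etype, n = (int(v) for v in lines[row].split())
        row += 1
        if etype in (1, 15):
            row += n
            continue
        if etype != 2:
            name = _MSH_TYPE_NAMES.get(etype, f"type {etype}")
            raise MeshIOError(f"{path}: unsupported cell type ({name}); triangles only")
        for k in range(n):
            parts = lines[row + k].split()
            tris.append([remap[int(v)] for v in parts[1:4]])
        row += n
    return np.array(coords), np.array(tris, dtype=int)


class SeriesWriter:
    """VTU time series: one file per saved iteration plus a JSON index."""

    def __init__(self, out_dir: str, basename: str = "state") -> None:
        self.out_dir = out_dir
        self.basename = basename
        self.entries: list[dict] = []
        os.makedirs(out_dir, exist_ok=True)

    def save(self, mesh: StumpMesh, iteration: int, cell_data: dict) -> str:
        fname = f"{self.basename}_{iteration:05d}.vtu"
        write_mesh(mesh, os.path.join(self.out_dir, fname), cell_data=cell_data)
        self.entries.append({"iteration": iteration, "file": fname})
        self._flush()
        return fname

    def _flush(self) -> None:
        with open(os.path.join(self.out_dir, f"{self.basename}_series.json"), "w") as fh:
            json.dump({"files": self.entries, "region_codes": REGION_CODES}, fh, indent=1)
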