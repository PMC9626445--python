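"""File formats, configuration and run manifests.

On-disk formats (all documented as mm / day / MPa):
  * Gmsh MSH 2.2 ASCII for bare tetrahedral meshes (input),
  * VTK unstructured-grid XML (.vtu, ASCII) for meshes with point/cell data
    (snapshots and time series; readable by ParaView),
  * NIfTI for voxel tensor grids (six components xx,xy,xz,yy,yz,zz),
  * YAML for configuration, CSV for tabular outputs,
  * JSON run manifest with config echo, input hashes and the per-step log.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from .mesh import TetMesh
from .params import GrowthParams, MaterialParams, ModelParams, PermeabilityParams
from .solver import SimulationConfig

UNITS = {"length": "mm", "time": "day", "stress": "MPa"}


# ----------------------------------------------------------------- MSH 2.2

def write_msh(path, mesh: TetMesh) -> None:
    """Write a bare tetrahedral mesh in Gmsh MSH 2.2 ASCII format."""
    path = Path(path)
    with path.open("w") as f:
        f.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        f.write(f"$Nodes\n{mesh.n_points}\n")
        for i, p in enumerate(mesh.points, start=1):
            f.write(f"{i} {p[0]:.16g} {p[1]:.16g} {p[2]:.16g}\n")
        f.write(f"$EndNodes\n$Elements\n{mesh.n_cells}\n")
        for i, c in enumerate(mesh.cells + 1, start=1):
            f.write(f"{i} 4 2 0 1 {c[0]} {c[1]} {c[2]} {c[3]}\n")
        f.write("$EndElements\n")


def read_msh(path) -> TetMesh:
    """Read tetrahedra (element type 4) from a Gmsh MSH 2.2 ASCII file."""
    lines = Path(path).read_text().splitlines()
    it = iter(lines)
    points = None
    cells = []
    for line in it:
        if line.strip() == "$MeshFormat":
            ver = next(it).split()[0]
            if not ver.startswith("2"):
                raise ValueError(f"unsupported MSH version {ver} (need 2.x ASCII)")
        elif line.strip() == "$Nodes":
            n = int(next(it))
            points = np.empty((n, 3))
            for k in range(n):
                parts = next(it).split()
                points[k] = [float(x) for x in parts[1:4]]
        elif line.strip() == "$Elements":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                etype = int(parts[1])
                ntags = int(parts[2])
                if etype == 4:
                    cells.append([int(x) - 1 for x in parts[3 + ntags:7 + ntags]])
    if points is None or not cells:
        raise ValueError(f"{path}: no tetrahedral mesh found")
    return TetMesh(points=points, cells=np.array(cells, dtype=np.int64))


# ---------------------------------------------------------------- VTU ASCII

def _da(name: str, arr: np.ndarray, ncomp: int) -> str:
    flat = np.asarray(arr, dtype=float).reshape(-1)
    body = " ".join(f"{x:.16g}" for x in flat)
    return (f'<DataArray type="Float64" Name="{name}" '
            f'NumberOfComponents="{ncomp}" format="ascii">{body}</DataArray>')


def write_vtu(path, mesh: TetMesh, point_data: dict | None = None,
              cell_data: dict | None = None) -> None:
    """Write mesh + named fields as an ASCII VTK unstructured grid (.vtu).

    Point data are nodal arrays (N,) or (N, d); cell data are (M,) or
    (M, d) — symmetric tensors should be passed as six components.
    """
    point_data = point_data or {}
    cell_data = cell_data or {}
    N, M = mesh.n_points, mesh.n_cells
    parts = ['<?xml version="1.0"?>',
             '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
             f'<!-- units: {json.dumps(UNITS)} -->',
             '<UnstructuredGrid>',
             f'<Piece NumberOfPoints="{N}" NumberOfCells="{M}">',
             '<Points>', _da("Points", mesh.points, 3), '</Points>',
             '<Cells>',
             '<DataArray type="Int64" Name="connectivity" format="ascii">'
             + " ".join(map(str, mesh.cells.reshape(-1))) + '</DataArray>',
             '<DataArray type="Int64" Name="offsets" format="ascii">'
             + " ".join(str(4 * (i + 1)) for i in range(M)) + '</DataArray>',
             '<DataArray type="UInt8" Name="types" format="ascii">'
             + " ".join(["10"] * M) + '</DataArray>',
             '</Cells>']
    parts.append('<PointData>')
    for name, arr in point_data.items():
        arr = np.asarray(arr)
        ncomp = 1 if arr.ndim == 1 else arr.shape[1]
        parts.append(_da(name, arr, ncomp))
    parts.append('</PointData><CellData>')
    for name, arr in cell_data.items():
        arr = np.asarray(arr)
        ncomp = 1 if arr.ndim == 1 else arr.shape[1]
        parts.append(_da(name, arr, ncomp))
    parts.append('</CellData></Piece></UnstructuredGrid></VTKFile>')
    Path(path).write_text("\n".join(parts))


def read_vtu(path):
    """Read an ASCII .vtu written by this package.

    Returns (mesh, point_data, cell_data).
    """
    from lxml import etree

    root = etree.parse(str(path)).getroot()
    piece = root.find(".//Piece")
    N = int(piece.get("NumberOfPoints"))
    M = int(piece.get("NumberOfCells"))

    def parse(el):
        return np.fromstring(el.text, sep=" ")

    pts = parse(piece.find("Points/DataArray")).reshape(N, 3)
    conn = parse(piece.find("Cells/DataArray[@Name='connectivity']")).astype(np.int64)
    mesh = TetMesh(points=pts, cells=conn.reshape(M, 4))

    def fields(tag, n):
        out = {}
        node = piece.find(tag)
        if node is not None:
            for el in node.findall("DataArray"):
                ncomp = int(el.get("NumberOfComponents", "1"))
                arr = parse(el)
                out[el.get("Name")] = arr if ncomp == 1 else arr.reshape(n, ncomp)
        return out

    return mesh, fields("PointData", N), fields("CellData", M)


def read_mesh_with_fields(path):
    """Read a mesh (+ fields for .vtu) and validate it.

    Validation: no inverted tetrahedra (error names the cell), finite values,
    a 'chi' point field inside [0, 1] if present, symmetric 6-component cell
    tensors for fields named D0/A0 (order xx,xy,xz,yy,yz,zz).
    """
    path = Path(path)
    if path.suffix == ".msh":
        mesh, point_data, cell_data = read_msh(path), {}, {}
    elif path.suffix == ".vtu":
        mesh, point_data, cell_data = read_vtu(path)
    else:
        raise ValueError(f"unknown mesh format '{path.suffix}' (use .msh or .vtu)")
    mesh.validate()
    for name, arr in {**point_data, **cell_data}.items():
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"field '{name}' contains non-finite values")
    if "chi" in point_data:
        chi = point_data["chi"]
        if np.any(chi < -1e-9) or np.any(chi > 1.0 + 1e-9):
            raise ValueError("field 'chi' leaves the admissible range [0, 1]")
    for name in ("D0", "A0"):
        if name in cell_data and cell_data[name].shape[1] != 6:
            raise ValueError(f"cell tensor field '{name}' must have 6 components")
    return mesh, point_data, cell_data


# ------------------------------------------------------------ configuration

def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["units"] = dict(UNITS)
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    d.pop("units", None)
    pblocks = d.pop("params", {}) or {}
    known = {f for f in SimulationConfig.__dataclass_fields__ if f != "params"}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    params = ModelParams(
        material=MaterialParams(**pblocks.get("material", {})),
        permeability=PermeabilityParams(**pblocks.get("permeability", {})),
        growth=GrowthParams(**pblocks.get("growth", {})),
    )
    return SimulationConfig(params=params, **d)


def load_config(path) -> SimulationConfig:
    with Path(path).open() as f:
        return config_from_dict(yaml.safe_load(f) or {})


def save_config(path, config: SimulationConfig) -> None:
    with Path(path).open("w") as f:
        yaml.safe_dump(config_to_dict(config), f, sort_keys=False)


# ---------------------------------------------------------------- manifest

def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(path, config: SimulationConfig, inputs: dict,
                   outputs: list, step_log: list) -> None:
    """JSON run manifest: config echo, input/output hashes, per-step log."""
    from . import __version__

    manifest = {
        "package": {"name": "gliomech", "version": __version__},
        "units": dict(UNITS),
        "config": config_to_dict(config),
        "inputs": {k: {"path": str(v), "sha256": _sha256(v)}
                   for k, v in inputs.items()},
        "outputs": [{"path": str(p), "sha256": _sha256(p)} for p in outputs],
        "steps": step_log,
    }
    Path(path).write_text(json.dumps(manifest, indent=1))
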