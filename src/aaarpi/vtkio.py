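"""Plain-text writers/readers for the pipeline's exchange formats.

* legacy ASCII ``.vtk`` unstructured grids for tetrahedral meshes
  (linear and quadratic tets, region tags as cell data, nodal fields)
* ASCII ``.vtp`` (XML PolyData) for result surfaces with per-vertex fields
* STL for analysis surfaces (via trimesh)
* the element-size lattice as ``x y z size`` lines
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import AaaError
from .geometry import SizeField
from .meshing import TetMesh
from .surface import TriSurface

__all__ = [
    "write_vtk_mesh",
    "read_vtk_mesh",
    "write_vtk_polydata",
    "read_vtk_polydata",
    "write_vtp_surface",
    "write_stl",
    "read_stl",
    "write_size_lattice",
]

_VTK_TET4, _VTK_TET10 = 10, 24


def write_vtk_mesh(
    mesh: TetMesh, path: str | Path, point_fields: dict[str, np.ndarray] | None = None
) -> None:
    """Legacy ASCII VTK unstructured grid with region tags and nodal fields."""
    path = Path(path)
    nsh = mesh.tets.shape[1]
    ctype = _VTK_TET4 if nsh == 4 else _VTK_TET10
    lines = [
        "# vtk DataFile Version 3.0",
        "aaarpi tetrahedral mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    lines += [" ".join(f"{x:.10g}" for x in p) for p in mesh.nodes]
    nt = len(mesh.tets)
    lines.append(f"CELLS {nt} {nt * (nsh + 1)}")
    lines += [f"{nsh} " + " ".join(str(i) for i in row) for row in mesh.tets]
    lines.append(f"CELL_TYPES {nt}")
    lines += [str(ctype)] * nt
    lines.append(f"CELL_DATA {nt}")
    lines.append("SCALARS region int 1")
    lines.append("LOOKUP_TABLE default")
    region_code = {"wall": 1, "ilt": 2}
    lines += [str(region_code.get(r, 0)) for r in mesh.region_tags]
    if point_fields:
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        for name, vals in point_fields.items():
            vals = np.asarray(vals)
            if vals.ndim == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines += [f"{v:.10g}" for v in vals]
            else:
                lines.append(f"VECTORS {name} double")
                lines += [" ".join(f"{x:.10g}" for x in v) for v in vals]
    path.write_text("\n".join(lines) + "\n")


def read_vtk_mesh(path: str | Path) -> tuple[TetMesh, dict[str, np.ndarray]]:
    """Read a mesh written by :func:`write_vtk_mesh` (returns point fields too)."""
    tokens = Path(path).read_text().split()
    it = iter(range(len(tokens)))

    def find(word: str, start: int = 0) -> int:
        for i in range(start, len(tokens)):
            if tokens[i] == word:
                return i
        raise AaaError(f"{path}: missing {word!r}")

    ip = find("POINTS")
    n = int(tokens[ip + 1])
    coords = np.asarray(tokens[ip + 3 : ip + 3 + 3 * n], dtype=float).reshape(n, 3)
    ic = find("CELLS")
    nt = int(tokens[ic + 1])
    total = int(tokens[ic + 2])
    flat = np.asarray(tokens[ic + 3 : ic + 3 + total], dtype=np.int64)
    nsh = int(flat[0])
    cells = flat.reshape(nt, nsh + 1)[:, 1:]
    ir = find("SCALARS")
    # region scalars follow "LOOKUP_TABLE default"
    il = find("default", ir)
    region_vals = np.asarray(tokens[il + 1 : il + 1 + nt], dtype=int)
    region = np.where(region_vals == 2, "ilt", "wall")
    fields: dict[str, np.ndarray] = {}
    try:
        ipd = find("POINT_DATA")
    except AaaError:
        ipd = None
    if ipd is not None:
        i = ipd + 2
        while i < len(tokens):
            kind = tokens[i]
            if kind == "SCALARS":
                name = tokens[i + 1]
                j = find("default", i) + 1
                fields[name] = np.asarray(tokens[j : j + n], dtype=float)
                i = j + n
            elif kind == "VECTORS":
                name = tokens[i + 1]
                j = i + 3
                fields[name] = np.asarray(tokens[j : j + 3 * n], dtype=float).reshape(n, 3)
                i = j + 3 * n
            else:
                i += 1
    return TetMesh(coords, cells, region, {}, {}), fields


def write_vtk_polydata(surface: TriSurface, path: str | Path) -> None:
    """Legacy ASCII VTK polydata with per-vertex scalar fields."""
    path = Path(path)
    v, t = surface.vertices, surface.triangles
    lines = [
        "# vtk DataFile Version 3.0",
        "aaarpi surface",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(v)} double",
    ]
    lines += [" ".join(f"{x:.10g}" for x in p) for p in v]
    lines.append(f"POLYGONS {len(t)} {4 * len(t)}")
    lines += ["3 " + " ".join(str(i) for i in tri) for tri in t]
    if surface.vertex_fields:
        lines.append(f"POINT_DATA {len(v)}")
        for name, vals in surface.vertex_fields.items():
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{x:.10g}" for x in np.asarray(vals, dtype=float)]
    path.write_text("\n".join(lines) + "\n")


def read_vtk_polydata(path: str | Path) -> TriSurface:
    """Read a surface written by :func:`write_vtk_polydata`."""
    tokens = Path(path).read_text().split()

    def find(word: str, start: int = 0) -> int:
        for i in range(start, len(tokens)):
            if tokens[i] == word:
                return i
        raise AaaError(f"{path}: missing {word!r}")

    ip = find("POINTS")
    n = int(tokens[ip + 1])
    verts = np.asarray(tokens[ip + 3 : ip + 3 + 3 * n], dtype=float).reshape(n, 3)
    ig = find("POLYGONS")
    m = int(tokens[ig + 1])
    total = int(tokens[ig + 2])
    flat = np.asarray(tokens[ig + 3 : ig + 3 + total], dtype=np.int64)
    tris = flat.reshape(m, 4)[:, 1:]
    fields: dict[str, np.ndarray] = {}
    i = ig + 3 + total
    while i < len(tokens):
        if tokens[i] == "SCALARS":
            name = tokens[i + 1]
            j = find("default", i) + 1
            fields[name] = np.asarray(tokens[j : j + n], dtype=float)
            i = j + n
        else:
            i += 1
    return TriSurface(verts, tris, fields)


def write_vtp_surface(surface: TriSurface, path: str | Path) -> None:
    """ASCII XML PolyData with every vertex field as a PointData array."""
    path = Path(path)
    v, t = surface.vertices, surface.triangles
    arrays = []
    for name, vals in surface.vertex_fields.items():
        data = " ".join(f"{x:.8g}" for x in np.asarray(vals, dtype=float))
        arrays.append(
            f'      <DataArray type="Float64" Name="{name}" format="ascii">\n'
            f"        {data}\n      </DataArray>"
        )
    pdata = "\n".join(arrays)
    pts = " ".join(f"{x:.8g}" for x in v.ravel())
    conn = " ".join(str(i) for i in t.ravel())
    offs = " ".join(str(3 * (i + 1)) for i in range(len(t)))
    xml = f"""<?xml version="1.0"?>
<VTKFile type="PolyData" version="0.1" byte_order="LittleEndian">
  <PolyData>
    <Piece NumberOfPoints="{len(v)}" NumberOfPolys="{len(t)}">
    <PointData>
{pdata}
    </PointData>
      <Points>
        <DataArray type="Float64" NumberOfComponents="3" format="ascii">
          {pts}
        </DataArray>
      </Points>
      <Polys>
        <DataArray type="Int64" Name="connectivity" format="ascii">
          {conn}
        </DataArray>
        <DataArray type="Int64" Name="offsets" format="ascii">
          {offs}
        </DataArray>
      </Polys>
    </Piece>
  </PolyData>
</VTKFile>
"""
    path.write_text(xml)


def write_stl(surface: TriSurface, path: str | Path) -> None:
    surface.as_trimesh().export(str(path))


def read_stl(path: str | Path) -> TriSurface:
    import trimesh

    m = trimesh.load(str(path), force="mesh")
    return TriSurface.from_trimesh(m)


def write_size_lattice(sf: SizeField, path: str | Path) -> None:
    """Element-size lattice as ``x y z size`` per line (mesher exchange file)."""
    path = Path(path)
    shape = sf.sizes.shape
    with open(path, "w") as fh:
        for i in range(shape[0]):
            x = sf.origin[0] + sf.spacing * i
            for j in range(shape[1]):
                y = sf.origin[1] + sf.spacing * j
                for k in range(shape[2]):
                    z = sf.origin[2] + sf.spacing * k
                    fh.write(f"{x:.3f} {y:.3f} {z:.3f} {sf.sizes[i, j, k]:.5f}\n")
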