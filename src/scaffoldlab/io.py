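"""Geometry and table writers: binary STL, legacy VTK, CSV metadata."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import trimesh

from .geometry import VoxelGrid

__all__ = ["write_stl", "write_vtk", "write_grid_metadata"]


def write_stl(path, verts: np.ndarray, faces: np.ndarray) -> Path:
    """Write a triangle mesh as binary STL.

    Returns the path written, or raises ``ValueError`` for an empty mesh
    (a single-phase cell has no interface to export).
    """
    path = Path(path)
    faces = np.asarray(faces, np.int64)
    if len(faces) == 0:
        raise ValueError("mesh has no triangles; nothing to export")
    mesh = trimesh.Trimesh(
        vertices=np.asarray(verts, float), faces=faces, process=False
    )
    mesh.export(path, file_type="stl")
    return path


def write_vtk(path, grid: VoxelGrid, name: str = "occupancy") -> Path:
    """Write the occupancy grid as a legacy-ASCII VTK structured-points file."""
    path = Path(path)
    nx, ny, nz = grid.shape
    h = grid.voxel_size
    ox, oy, oz = grid.origin
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("scaffoldlab voxel grid\nASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write(f"ORIGIN {ox + h / 2} {oy + h / 2} {oz + h / 2}\n")
        fh.write(f"SPACING {h} {h} {h}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        fh.write(f"SCALARS {name} unsigned_char 1\nLOOKUP_TABLE default\n")
        vals = grid.occupancy.astype(np.uint8).transpose(2, 1, 0).ravel()
        for lo in range(0, vals.size, 30):
            fh.write(" ".join(map(str, vals[lo : lo + 30])) + "\n")
    return path


def write_grid_metadata(path, grid: VoxelGrid) -> Path:
    """Plain-text dump of the grid's descriptive numbers."""
    path = Path(path)
    nx, ny, nz = grid.shape
    lines = [
        "key,value",
        f"shape,{nx}x{ny}x{nz}",
        f"voxel_size_mm,{grid.voxel_size!r}",
        f"porosity,{grid.porosity!r}",
        f"solid_fraction,{grid.solid_fraction!r}",
    ]
    if grid.spec is not None:
        lines += [
            f"topology,{grid.spec.topology.value}",
            f"level_set_constant,{grid.spec.C!r}",
            f"edge_length_mm,{grid.spec.edge_length!r}",
        ]
    path.write_text("\n".join(lines) + "\n")
    return path
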