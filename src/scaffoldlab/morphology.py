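"""Porosity and surface-to-volume ratio of scaffold cells.

Porosity is the void fraction of the nominal bounding cube, measured as the
voxel phase fraction.  The inner surface — the solid/void interface, the
outer cube faces excluded — is triangulated by marching cubes on the
continuous implicit field whenever one is available, which tracks the smooth
iso-surface instead of the staircase voxel boundary; its area divided by the
nominal volume gives S/V in 1/mm.  A quadratic in porosity is fitted to
(porosity, S/V) sweeps by ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import marching_cubes, mesh_surface_area

from .geometry import UnitCellSpec, VoxelGrid, calibrate_levelset, voxelize

__all__ = [
    "MorphologyResult",
    "QuadraticFit",
    "measure_morphology",
    "fit_sv_quadratic",
    "sv_porosity_sweep",
    "iso_surface",
]


@dataclass
class MorphologyResult:
    """Morphometry of one cell: porosity, inner surface area, S/V."""

    porosity: float
    surface_area: float  # mm^2
    sv_ratio: float  # mm^-1, surface_area / nominal_volume
    nominal_volume: float  # mm^3


@dataclass
class QuadraticFit:
    """Coefficients of ``a2 * p**2 + a1 * p + a0`` with goodness of fit."""

    a2: float
    a1: float
    a0: float
    r_squared: float

    def __call__(self, p):
        return self.a2 * np.asarray(p) ** 2 + self.a1 * np.asarray(p) + self.a0

    def summary(self) -> str:
        return (
            f"S/V = {self.a2:+.3f} p^2 {self.a1:+.3f} p {self.a0:+.3f}"
            f"  (R^2 = {self.r_squared:.4f})"
        )


def _node_field(spec):
    """Field sampled on the (res+1)^3 node lattice spanning the full cell."""
    n = spec.resolution
    c = np.linspace(0.0, spec.edge_length, n + 1)
    return spec.field(c[:, None, None], c[None, :, None], c[None, None, :])


def iso_surface(spec):
    """Marching-cubes triangulation (verts mm, faces) of the solid boundary.

    ``spec`` is anything with the continuous-field protocol (``field``,
    ``resolution``, ``edge_length``): a unit-cell spec or an analytic
    fixture.  Returns ``(verts, faces)``; both empty for a single-phase cell.
    """
    f = _node_field(spec)
    h = spec.edge_length / spec.resolution
    if f.min() >= 0.0 or f.max() < 0.0:
        return np.empty((0, 3)), np.empty((0, 3), int)
    verts, faces, _, _ = marching_cubes(f, level=0.0, spacing=(h, h, h))
    return verts, faces


def _has_field(obj) -> bool:
    return all(hasattr(obj, a) for a in ("field", "resolution", "edge_length"))


def measure_morphology(obj, resolution: int | None = None) -> MorphologyResult:
    """Measure porosity and inner S/V of a cell.

    Parameters
    ----------
    obj : UnitCellSpec, fixture, or VoxelGrid
        With a continuous field available (spec, fixture, or a grid carrying
        its spec) the surface is triangulated on the smooth iso-surface; a
        bare grid falls back to marching cubes on the voxel indicator, which
        carries staircase bias of up to a few percent.
    resolution : int, optional
        Override the object's resolution (continuous-field route only).
    """
    if isinstance(obj, VoxelGrid):
        grid, spec = obj, obj.spec
    elif _has_field(obj):
        spec = obj if resolution is None else obj.with_resolution(resolution)
        grid = spec.grid if hasattr(spec, "grid") else voxelize(spec)
    else:
        raise TypeError(f"cannot measure morphology of {type(obj).__name__}")

    ex, ey, ez = grid.extent
    nominal_volume = ex * ey * ez
    porosity = grid.porosity

    if spec is not None and _has_field(spec):
        verts, faces = iso_surface(spec)
        area = float(mesh_surface_area(verts, faces)) if len(faces) else 0.0
    else:
        f = grid.occupancy.astype(float)
        if 0.0 < f.mean() < 1.0:
            h = grid.voxel_size
            verts, faces, _, _ = marching_cubes(f, level=0.5, spacing=(h, h, h))
            area = float(mesh_surface_area(verts, faces))
        else:
            area = 0.0
    return MorphologyResult(porosity, area, area / nominal_volume, nominal_volume)


def fit_sv_quadratic(points) -> QuadraticFit:
    """Least-squares quadratic of S/V against porosity.

    ``points`` is a sequence of ``(porosity, sv_ratio)`` pairs; at least four
    points spanning >= 0.2 in porosity are required for a meaningful fit.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 4:
        raise ValueError("need at least 4 (porosity, S/V) points")
    p, sv = pts[:, 0], pts[:, 1]
    if p.max() - p.min() < 0.2:
        raise ValueError("porosity spread must be >= 0.2 for a quadratic fit")
    coef = np.polyfit(p, sv, 2)
    pred = np.polyval(coef, p)
    ss_res = float(np.sum((sv - pred) ** 2))
    ss_tot = float(np.sum((sv - sv.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return QuadraticFit(float(coef[0]), float(coef[1]), float(coef[2]), r2)


def sv_porosity_sweep(
    topology,
    porosities=(0.3, 0.4, 0.5, 0.6, 0.7),
    resolution: int = 128,
    edge_length: float = 2.5,
):
    """Calibrate, voxelize and measure a cell at each target porosity.

    Returns a list of ``(spec, MorphologyResult)`` in porosity order.
    """
    out = []
    for target in porosities:
        C = calibrate_levelset(topology, target, resolution, edge_length)
        spec = UnitCellSpec(topology, C, edge_length, resolution)
        out.append((spec, measure_morphology(spec)))
    return out
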