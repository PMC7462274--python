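"""Unit-cell geometry: TPMS nodal fields, strut lattices, calibration, voxelization.

A scaffold unit cell is described implicitly by a scalar field f(x, y, z):
the solid phase is ``{f >= 0}`` and the void phase its complement.  For the
five TPMS topologies the field is the trigonometric nodal approximation
``U(x, y, z) - C`` with one period mapped onto one cell edge; for the three
strut lattices it is ``half_width - D(x, y, z)`` where ``D`` is a periodic
distance to the strut skeleton.  Porosity is tuned by the level-set constant
``C`` (TPMS) or the strut half-width (lattices), both monotone, so a target
porosity is reached by bisection against the voxel phase fraction.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Topology",
    "UnitCellSpec",
    "VoxelGrid",
    "evaluate_tpms_field",
    "strut_lattice_field",
    "scaffold_field",
    "calibrate_levelset",
    "voxelize",
    "tile",
    "voxel_centers",
    "CalibrationError",
]

DEFAULT_EDGE_LENGTH = 2.5  # mm, cubic cell edge


class Topology(str, enum.Enum):
    """Scaffold unit-cell topologies: five TPMS and three strut lattices."""

    DIAMOND = "diamond"
    GYROID = "gyroid"
    SCHWARZ_P = "schwarz-p"
    FISCHER_KOCH_S = "fischer-koch-s"
    F_RD = "f-rd"
    CUBE = "cube"
    FD_CUBE = "fd-cube"
    OCTA = "octa"

    @property
    def is_tpms(self) -> bool:
        return self in _TPMS_EQUATIONS

    @classmethod
    def coerce(cls, name: "Topology | str") -> "Topology":
        if isinstance(name, cls):
            return name
        key = str(name).strip().lower().replace("_", "-").replace(" ", "-")
        aliases = {
            "schwarzp": "schwarz-p",
            "p": "schwarz-p",
            "primitive": "schwarz-p",
            "d": "diamond",
            "g": "gyroid",
            "fischerkochs": "fischer-koch-s",
            "fischer-koch": "fischer-koch-s",
            "fks": "fischer-koch-s",
            "frd": "f-rd",
            "fdcube": "fd-cube",
        }
        key = aliases.get(key, key)
        try:
            return cls(key)
        except ValueError:
            raise ValueError(
                f"unknown topology {name!r}; choose from "
                f"{[t.value for t in cls]}"
            ) from None


def _u_diamond(x, y, z):
    return (
        np.sin(x) * np.sin(y) * np.sin(z)
        + np.sin(x) * np.cos(y) * np.cos(z)
        + np.cos(x) * np.sin(y) * np.cos(z)
        + np.cos(x) * np.cos(y) * np.sin(z)
    )


def _u_gyroid(x, y, z):
    return np.cos(x) * np.sin(y) + np.cos(y) * np.sin(z) + np.cos(z) * np.sin(x)


def _u_schwarz_p(x, y, z):
    return np.cos(x) + np.cos(y) + np.cos(z)


def _u_fischer_koch_s(x, y, z):
    return (
        np.cos(2 * x) * np.sin(y) * np.cos(z)
        + np.cos(2 * y) * np.sin(z) * np.cos(x)
        + np.cos(2 * z) * np.sin(x) * np.cos(y)
    )


def _u_f_rd(x, y, z):
    c2x, c2y, c2z = np.cos(2 * x), np.cos(2 * y), np.cos(2 * z)
    return (
        8 * np.cos(x) * np.cos(y) * np.cos(z)
        + c2x * c2y * c2z
        - c2x * c2y
        + c2y * c2z
        + c2z * c2x
    )


_TPMS_EQUATIONS = {
    Topology.DIAMOND: _u_diamond,
    Topology.GYROID: _u_gyroid,
    Topology.SCHWARZ_P: _u_schwarz_p,
    Topology.FISCHER_KOCH_S: _u_fischer_koch_s,
    Topology.F_RD: _u_f_rd,
}


def evaluate_tpms_field(topology, x, y, z, C=0.0, edge_length=DEFAULT_EDGE_LENGTH):
    """Evaluate the TPMS nodal field ``U(x, y, z) - C`` at physical points.

    Parameters
    ----------
    topology : Topology or str
        One of the five TPMS topologies.
    x, y, z : array_like
        Coordinates in mm; broadcast together.  One cell edge spans one
        period, i.e. the equation coordinate is ``2*pi * p / edge_length``.
    C : float
        Level-set constant (dimensionless).
    edge_length : float
        Cell edge in mm.

    Returns
    -------
    ndarray
        Field values; the solid phase is where the value is >= 0.
    """
    topology = Topology.coerce(topology)
    if not topology.is_tpms:
        raise ValueError(f"{topology.value} is a strut lattice, not a TPMS")
    scale = 2.0 * np.pi / edge_length
    x, y, z = np.broadcast_arrays(
        np.asarray(x, float), np.asarray(y, float), np.asarray(z, float)
    )
    return _TPMS_EQUATIONS[topology](x * scale, y * scale, z * scale) - C


def _per_dist(t, L):
    """Periodic distance of coordinate(s) t to the lattice planes {0 mod L}."""
    r = np.mod(t, L)
    return np.minimum(r, L - r)


def _cube_skeleton_distance(x, y, z, L):
    # 12 cell edges, square cross-section: a point lies in an edge strut of
    # half-width w when two of its three periodic plane distances are <= w.
    dx, dy, dz = _per_dist(x, L), _per_dist(y, L), _per_dist(z, L)
    return np.minimum(
        np.maximum(dx, dy), np.minimum(np.maximum(dy, dz), np.maximum(dz, dx))
    )


def _fd_cube_skeleton_distance(x, y, z, L):
    # Cube plus the 12 face diagonals, square cross-section oriented with the
    # face; min(max(da, dn), max(db, dn)) == max(min(da, db), dn).
    d_c = _cube_skeleton_distance(x, y, z, L)
    dx, dy, dz = _per_dist(x, L), _per_dist(y, L), _per_dist(z, L)
    rt2 = np.sqrt(2.0)

    def diag(a, b, dn):
        da = _per_dist(a - b, L) / rt2
        db = _per_dist(a + b, L) / rt2
        return np.maximum(np.minimum(da, db), dn)

    return np.minimum.reduce([d_c, diag(x, y, dz), diag(y, z, dx), diag(z, x, dy)])


def _octa_segments(L):
    """The 12 edges of the octahedron spanned by the six cell-face centers."""
    h = L / 2.0
    xs = [np.array(v, float) for v in ((0, h, h), (L, h, h))]
    ys = [np.array(v, float) for v in ((h, 0, h), (h, L, h))]
    zs = [np.array(v, float) for v in ((h, h, 0), (h, h, L))]
    segs = []
    for a in xs:
        for b in ys + zs:
            segs.append((a, b))
    for a in ys:
        for b in zs:
            segs.append((a, b))
    return segs


def _octa_skeleton_distance(x, y, z, L, chunk=1 << 16):
    # Circular cross-section struts on the octahedron edges.  Exact periodic
    # point-segment distance via the 27 lattice images of each (wrapped) point.
    shape = np.broadcast_shapes(x.shape, y.shape, z.shape)
    pts = np.stack(
        [np.mod(np.broadcast_to(c, shape).ravel(), L) for c in (x, y, z)], axis=1
    )
    segs = _octa_segments(L)
    shifts = np.array(
        [(i * L, j * L, k * L) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
    )
    out = np.empty(pts.shape[0])
    for lo in range(0, pts.shape[0], chunk):
        p = pts[lo : lo + chunk]  # (m, 3)
        best = np.full(p.shape[0], np.inf)
        for a, b in segs:
            ab = b - a
            denom = ab @ ab
            for s in shifts:
                ap = (p + s) - a  # (m, 3)
                t = np.clip((ap @ ab) / denom, 0.0, 1.0)
                d2 = np.einsum("ij,ij->i", ap, ap) - 2 * t * (ap @ ab) + t * t * denom
                np.minimum(best, d2, out=best)
        out[lo : lo + chunk] = np.sqrt(np.maximum(best, 0.0))
    return out.reshape(shape)


_STRUT_SKELETONS = {
    Topology.CUBE: _cube_skeleton_distance,
    Topology.FD_CUBE: _fd_cube_skeleton_distance,
    Topology.OCTA: _octa_skeleton_distance,
}


def strut_skeleton_distance(topology, x, y, z, edge_length=DEFAULT_EDGE_LENGTH):
    """Periodic distance from points (mm) to the lattice strut skeleton."""
    topology = Topology.coerce(topology)
    if topology.is_tpms:
        raise ValueError(f"{topology.value} is a TPMS, not a strut lattice")
    x, y, z = np.broadcast_arrays(
        np.asarray(x, float), np.asarray(y, float), np.asarray(z, float)
    )
    return _STRUT_SKELETONS[topology](x, y, z, edge_length)


def strut_lattice_field(
    topology, x, y, z, half_width, edge_length=DEFAULT_EDGE_LENGTH
):
    """Signed strut-lattice field ``half_width - D``; >= 0 inside the solid.

    ``half_width`` is the strut half-width in mm and must lie in
    ``(0, edge_length / 2)``.
    """
    if not 0.0 < half_width < edge_length / 2.0:
        raise ValueError(
            f"half_width must lie in (0, {edge_length / 2}); got {half_width}"
        )
    return half_width - strut_skeleton_distance(topology, x, y, z, edge_length)


def scaffold_field(topology, x, y, z, C, edge_length=DEFAULT_EDGE_LENGTH):
    """Dispatch to the TPMS nodal field or the strut field (C = half-width)."""
    topology = Topology.coerce(topology)
    if topology.is_tpms:
        return evaluate_tpms_field(topology, x, y, z, C, edge_length)
    return strut_lattice_field(topology, x, y, z, C, edge_length)


@dataclass(frozen=True)
class UnitCellSpec:
    """Generative description of one periodic scaffold microstructure.

    ``C`` is the dimensionless level-set constant for TPMS topologies and the
    strut half-width in mm for the strut lattices.
    """

    topology: Topology
    C: float
    edge_length: float = DEFAULT_EDGE_LENGTH
    resolution: int = 64

    def __post_init__(self):
        object.__setattr__(self, "topology", Topology.coerce(self.topology))
        if self.edge_length <= 0:
            raise ValueError("edge_length must be positive")
        if int(self.resolution) < 16 or int(self.resolution) != self.resolution:
            raise ValueError("resolution must be an integer >= 16")
        object.__setattr__(self, "resolution", int(self.resolution))

    def field(self, x, y, z):
        return scaffold_field(self.topology, x, y, z, self.C, self.edge_length)

    def with_resolution(self, resolution: int) -> "UnitCellSpec":
        return replace(self, resolution=resolution)


@dataclass
class VoxelGrid:
    """Regular occupancy grid over the cell; ``True`` marks the solid phase."""

    occupancy: np.ndarray
    voxel_size: float  # mm
    origin: tuple = (0.0, 0.0, 0.0)
    spec: UnitCellSpec | None = field(default=None, repr=False)

    def __post_init__(self):
        self.occupancy = np.asarray(self.occupancy, bool)
        if self.occupancy.ndim != 3:
            raise ValueError("occupancy must be a 3D array")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @property
    def shape(self):
        return self.occupancy.shape

    @property
    def extent(self):
        """Physical edge lengths (mm) along the three axes."""
        return tuple(n * self.voxel_size for n in self.shape)

    @property
    def porosity(self) -> float:
        return float(1.0 - self.occupancy.mean())

    @property
    def solid_fraction(self) -> float:
        return float(self.occupancy.mean())


def voxel_centers(resolution: int, edge_length: float = DEFAULT_EDGE_LENGTH):
    """1-D voxel-center coordinates (mm); sampling at centers keeps the voxel
    phase fraction an unbiased estimator of the continuous one."""
    h = edge_length / resolution
    return (np.arange(resolution) + 0.5) * h


def _center_mesh(resolution, edge_length):
    c = voxel_centers(resolution, edge_length)
    return c[:, None, None], c[None, :, None], c[None, None, :]


def voxelize(spec: UnitCellSpec) -> VoxelGrid:
    """Voxelize a unit cell: ``occupancy = field(voxel center) >= 0``."""
    x, y, z = _center_mesh(spec.resolution, spec.edge_length)
    occ = spec.field(x, y, z) >= 0.0
    return VoxelGrid(occ, spec.edge_length / spec.resolution, spec=spec)


def tile(grid: VoxelGrid, reps: int) -> VoxelGrid:
    """Periodic n x n x n repetition of a unit cell grid."""
    reps = int(reps)
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if reps == 1:
        return VoxelGrid(grid.occupancy.copy(), grid.voxel_size, grid.origin, grid.spec)
    occ = np.tile(grid.occupancy, (reps, reps, reps))
    return VoxelGrid(occ, grid.voxel_size, grid.origin, grid.spec)


class CalibrationError(ValueError):
    """Raised when a target porosity is unreachable for a topology."""


def _base_scalar(topology, resolution, edge_length):
    """Scalar whose comparison with the parameter gives the phase split.

    TPMS: solid = {U >= C}, porosity(C) = mean(U < C), increasing in C.
    Struts: solid = {D <= w}, porosity(w) = mean(D > w), decreasing in w.
    """
    topology = Topology.coerce(topology)
    x, y, z = _center_mesh(resolution, edge_length)
    if topology.is_tpms:
        return evaluate_tpms_field(topology, x, y, z, 0.0, edge_length), True
    return strut_skeleton_distance(topology, x, y, z, edge_length), False


def calibrate_levelset(
    topology,
    target_porosity: float,
    resolution: int = 64,
    edge_length: float = DEFAULT_EDGE_LENGTH,
    tol: float = 1e-3,
    max_iter: int = 60,
) -> float:
    """Find the level-set constant (or strut half-width) for a target porosity.

    Bisection on the monotone voxel-porosity curve; the nodal field is sampled
    once and reused, so each iteration is a single threshold count.

    Raises
    ------
    CalibrationError
        If the target lies outside the porosity interval reachable within the
        parameter's valid range (the message names the reachable interval).
    """
    if not 0.05 < target_porosity < 0.95:
        raise CalibrationError(
            f"target porosity must lie in (0.05, 0.95); got {target_porosity}"
        )
    topology = Topology.coerce(topology)
    base, increasing = _base_scalar(topology, resolution, edge_length)

    if increasing:  # TPMS: parameter is C
        lo, hi = float(base.min()) - 1e-9, float(base.max()) + 1e-9
        porosity_of = lambda c: float(np.mean(base < c))
    else:  # strut lattice: parameter is half-width
        eps = edge_length / resolution * 1e-6
        lo, hi = eps, edge_length / 2.0 - eps
        porosity_of = lambda w: float(np.mean(base > w))

    p_lo, p_hi = porosity_of(lo), porosity_of(hi)
    p_min, p_max = min(p_lo, p_hi), max(p_lo, p_hi)
    if not p_min <= target_porosity <= p_max:
        raise CalibrationError(
            f"target porosity {target_porosity} unreachable for "
            f"{topology.value}; achievable interval is "
            f"[{p_min:.4f}, {p_max:.4f}] at resolution {resolution}"
        )

    # The voxel porosity is a step function of the parameter (axis-aligned
    # strut lattices can jump by whole voxel rows), so track the best
    # parameter seen in case the target falls inside a step.
    sign = 1.0 if increasing else -1.0
    best, best_err = 0.5 * (lo + hi), np.inf
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        p = porosity_of(mid)
        err = abs(p - target_porosity)
        if err < best_err:
            best, best_err = mid, err
        if err <= tol:
            return mid
        if sign * (p - target_porosity) < 0:
            lo = mid
        else:
            hi = mid
    return best
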