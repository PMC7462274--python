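"""Analytic validation geometries with closed-form properties.

Every downstream stage (morphometry, homogenization, flow) is checked
against geometries whose porosity, interface area, effective moduli or
permeability follow from textbook closed forms: laminates (Voigt/Reuss
bounds and the exact series modulus for zero-Poisson phases), spheres
(area, volume), and straight channels (Poiseuille flow).  Permeability
oracles use the superficial-velocity (Darcy) convention, i.e. the flow
rate is divided by the *full* sample cross-section, not the pore area.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .geometry import VoxelGrid, voxel_centers

__all__ = ["FixtureSpec", "Fixture", "make_fixture", "square_duct_shape_factor"]

_KINDS = (
    "full_solid",
    "empty",
    "laminate",
    "sphere",
    "square_channel",
    "circular_channel",
)


def square_duct_shape_factor(n_terms: int = 50) -> float:
    """Flow shape factor c in Q = c * a^4 * dP / (mu * L) for a square duct.

    Classic separation-of-variables series for laminar flow in a square of
    side a; c ~ 0.035144.
    """
    n = np.arange(1, 2 * n_terms, 2)
    series = np.sum(np.tanh(n * np.pi / 2.0) / n**5)
    return (1.0 - 192.0 / np.pi**5 * series) / 12.0


@dataclass(frozen=True)
class FixtureSpec:
    """Parameterized analytic geometry inside an ``edge_length`` cube."""

    kind: str
    edge_length: float = 2.5  # mm
    resolution: int = 64
    volume_fraction: float = 0.5  # laminate solid fraction
    layer_normal: int = 2  # laminate normal axis (0, 1, 2)
    radius: float = 0.5  # mm; sphere / circular_channel
    side: float = 0.5  # mm; square_channel
    E_a: float = 110.0  # GPa, laminate stiff phase
    E_b: float = 1.0e-3  # GPa, laminate soft phase

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}; got {self.kind!r}")
        if self.resolution < 8:
            raise ValueError("resolution too coarse for a fixture")
        L = self.edge_length
        if self.kind == "sphere" and not 0 < 2 * self.radius <= L:
            raise ValueError("sphere must fit inside the cell")
        if self.kind == "circular_channel" and not 0 < 2 * self.radius < L:
            raise ValueError("channel must fit inside the cell")
        if self.kind == "square_channel" and not 0 < self.side < L:
            raise ValueError("channel must fit inside the cell")
        if self.kind == "laminate" and not 0 < self.volume_fraction < 1:
            raise ValueError("laminate volume_fraction must lie in (0, 1)")


@dataclass
class Fixture:
    """A voxelized analytic geometry plus the values it must reproduce.

    Duck-types the continuous-field protocol of ``UnitCellSpec`` (``field``,
    ``resolution``, ``edge_length``) so the iso-surface morphometry path
    applies unchanged.
    """

    fixture_spec: FixtureSpec
    grid: VoxelGrid
    properties: dict
    _field: Callable = field(repr=False, default=None)

    @property
    def resolution(self) -> int:
        return self.fixture_spec.resolution

    @property
    def edge_length(self) -> float:
        return self.fixture_spec.edge_length

    def field(self, x, y, z):
        return self._field(
            np.asarray(x, float), np.asarray(y, float), np.asarray(z, float)
        )

    def with_resolution(self, resolution: int) -> "Fixture":
        return make_fixture(replace(self.fixture_spec, resolution=resolution))


def _closed_forms(s: FixtureSpec) -> dict:
    L = s.edge_length
    V = L**3
    p: dict = {}
    if s.kind == "full_solid":
        p.update(porosity=0.0, surface_area=0.0)
    elif s.kind == "empty":
        p.update(porosity=1.0, surface_area=0.0)
    elif s.kind == "laminate":
        f = s.volume_fraction
        p.update(
            porosity=1.0 - f,
            surface_area=L**2,
            modulus_series=1.0 / (f / s.E_a + (1.0 - f) / s.E_b),
            modulus_voigt=f * s.E_a + (1.0 - f) * s.E_b,
        )
    elif s.kind == "sphere":
        r = s.radius
        p.update(
            porosity=1.0 - (4.0 / 3.0) * np.pi * r**3 / V,
            surface_area=4.0 * np.pi * r**2,
        )
    elif s.kind == "circular_channel":
        r = s.radius
        phi = np.pi * r**2 / L**2
        p.update(
            porosity=phi,
            surface_area=2.0 * np.pi * r * L,
            permeability=phi * r**2 / 8.0,  # mm^2, Hagen-Poiseuille
        )
    elif s.kind == "square_channel":
        a = s.side
        phi = a**2 / L**2
        c = square_duct_shape_factor()
        p.update(
            porosity=phi,
            surface_area=4.0 * a * L,
            permeability=c * a**4 / L**2,  # mm^2
        )
    if "surface_area" in p:
        p["sv_ratio"] = p["surface_area"] / V
    return p


def _field_function(s: FixtureSpec) -> Callable:
    L = s.edge_length
    c = L / 2.0
    if s.kind == "full_solid":
        return lambda x, y, z: np.ones(np.broadcast_shapes(x.shape, y.shape, z.shape))
    if s.kind == "empty":
        return lambda x, y, z: -np.ones(np.broadcast_shapes(x.shape, y.shape, z.shape))
    if s.kind == "laminate":
        axis = s.layer_normal
        cut = s.volume_fraction * L

        def lam(x, y, z):
            coord = (x, y, z)[axis]
            return np.broadcast_to(
                cut - coord, np.broadcast_shapes(x.shape, y.shape, z.shape)
            ).copy()

        return lam
    if s.kind == "sphere":
        r = s.radius
        return lambda x, y, z: r - np.sqrt(
            (x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2
        )
    if s.kind == "circular_channel":
        r = s.radius

        def circ(x, y, z):
            d = np.sqrt((x - c) ** 2 + (y - c) ** 2) - r
            return np.broadcast_to(
                d, np.broadcast_shapes(x.shape, y.shape, z.shape)
            ).copy()

        return circ
    a = s.side  # square_channel

    def sq(x, y, z):
        d = np.maximum(np.abs(x - c), np.abs(y - c)) - a / 2.0
        return np.broadcast_to(
            d, np.broadcast_shapes(x.shape, y.shape, z.shape)
        ).copy()

    return sq


def make_fixture(spec: FixtureSpec) -> Fixture:
    """Voxelize an analytic geometry and attach its closed-form record."""
    fn = _field_function(spec)
    cc = voxel_centers(spec.resolution, spec.edge_length)
    occ = fn(cc[:, None, None], cc[None, :, None], cc[None, None, :]) >= 0.0
    grid = VoxelGrid(occ, spec.edge_length / spec.resolution)
    fx = Fixture(spec, grid, _closed_forms(spec))
    fx._field = fn
    return fx
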