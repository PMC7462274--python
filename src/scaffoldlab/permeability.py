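"""Scaffold permeability: Stokes flow through the void network and Darcy's law.

At the study's inlet velocity (0.1 mm/s) and pore scale the Reynolds number
is ~1e-4, so the laminar flow through the scaffold is creeping flow and the
steady incompressible Stokes equations apply.  They are discretized on a
marker-and-cell (MAC) staggered grid over the void voxels — pressures at
cell centers, velocity components on faces — with a uniform normal velocity
at the inlet, zero gauge pressure at the outlet, and no-slip on the solid
surface and the four lateral walls.  Short fully-open buffer layers are
prepended and appended so the plug inlet profile can develop; the pressure
drop is read between the scaffold's entry and exit planes.  The symmetric
indefinite saddle-point system is solved with MINRES under a diagonal
block preconditioner.

Darcy's law ``k = Q mu L / (A dP)`` converts the solve into a permeability;
the Kozeny-Carman closed form ``k* = phi^3 / (2 s^2)`` gives the empirical
counterpart from porosity and specific surface alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.ndimage import label as cc_label
from scipy.sparse.linalg import LinearOperator, minres

from .geometry import VoxelGrid

__all__ = [
    "FluidSpec",
    "FlowResult",
    "PermeabilityResult",
    "solve_flow",
    "darcy_permeability",
    "kozeny_carman",
    "fit_permeability_model",
    "PermeabilityFit",
    "BlockedDomainError",
]

MM = 1.0e-3  # mm -> m


class BlockedDomainError(RuntimeError):
    """No percolating void path between the inlet and outlet faces."""


@dataclass(frozen=True)
class FluidSpec:
    """Incompressible working fluid and inlet condition (water defaults)."""

    viscosity: float = 1.0e-3  # Pa s
    density: float = 998.2  # kg/m^3 (unused in creeping flow; kept for record)
    inlet_velocity: float = 0.1  # mm/s

    def __post_init__(self):
        if min(self.viscosity, self.density, self.inlet_velocity) <= 0:
            raise ValueError("fluid constants must be positive")


@dataclass
class FlowResult:
    """Stokes solution on the tiled void domain (SI units).

    Velocity components live on the staggered faces of the internal grid;
    ``pressure`` is cell-centered with NaN in solid cells.  ``dp`` is the
    area-averaged pressure at the scaffold entry plane minus the exit plane.
    """

    pressure: np.ndarray
    velocity: tuple  # (u, v, w) staggered arrays, m/s
    dp: float  # Pa
    q: float  # m^3/s
    dp_gradient: float  # Pa, interior pressure gradient scaled to the length
    length: float  # m, scaffold extent along the flow axis
    area: float  # m^2, full cross-section
    h: float  # m, voxel size
    porosity: float
    viscosity: float  # Pa s
    n_buffer: int
    iterations: int


def _percolating_fluid(fluid: np.ndarray) -> np.ndarray:
    """Keep void cells connected to the inlet; demand outlet connectivity."""
    labels, _ = cc_label(fluid)
    inlet_labels = np.unique(labels[:, :, 0])
    outlet_labels = np.unique(labels[:, :, -1])
    inlet_labels = inlet_labels[inlet_labels > 0]
    through = np.intersect1d(inlet_labels, np.unique(outlet_labels[outlet_labels > 0]))
    if through.size == 0:
        raise BlockedDomainError(
            "void phase does not percolate between inlet and outlet faces"
        )
    return np.isin(labels, inlet_labels)


def solve_flow(
    grid: VoxelGrid,
    fluid: FluidSpec | None = None,
    n_buffer: int = 4,
    lateral_bc="noslip",
    rtol: float = 1e-9,
    maxiter: int = 60000,
) -> FlowResult:
    """Solve steady Stokes flow through the void domain of a voxel grid.

    Flow is driven along the third axis.  ``lateral_bc`` is "noslip" (the
    walled flow channel of the permeability protocol) or "slip" (symmetry
    planes, useful for analytic profile checks), or a pair giving the
    condition per lateral axis, e.g. ``("noslip", "slip")``.

    Raises
    ------
    BlockedDomainError
        If no void path percolates from inlet to outlet.
    RuntimeError
        If MINRES stalls before the requested residual.
    """
    if fluid is None:
        fluid = FluidSpec()
    if isinstance(lateral_bc, str):
        lateral_bc = (lateral_bc, lateral_bc)
    if any(bc not in ("noslip", "slip") for bc in lateral_bc):
        raise ValueError("lateral_bc entries must be 'noslip' or 'slip'")
    mu = fluid.viscosity
    v_in = fluid.inlet_velocity * MM
    h = grid.voxel_size * MM
    nx, ny, nz = grid.shape
    nb = int(n_buffer)

    solid = grid.occupancy
    fluid_mask = np.ones((nx, ny, nz + 2 * nb), bool)
    fluid_mask[:, :, nb : nb + nz] = ~solid
    fluid_mask = _percolating_fluid(fluid_mask)
    nzt = nz + 2 * nb

    pid = -np.ones(fluid_mask.shape, np.int64)
    pid[fluid_mask] = np.arange(int(fluid_mask.sum()))
    n_p = int(fluid_mask.sum())

    # --- face bookkeeping -------------------------------------------------
    # A face is an unknown iff every adjacent cell is fluid and it is not a
    # Dirichlet face (domain side walls; the inlet plane for w).
    def face_ids(axis):
        shape = [nx, ny, nzt]
        shape[axis] += 1
        unknown = np.zeros(shape, bool)
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(0, -1)
        sl_hi[axis] = slice(1, None)
        both_fluid = fluid_mask[tuple(sl_lo)] & fluid_mask[tuple(sl_hi)]
        mid = [slice(None)] * 3
        mid[axis] = slice(1, -1)
        unknown[tuple(mid)] = both_fluid
        if axis == 2:  # outlet faces are unknowns (ghost pressure = 0)
            unknown[:, :, -1] = fluid_mask[:, :, -1]
            unknown[:, :, 0] = False  # inlet is Dirichlet v_in
        ids = -np.ones(shape, np.int64)
        ids[unknown] = np.arange(int(unknown.sum()))
        return ids, unknown

    u_ids, u_unk = face_ids(0)
    v_ids, v_unk = face_ids(1)
    w_ids, w_unk = face_ids(2)
    n_u, n_v, n_w = int(u_unk.sum()), int(v_unk.sum()), int(w_unk.sum())
    n_vel = n_u + n_v + n_w
    offs = (0, n_u, n_u + n_v)

    rows_A, cols_A, vals_A = [], [], []
    rows_G, cols_G, vals_G = [], [], []
    b = np.zeros(n_vel + n_p)

    wall_coeff = tuple(0.0 if bc == "slip" else 2.0 for bc in lateral_bc)

    for axis, (ids, unk) in enumerate(((u_ids, u_unk), (v_ids, v_unk), (w_ids, w_unk))):
        off = offs[axis]
        idx = np.argwhere(unk)
        fid = ids[unk] + off
        m = len(fid)
        diag = np.zeros(m)

        for nb_axis in range(3):
            for sgn in (-1, +1):
                nidx = idx.copy()
                nidx[:, nb_axis] += sgn
                inside = (nidx[:, nb_axis] >= 0) & (
                    nidx[:, nb_axis] < ids.shape[nb_axis]
                )
                nid = np.full(m, -1, np.int64)
                nid[inside] = ids[tuple(nidx[inside].T)]
                is_unk = nid >= 0
                contrib = np.zeros(m)

                if nb_axis == axis:
                    # Neighbor faces along the flow component's own axis sit
                    # on the lattice at distance h; Dirichlet ones carry value
                    # 0 (walls/solid) or the inlet velocity.  Beyond the
                    # outlet plane a zero-gradient ghost contributes nothing.
                    contrib[inside] = 1.0
                    if axis == 2 and sgn == -1:
                        at_inlet = inside & (nidx[:, 2] == 0) & ~is_unk
                        b[fid[at_inlet]] += mu * h * v_in
                else:
                    # Tangential neighbors: solid surfaces and no-slip walls
                    # run halfway between face rows -> mirror ghost (+2);
                    # slip walls and the outlet plane -> zero gradient (0).
                    contrib[is_unk] = 1.0
                    contrib[inside & ~is_unk] = 2.0
                    outside = ~inside
                    if nb_axis == 2:
                        contrib[outside & (sgn < 0)] = 2.0  # plug inlet plane
                        contrib[outside & (sgn > 0)] = 0.0
                    else:
                        contrib[outside] = wall_coeff[nb_axis]
                diag += contrib
                take = is_unk & (contrib > 0)
                rows_A.append(fid[take])
                cols_A.append(nid[take] + off)
                vals_A.append(-np.ones(int(take.sum())))

        rows_A.append(fid)
        cols_A.append(fid)
        vals_A.append(diag)

        # pressure gradient: + h^2 (p_hi - p_lo)
        lo = idx.copy()
        lo[:, axis] -= 1
        p_lo = np.full(m, -1, np.int64)
        ok_lo = lo[:, axis] >= 0
        p_lo[ok_lo] = pid[tuple(lo[ok_lo].T)]
        p_hi = np.full(m, -1, np.int64)
        ok_hi = idx[:, axis] <= pid.shape[axis] - 1
        p_hi[ok_hi] = pid[tuple(idx[ok_hi].T)]
        for pidx, sgn in ((p_hi, +1.0), (p_lo, -1.0)):
            take = pidx >= 0
            rows_G.append(fid[take])
            cols_G.append(pidx[take])
            vals_G.append(np.full(int(take.sum()), sgn))

    # Scaled pressure unknown p~ = (h / mu) p balances the saddle-point
    # blocks (all entries ~ mu h), which keeps the continuity residual from
    # being under-weighted in the MINRES stopping criterion.
    A = sp.coo_matrix(
        (
            mu * h * np.concatenate(vals_A),
            (np.concatenate(rows_A), np.concatenate(cols_A)),
        ),
        shape=(n_vel, n_vel),
    ).tocsr()
    G = sp.coo_matrix(
        (
            mu * h * np.concatenate(vals_G),
            (np.concatenate(rows_G), np.concatenate(cols_G)),
        ),
        shape=(n_vel, n_p),
    ).tocsr()

    # continuity rhs: signed Dirichlet outflow; inlet contributes -mu h v_in
    cells_k0 = pid[:, :, 0]
    b[n_vel + cells_k0[cells_k0 >= 0]] = -mu * h * v_in

    K = sp.bmat([[A, G], [G.T, None]], format="csr")
    dA = A.diagonal()
    dP = np.full(n_p, mu * h)
    dinv = 1.0 / np.concatenate([dA, dP])
    M = LinearOperator(K.shape, matvec=lambda r: dinv * r, dtype=float)

    it = [0]

    def count(_):
        it[0] += 1

    x, info = minres(K, b, M=M, rtol=rtol, maxiter=maxiter, callback=count)
    if info != 0:
        res = np.linalg.norm(K @ x - b) / np.linalg.norm(b)
        raise RuntimeError(
            f"Stokes solver did not converge in {maxiter} iterations "
            f"(relative residual {res:.2e})"
        )

    u = np.zeros(u_ids.shape)
    u[u_unk] = x[: n_u]
    v = np.zeros(v_ids.shape)
    v[v_unk] = x[n_u : n_u + n_v]
    w = np.zeros(w_ids.shape)
    w[w_unk] = x[n_u + n_v : n_vel]
    w[:, :, 0][fluid_mask[:, :, 0]] = v_in
    p = np.full(fluid_mask.shape, np.nan)
    p[fluid_mask] = x[n_vel:] * (mu / h)  # undo the pressure scaling

    # Pressure drop between the scaffold entry and exit planes: the layer
    # means adjacent to each plane are interpolated onto it, so the drop
    # spans exactly the scaffold length.  A second estimate fits the
    # interior layer-mean gradient, free of entrance/contraction losses.
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        layer_mean = np.nanmean(p, axis=(0, 1))
    if nb > 0:
        p_in = 0.5 * (layer_mean[nb - 1] + layer_mean[nb])
        p_out = 0.5 * (layer_mean[nb + nz - 1] + layer_mean[nb + nz])
    else:
        p_in, p_out = layer_mean[0], layer_mean[-1]
    dp = float(p_in - p_out)
    lo, hi = nb + nz // 4, nb + max(nz // 4 + 2, (3 * nz) // 4)
    hi = min(hi, nb + nz)
    kk = np.arange(lo, hi)
    good = np.isfinite(layer_mean[lo:hi])
    if good.sum() >= 2:
        slope = np.polyfit(kk[good], layer_mean[lo:hi][good], 1)[0]
        dp_gradient = float(-slope * nz)
    else:
        dp_gradient = dp

    area = nx * ny * h * h
    return FlowResult(
        pressure=p,
        velocity=(u, v, w),
        dp=dp,
        dp_gradient=dp_gradient,
        q=v_in * area,
        length=nz * h,
        area=area,
        h=h,
        porosity=grid.porosity,
        viscosity=mu,
        n_buffer=nb,
        iterations=it[0],
    )


def darcy_permeability(flow: FlowResult, dp_method: str = "planes") -> float:
    """Darcy permeability k = Q mu L / (A dP) in m^2.

    ``dp_method`` "planes" uses the entry/exit plane averages (the protocol
    pressure drop, entrance losses included); "gradient" uses the interior
    pressure gradient, appropriate when comparing against fully-developed
    closed forms.
    """
    if dp_method not in ("planes", "gradient"):
        raise ValueError("dp_method must be 'planes' or 'gradient'")
    dp = flow.dp if dp_method == "planes" else flow.dp_gradient
    if dp <= 0:
        raise ValueError(f"pressure drop must be positive; got {dp}")
    return flow.q * flow.viscosity * flow.length / (flow.area * dp)


def kozeny_carman(porosity: float, s: float) -> float:
    """Kozeny-Carman permeability ``k* = phi^3 / (2 s^2)``.

    ``s`` is the specific surface (inner pore area / total volume) in 1/m;
    the result is in m^2.
    """
    if s <= 0:
        raise ValueError("specific surface s must be positive")
    if not 0.0 <= porosity <= 1.0:
        raise ValueError("porosity must lie in [0, 1]")
    return porosity**3 / (2.0 * s * s)


@dataclass
class PermeabilityResult:
    """Darcy permeability with its flow diagnostics and the Kozeny-Carman
    counterpart (all SI)."""

    k: float  # m^2
    k_star: float  # m^2
    q: float  # m^3/s
    dp: float  # Pa
    length: float  # m
    area: float  # m^2
    porosity: float


@dataclass
class PermeabilityFit:
    """One fitted permeability-porosity relation."""

    family: str  # exponential | quadratic | power
    params: tuple
    r_squared: float
    alternatives: dict = field(default_factory=dict)

    def __call__(self, p):
        p = np.asarray(p, float)
        a = self.params
        if self.family == "exponential":
            return a[0] * np.exp(a[1] * p)
        if self.family == "power":
            return a[0] * p ** a[1]
        return a[0] * p**2 + a[1] * p + a[2]

    def summary(self) -> str:
        a = self.params
        if self.family == "exponential":
            form = f"k = {a[0]:.4g} exp({a[1]:.3f} phi)"
        elif self.family == "power":
            form = f"k = {a[0]:.4g} phi^{a[1]:.3f}"
        else:
            form = f"k = {a[0]:.4g} phi^2 {a[1]:+.4g} phi {a[2]:+.4g}"
        return f"{form}  (R^2 = {self.r_squared:.4f})"


def _r2(y, pred):
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0
    return 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot


def fit_permeability_model(points, family: str = "auto") -> PermeabilityFit:
    """Fit k(phi) within a family: exponential a*e^(b phi), power a*phi^b,
    quadratic, or "auto" (all three, highest R^2 on the k scale wins).

    Exponential and power families are fitted log-linearly, mirroring the
    regression practice for permeability data; they require positive k.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 4:
        raise ValueError("need at least 4 (porosity, k) points")
    phi, k = pts[:, 0], pts[:, 1]

    def fit_one(fam):
        if fam in ("exponential", "power"):
            if np.any(k <= 0) or (fam == "power" and np.any(phi <= 0)):
                raise ValueError(f"{fam} fit requires positive data")
            xs = phi if fam == "exponential" else np.log(phi)
            slope, icept = np.polyfit(xs, np.log(k), 1)
            params = (float(np.exp(icept)), float(slope))
        elif fam == "quadratic":
            params = tuple(float(c) for c in np.polyfit(phi, k, 2))
        else:
            raise ValueError(f"unknown family {fam!r}")
        fit = PermeabilityFit(fam, params, 0.0)
        fit.r_squared = _r2(k, fit(phi))
        return fit

    if family != "auto":
        return fit_one(family)
    fits = {}
    for fam in ("exponential", "quadratic", "power"):
        try:
            fits[fam] = fit_one(fam)
        except ValueError:
            continue
    if not fits:
        raise ValueError("no family could be fitted")
    best = max(fits.values(), key=lambda f: f.r_squared)
    best.alternatives = {f.family: f for f in fits.values() if f is not best}
    return best
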