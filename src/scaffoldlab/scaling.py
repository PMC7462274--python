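"""Gibson-Ashby scaling of scaffold stiffness and shear-compression relations.

Cellular solids obey ``E* = C1 * rho**n + E0`` where ``E*`` is the modulus
relative to the base material and ``rho = 1 - porosity`` the relative
density.  The exponent diagnoses the strut deformation mode: n near 2 for
bending-dominated architectures, near 1 for stretching-dominated ones.  The
accompanying linear regression of relative shear on relative compressive
modulus quantifies how much faster the shear stiffness responds to a
porosity change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import linregress

__all__ = [
    "GibsonAshbyFit",
    "LinearRelation",
    "fit_gibson_ashby",
    "classify_mode",
    "fit_linear_relation",
    "MODE_THRESHOLD",
]

# Deformation-mode cut on the exponent: published stretching exponents for
# these lattices top out near 1.5 and bending ones start near 1.9, so any
# threshold between works; 1.7 splits the gap.
MODE_THRESHOLD = 1.7

# Accepted prefactor range for cellular solids.
C1_RANGE = (0.1, 4.0)


@dataclass
class GibsonAshbyFit:
    """Fitted ``E* = C1 * rho**n + E0`` with mode classification."""

    C1: float
    n: float
    E0: float
    r_squared: float
    mode: str  # "bending" | "stretching"

    def __call__(self, rho):
        return self.C1 * np.asarray(rho, float) ** self.n + self.E0

    @property
    def c1_in_range(self) -> bool:
        return C1_RANGE[0] < self.C1 < C1_RANGE[1]

    def summary(self) -> str:
        return (
            f"E* = {self.C1:.3f} rho^{self.n:.3f} {self.E0:+.4f}"
            f"  (R^2 = {self.r_squared:.4f}, {self.mode})"
        )


@dataclass
class LinearRelation:
    """Ordinary least squares ``y = slope * x + intercept``."""

    slope: float
    intercept: float
    r_squared: float

    def __call__(self, x):
        return self.slope * np.asarray(x, float) + self.intercept

    def summary(self) -> str:
        return (
            f"G_s = {self.slope:.2f} E_c {self.intercept:+.2f}"
            f"  (R^2 = {self.r_squared:.4f})"
        )


def classify_mode(n: float) -> str:
    """Deformation mode from the Gibson-Ashby exponent (cut at 1.7)."""
    if n <= 0:
        raise ValueError("exponent must be positive")
    return "bending" if n >= MODE_THRESHOLD else "stretching"


def fit_gibson_ashby(points) -> GibsonAshbyFit:
    """Fit the three-parameter power law to (rho, E*) points.

    Deterministic multi-start nonlinear least squares: for each starting
    exponent in {1, 1.5, 2, 2.5} the problem is solved from (C1, n, E0) =
    (1, n0, 0) and the lowest-residual solution is kept.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 4:
        raise ValueError("need at least 4 (rho, E*) points")
    rho, e = pts[:, 0], pts[:, 1]
    if np.any((rho <= 0) | (rho >= 1)):
        raise ValueError("relative density must lie in (0, 1)")

    def resid(theta):
        c1, n, e0 = theta
        return c1 * rho**n + e0 - e

    best = None
    for n0 in (1.0, 1.5, 2.0, 2.5):
        try:
            sol = least_squares(
                resid,
                x0=(1.0, n0, 0.0),
                bounds=([1e-8, 0.05, -np.inf], [np.inf, 10.0, np.inf]),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
        except Exception:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise RuntimeError("Gibson-Ashby fit did not converge from any start")
    c1, n, e0 = best.x
    pred = c1 * rho**n + e0
    ss_tot = float(np.sum((e - e.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - float(np.sum((e - pred) ** 2)) / ss_tot
    return GibsonAshbyFit(float(c1), float(n), float(e0), r2, classify_mode(n))


def fit_linear_relation(points) -> LinearRelation:
    """OLS of relative shear modulus on relative compressive modulus."""
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (E_c, G_s) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0.0:
        raise ValueError("zero variance in the compressive modulus")
    res = linregress(x, y)
    return LinearRelation(float(res.slope), float(res.intercept), float(res.rvalue**2))
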