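import numpy as np
import pytest

from scaffoldlab.fixtures import FixtureSpec, make_fixture
from scaffoldlab.geometry import VoxelGrid
from scaffoldlab.permeability import (
    BlockedDomainError,
    FlowResult,
    FluidSpec,
    darcy_permeability,
    fit_permeability_model,
    kozeny_carman,
    solve_flow,
)

L_MM = 2.5


def fabricated_flow(dp=1.0, v=1.0e-4, length=1.0e-2, area=1.0e-4):
    return FlowResult(
        pressure=np.zeros((2, 2, 2)),
        velocity=(None, None, None),
        dp=dp,
        dp_gradient=dp,
        q=v * area,
        length=length,
        area=area,
        h=1e-4,
        porosity=0.5,
        viscosity=1.0e-3,
        n_buffer=0,
        iterations=0,
    )


class TestDarcy:
    def test_direct_substitution(self):
        # v = 0.1 mm/s, mu = 1e-3 Pa s, L = 10 mm, dP = 1 Pa -> 1e-9 m^2
        assert darcy_permeability(fabricated_flow()) == pytest.approx(1.0e-9)

    def test_doubling_pressure_drop_halves_k(self):
        k1 = darcy_permeability(fabricated_flow(dp=1.0))
        k2 = darcy_permeability(fabricated_flow(dp=2.0))
        assert k2 == pytest.approx(k1 / 2.0)

    def test_nonpositive_pressure_drop_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            darcy_permeability(fabricated_flow(dp=0.0))


class TestKozenyCarman:
    def test_direct_substitution(self):
        # phi = 0.5, s = 1/mm = 1000/m -> 0.125 / 2e6 = 6.25e-8 m^2
        assert kozeny_carman(0.5, 1000.0) == pytest.approx(6.25e-8)

    def test_zero_porosity(self):
        assert kozeny_carman(0.0, 500.0) == 0.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            kozeny_carman(0.5, 0.0)
        with pytest.raises(ValueError):
            kozeny_carman(1.5, 100.0)


class TestStokesSolver:
    def test_fully_solid_domain_is_blocked(self):
        grid = VoxelGrid(np.ones((12, 12, 12), bool), L_MM / 12)
        with pytest.raises(BlockedDomainError):
            solve_flow(grid)

    def test_walled_off_domain_is_blocked(self):
        occ = np.zeros((12, 12, 12), bool)
        occ[:, :, 6] = True  # solid wall across the flow axis
        with pytest.raises(BlockedDomainError):
            solve_flow(VoxelGrid(occ, L_MM / 12))

    def test_mass_conservation(self):
        fx = make_fixture(FixtureSpec("circular_channel", radius=0.8, resolution=24))
        fl = solve_flow(fx.grid, rtol=1e-12)
        _, _, w = fl.velocity
        flux = w.sum(axis=(0, 1)) * fl.h**2
        np.testing.assert_allclose(flux, fl.q, rtol=1e-5)

    def test_plane_poiseuille_profile(self):
        # no-slip walls across x, symmetry in y: the classic parabola
        nx, ny, nz = 64, 8, 64
        grid = VoxelGrid(np.zeros((nx, ny, nz), bool), L_MM / 64)
        fl = solve_flow(grid, lateral_bc=("noslip", "slip"), rtol=1e-10)
        _, _, w = fl.velocity
        prof = w[:, ny // 2, fl.n_buffer + nz - 2]
        W = nx * fl.h
        x = (np.arange(nx) + 0.5) * fl.h
        v_in = FluidSpec().inlet_velocity * 1e-3
        exact = 6.0 * v_in * (x / W) * (1.0 - x / W)
        assert np.max(np.abs(prof - exact)) / exact.max() < 0.02

    def test_circular_channel_hagen_poiseuille(self):
        fx = make_fixture(FixtureSpec("circular_channel", radius=0.8, resolution=48))
        fl = solve_flow(fx.grid, rtol=1e-10)
        k = darcy_permeability(fl, dp_method="gradient")
        k_exact = fx.properties["permeability"] * 1e-6  # mm^2 -> m^2
        assert k == pytest.approx(k_exact, rel=0.05)

    def test_square_channel_reference(self):
        # side chosen as a whole number of voxels so the duct walls fall on
        # voxel boundaries and the staircase does not narrow the channel
        fx = make_fixture(FixtureSpec("square_channel", side=1.25, resolution=48))
        fl = solve_flow(fx.grid, rtol=1e-10)
        k = darcy_permeability(fl, dp_method="gradient")
        k_exact = fx.properties["permeability"] * 1e-6
        assert k == pytest.approx(k_exact, rel=0.05)


class TestPermeabilityFits:
    def test_exponential_recovery(self):
        phi = np.linspace(0.3, 0.7, 5)
        k = 0.01 * np.exp(5.0 * phi)
        fit = fit_permeability_model(np.column_stack([phi, k]), "exponential")
        assert fit.params == pytest.approx((0.01, 5.0), rel=1e-10)
        assert fit.r_squared == pytest.approx(1.0)

    def test_power_recovery(self):
        phi = np.linspace(0.3, 0.7, 6)
        k = 1.25 * phi**4.2
        fit = fit_permeability_model(np.column_stack([phi, k]), "power")
        assert fit.params == pytest.approx((1.25, 4.2), rel=1e-10)

    def test_quadratic_recovery(self):
        phi = np.linspace(0.2, 0.8, 5)
        k = 0.89 * phi**2 - 0.48 * phi + 0.07
        fit = fit_permeability_model(np.column_stack([phi, k]), "quadratic")
        assert fit.params == pytest.approx((0.89, -0.48, 0.07), abs=1e-10)

    def test_auto_selects_generating_family(self):
        phi = np.linspace(0.3, 0.7, 5)
        k = 0.01 * np.exp(5.55 * phi)
        fit = fit_permeability_model(np.column_stack([phi, k]), "auto")
        assert fit.family == "exponential"
        assert fit.params[1] == pytest.approx(5.55, rel=1e-8)
        assert set(fit.alternatives) <= {"quadratic", "power"}

    def test_log_families_require_positive_k(self):
        pts = [(0.3, 1.0), (0.4, -0.1), (0.5, 1.0), (0.6, 2.0)]
        with pytest.raises(ValueError, match="positive"):
            fit_permeability_model(pts, "exponential")

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_permeability_model([(0.3, 1.0), (0.5, 2.0)], "quadratic")
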