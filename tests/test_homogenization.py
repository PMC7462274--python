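import numpy as np
import pytest

from scaffoldlab.fixtures import FixtureSpec, make_fixture
from scaffoldlab.geometry import UnitCellSpec, VoxelGrid, voxelize
from scaffoldlab.homogenization import (
    ConvergenceStudy,
    ElasticityTensor,
    PhaseMaterials,
    convergence_study,
    extract_engineering_moduli,
    homogenize,
)

from conftest import spec_at


def cubic_tensor(C11, C12, C44):
    C = np.zeros((6, 6))
    C[:3, :3] = C12
    np.fill_diagonal(C[:3, :3], C11)
    C[3, 3] = C[4, 4] = C[5, 5] = C44
    return ElasticityTensor(C, 0.0)


class TestMaterials:
    def test_defaults_are_titanium_and_soft_void(self):
        m = PhaseMaterials()
        assert m.E_solid == 110.0 and m.nu_solid == 0.34
        assert m.E_void == pytest.approx(1.0e-3) and m.nu_void == 0.45
        assert m.G_solid == pytest.approx(41.045, abs=5e-3)

    def test_invalid_phases_rejected(self):
        with pytest.raises(ValueError):
            PhaseMaterials(E_solid=-1.0)
        with pytest.raises(ValueError):
            PhaseMaterials(nu_void=0.6)


class TestHomogenize:
    def test_full_solid_reproduces_base_material(self):
        grid = VoxelGrid(np.ones((16, 16, 16), bool), 2.5 / 16)
        mod = extract_engineering_moduli(homogenize(grid))
        assert mod.E_c == pytest.approx(1.0, abs=1e-6)
        assert mod.G_s == pytest.approx(1.0, abs=1e-6)
        assert mod.E_e == pytest.approx(110.0, rel=1e-6)

    def test_empty_solid_rejected(self):
        grid = VoxelGrid(np.zeros((16, 16, 16), bool), 2.5 / 16)
        with pytest.raises(ValueError, match="empty"):
            homogenize(grid)

    def test_laminate_series_modulus(self):
        # nu = 0 phases: the axial response across layers is the exact
        # harmonic (series) closed form
        mats = PhaseMaterials(E_solid=110.0, nu_solid=0.0, E_void=1e-3, nu_void=0.0)
        fx = make_fixture(FixtureSpec("laminate", volume_fraction=0.5, resolution=16))
        T = homogenize(fx.grid, mats, load_cases="full", rtol=1e-10)
        assert T.stiffness[2, 2] == pytest.approx(
            fx.properties["modulus_series"], rel=0.01
        )
        assert T.stiffness[0, 0] == pytest.approx(
            fx.properties["modulus_voigt"], rel=0.01
        )

    def test_homogeneous_shear_consistency(self):
        # G = E / (2 (1 + nu)) must come out of the shear load case
        mats = PhaseMaterials(E_solid=80.0, nu_solid=0.25, E_void=80.0, nu_void=0.25)
        grid = VoxelGrid(np.ones((16, 16, 16), bool), 2.5 / 16)
        T = homogenize(grid, mats)
        assert T.C44 == pytest.approx(80.0 / (2 * 1.25), rel=1e-8)

    def test_voigt_reuss_bounds_on_gyroid(self):
        spec = spec_at("gyroid", 0.5, 24)
        mats = PhaseMaterials()
        T = homogenize(spec, mats, rtol=1e-6)
        mod = extract_engineering_moduli(T, mats, check_cubic=False)
        vf = voxelize(spec).solid_fraction
        reuss = 1.0 / (vf / mats.E_solid + (1 - vf) / mats.E_void)
        voigt = vf * mats.E_solid + (1 - vf) * mats.E_void
        assert reuss <= mod.E_e <= voigt

    def test_cubic_residual_small_for_tpms(self):
        T = homogenize(spec_at("schwarz-p", 0.5, 24), rtol=1e-6)
        assert T.cubic_residual < 0.02

    def test_load_case_magnitude_irrelevant(self):
        # linear elasticity: stiffness columns are strain-magnitude free
        T1 = homogenize(spec_at("gyroid", 0.5, 16), rtol=1e-8)
        T2 = homogenize(spec_at("gyroid", 0.5, 16), rtol=1e-8)
        assert T1.C11 == pytest.approx(T2.C11)  # determinism doubles as check


class TestExtractModuli:
    def test_isotropic_round_trip(self):
        E, nu = 110.0, 0.34
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        T = cubic_tensor(lam + 2 * mu, lam, mu)
        mod = extract_engineering_moduli(T)
        assert mod.E_e == pytest.approx(E, rel=1e-12)
        assert mod.G_e == pytest.approx(mu, rel=1e-12)
        assert (mod.E_c, mod.G_s) == pytest.approx((1.0, 1.0))

    def test_hand_computed_cubic_formula(self):
        mod = extract_engineering_moduli(cubic_tensor(2.0, 1.0, 1.0))
        assert mod.E_e == pytest.approx(4.0 / 3.0, rel=1e-12)
        assert mod.G_e == pytest.approx(1.0)

    def test_degenerate_limit(self):
        mod = extract_engineering_moduli(cubic_tensor(2.0, 2.0, 1.0))
        assert mod.E_e == pytest.approx(0.0, abs=1e-12)

    def test_non_positive_definite_rejected(self):
        with pytest.raises(ValueError):
            extract_engineering_moduli(cubic_tensor(-1.0, 0.5, 1.0))

    def test_non_cubic_tensor_flagged(self):
        C = cubic_tensor(2.0, 1.0, 1.0).stiffness.copy()
        C[0, 0] = 4.0  # break cubic symmetry
        T = ElasticityTensor(C, cubic_residual=0.5)
        with pytest.raises(ValueError, match="cubic"):
            extract_engineering_moduli(T, check_cubic=True)


class TestConvergenceStudy:
    def test_full_solid_converges_immediately(self):
        fx = make_fixture(FixtureSpec("full_solid", resolution=16))
        spec = UnitCellSpec("gyroid", -10.0, resolution=16)  # C=-10: all solid
        study = convergence_study(spec, [16, 32])
        assert isinstance(study, ConvergenceStudy)
        assert study.converged
        assert study.relative_changes[-1] == pytest.approx(0.0, abs=1e-9)
        del fx

    def test_single_resolution_rejected(self):
        spec = UnitCellSpec("gyroid", 0.0, resolution=16)
        with pytest.raises(ValueError, match="increasing"):
            convergence_study(spec, [32])
        with pytest.raises(ValueError, match="increasing"):
            convergence_study(spec, [32, 32])
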