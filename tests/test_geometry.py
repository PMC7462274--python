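import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scaffoldlab.geometry import (
    CalibrationError,
    Topology,
    UnitCellSpec,
    calibrate_levelset,
    evaluate_tpms_field,
    scaffold_field,
    strut_lattice_field,
    tile,
    voxelize,
)

from conftest import ALL_TOPOLOGIES, TPMS

L = 2.5


class TestNodalEquations:
    @pytest.mark.parametrize(
        "topology,point,expected",
        [
            ("schwarz-p", (0.0, 0.0, 0.0), 3.0),
            ("gyroid", (0.0, 0.0, 0.0), 0.0),
            # equation coordinates (pi/2, pi/2, pi/2) == physical L/4
            ("diamond", (L / 4, L / 4, L / 4), 1.0),
            ("f-rd", (0.0, 0.0, 0.0), 10.0),
        ],
    )
    def test_reference_point_values(self, topology, point, expected):
        val = evaluate_tpms_field(topology, *point, C=0.0)
        assert val == pytest.approx(expected, abs=1e-12)

    def test_level_set_constant_shifts_field(self):
        assert evaluate_tpms_field("schwarz-p", 0, 0, 0, C=1.25) == pytest.approx(
            1.75
        )

    def test_unknown_topology_rejected(self):
        with pytest.raises(ValueError, match="unknown topology"):
            evaluate_tpms_field("octet", 0, 0, 0)

    def test_strut_topology_rejected_by_tpms_evaluator(self):
        with pytest.raises(ValueError, match="strut lattice"):
            evaluate_tpms_field("cube", 0, 0, 0)

    def test_name_aliases(self):
        assert Topology.coerce("Schwarz_P") is Topology.SCHWARZ_P
        assert Topology.coerce("FRD") is Topology.F_RD


class TestPeriodicity:
    @pytest.mark.parametrize("topology", ALL_TOPOLOGIES)
    def test_field_periodic_across_opposite_faces(self, topology, rng):
        pts = rng.uniform(0.0, L, size=(40, 3))
        C = 0.2 if Topology.coerce(topology).is_tpms else 0.3
        base = scaffold_field(topology, *pts.T, C=C)
        for axis in range(3):
            shift = np.zeros(3)
            shift[axis] = L
            moved = scaffold_field(topology, *(pts + shift).T, C=C)
            np.testing.assert_allclose(moved, base, atol=1e-9)

    @given(
        x=st.floats(0, L),
        y=st.floats(0, L),
        z=st.floats(0, L),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_gyroid_periodicity_property(self, x, y, z):
        a = evaluate_tpms_field("gyroid", x, y, z)
        b = evaluate_tpms_field("gyroid", x + L, y - L, z + 2 * L)
        assert a == pytest.approx(b, abs=1e-9)


class TestStrutLattices:
    def test_cube_edge_midpoint_is_solid(self):
        # cell edges belong to the edge struts for any positive half-width
        assert strut_lattice_field("cube", 0.0, 0.0, L / 2, half_width=0.05) > 0

    def test_cube_body_center_is_void(self):
        assert strut_lattice_field("cube", L / 2, L / 2, L / 2, half_width=0.25) < 0

    def test_fd_cube_face_diagonal_is_solid(self):
        # midpoint of the z=0 face diagonal
        assert strut_lattice_field("fd-cube", L / 4, L / 4, 0.0, half_width=0.1) > 0

    def test_octa_edge_midpoint_is_solid(self):
        # midpoint between the face centers (L/2, L/2, 0) and (L/2, 0, L/2)
        assert strut_lattice_field("octa", L / 2, L / 4, L / 4, half_width=0.1) > 0

    def test_half_width_out_of_range(self):
        with pytest.raises(ValueError, match="half_width"):
            strut_lattice_field("cube", 0, 0, 0, half_width=1.5 * L)

    @pytest.mark.parametrize("topology", ["cube", "fd-cube", "octa"])
    def test_porosity_monotone_decreasing_in_width(self, topology):
        widths = np.linspace(0.08, 1.1, 8)
        porosities = []
        for w in widths:
            spec = UnitCellSpec(topology, w, resolution=32)
            porosities.append(voxelize(spec).porosity)
        assert all(b <= a for a, b in zip(porosities, porosities[1:]))


class TestCalibration:
    @pytest.mark.parametrize("topology", ["schwarz-p", "gyroid"])
    def test_symmetric_topologies_balance_at_zero(self, topology):
        # U(p + half-period shift) = -U, so C = 0 splits the cell in half
        C = calibrate_levelset(topology, 0.5, resolution=64)
        assert abs(C) < 0.02

    def test_diamond_hits_target_within_tolerance(self):
        C = calibrate_levelset("diamond", 0.54, resolution=64, tol=1e-3)
        spec = UnitCellSpec("diamond", C, resolution=64)
        assert 0.539 <= voxelize(spec).porosity <= 0.541

    def test_strut_lattice_calibration(self):
        # axis-aligned struts quantize the voxel porosity in whole rows, so
        # the reachable value sits within about one row of the target
        w = calibrate_levelset("cube", 0.7, resolution=96)
        grid = voxelize(UnitCellSpec("cube", w, resolution=96))
        assert grid.porosity == pytest.approx(0.7, abs=0.01)

    @pytest.mark.parametrize("target", [0.01, 0.99])
    def test_target_outside_supported_interval(self, target):
        with pytest.raises(CalibrationError):
            calibrate_levelset("gyroid", target, resolution=32)

    @pytest.mark.parametrize("topology", TPMS)
    def test_porosity_monotone_increasing_in_C(self, topology):
        spec0 = UnitCellSpec(topology, 0.0, resolution=32)
        lo, hi = -0.8, 0.8
        porosities = [
            voxelize(UnitCellSpec(topology, C, resolution=32)).porosity
            for C in np.linspace(lo, hi, 7)
        ]
        assert all(b >= a for a, b in zip(porosities, porosities[1:]))
        del spec0

    @pytest.mark.parametrize("topology", ["schwarz-p", "gyroid", "diamond"])
    def test_phase_swap_symmetry(self, topology):
        for C in (0.2, 0.5):
            p_plus = voxelize(UnitCellSpec(topology, C, resolution=48)).porosity
            p_minus = voxelize(UnitCellSpec(topology, -C, resolution=48)).porosity
            assert p_plus + p_minus == pytest.approx(1.0, abs=0.01)


class TestVoxelizeAndTile:
    def test_spec_validation(self):
        with pytest.raises(ValueError):
            UnitCellSpec("gyroid", 0.0, edge_length=-1.0)
        with pytest.raises(ValueError):
            UnitCellSpec("gyroid", 0.0, resolution=8)

    def test_schwarz_p_half_porosity_at_C0(self):
        grid = voxelize(UnitCellSpec("schwarz-p", 0.0, resolution=128))
        assert grid.porosity == pytest.approx(0.5, abs=0.005)

    def test_voxel_porosity_converges(self):
        spec = UnitCellSpec("gyroid", 0.3, resolution=64)
        p64 = voxelize(spec).porosity
        p128 = voxelize(spec.with_resolution(128)).porosity
        assert abs(p64 - p128) < 0.005

    def test_tile_identity(self, gyroid_half):
        grid = voxelize(gyroid_half)
        same = tile(grid, 1)
        np.testing.assert_array_equal(same.occupancy, grid.occupancy)
        assert same.voxel_size == grid.voxel_size

    def test_tile_preserves_porosity(self, gyroid_half):
        grid = voxelize(gyroid_half)
        assert tile(grid, 4).porosity == pytest.approx(grid.porosity, abs=1e-12)

    def test_tile_seams_continuous(self, gyroid_half):
        # periodic field: the phase pattern on opposite cell faces matches
        # almost everywhere, so tiling creates no jump at internal seams
        occ = voxelize(gyroid_half).occupancy
        for axis in range(3):
            first = np.take(occ, 0, axis=axis)
            last = np.take(occ, -1, axis=axis)
            assert (first != last).mean() < 0.08

    def test_tile_rejects_bad_reps(self, gyroid_half):
        with pytest.raises(ValueError):
            tile(voxelize(gyroid_half), 0)
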