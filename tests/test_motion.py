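import numpy as np
import pytest

from bronchodose import motion as mot
from bronchodose import synthetic as synth
from bronchodose.dosimetry import DoseStudy
from bronchodose.grids import (
    ScalarVolume,
    StructureMask,
    VoxelGrid,
    resample_volume,
    sphere_mask,
)
from .conftest import random_dose, random_mask


def _dvf(grid, disp, direction=("subsequent", "source")):
    return mot.DeformationField(grid, disp, direction)


class TestRigidTransform:
    def test_orthonormality_enforced(self):
        with pytest.raises(ValueError):
            mot.RigidTransform(rotation=((1, 0, 0), (0, 2, 0), (0, 0, 1)))

    def test_inverse_round_trip(self, rng):
        th = 0.3
        R = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
        )
        t = mot.RigidTransform((3, -2, 5), tuple(map(tuple, R)))
        pts = rng.normal(size=(10, 3)) * 30
        back = t.inverse().apply(t.apply(pts))
        assert np.allclose(back, pts, atol=1e-9)


class TestRigidAlign:
    def test_identity_for_same_mask(self, phantom2mm):
        _, prim, _ = phantom2mm
        tr = mot.rigid_align_masks(prim["CBT"], prim["CBT"])
        assert np.linalg.norm(tr.translation) < 0.01

    def test_recovers_translation(self, phantom2mm):
        ct, prim, _ = phantom2mm
        _, masks1, _ = synth.deform_anatomy(
            ct, {"CBT": prim["CBT"]}, rigid_shift_mm=(3, -2, 5), seed=1
        )
        tr = mot.rigid_align_masks(prim["CBT"], masks1["CBT"])
        assert np.linalg.norm(np.array(tr.translation) - [3, -2, 5]) <= 0.2

    def test_recovers_rotation(self, phantom2mm):
        ct, prim, _ = phantom2mm
        th = np.deg2rad(5)
        R = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
        )
        grid = ct.grid
        pts = grid.centers_mm().reshape(-1, 3)
        disp = (pts @ R) - pts  # maps subsequent x to source R⁻¹x
        _, masks1, _ = synth.deform_anatomy(
            ct, {"CBT": prim["CBT"]}, displacement=disp.reshape(*grid.dims, 3)
        )
        tr = mot.rigid_align_masks(prim["CBT"], masks1["CBT"])
        angle = np.rad2deg(
            np.arccos(np.clip((np.trace(tr.matrix) - 1) / 2, -1, 1))
        )
        assert abs(angle - 5.0) <= 0.5

    def test_tiny_mask_rejected(self, unit_grid):
        m = StructureMask(unit_grid, np.zeros(unit_grid.dims, bool))
        m.membership[5, 5, 5] = True
        with pytest.raises(ValueError):
            mot.rigid_align_masks(m, m)


class TestResidualShift:
    def test_identical_transforms_zero(self):
        t = mot.RigidTransform((1, 2, 3))
        comps, norm = mot.residual_shift(t, t)
        assert comps == (0, 0, 0) and norm == 0

    def test_pythagorean_triple(self):
        comps, norm = mot.residual_shift(
            mot.RigidTransform((1, 2, 2)), mot.RigidTransform()
        )
        assert norm == pytest.approx(3.0)

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            a, b = rng.normal(size=(2, 3)) * 5
            comps, norm = mot.residual_shift(
                mot.RigidTransform(tuple(a)), mot.RigidTransform(tuple(b))
            )
            assert norm == pytest.approx(np.sqrt(np.sum((a - b) ** 2)))
            assert np.allclose(comps, a - b)


class TestDvfShiftAtDmax:
    def test_constant_field_345(self, unit_grid):
        disp = np.zeros((*unit_grid.dims, 3))
        disp[..., 1] = 3.0
        disp[..., 2] = 4.0
        assert mot.dvf_shift_at_dmax(_dvf(unit_grid, disp), (5, 5, 5)) == \
            pytest.approx(5.0)

    def test_zero_field(self, unit_grid):
        disp = np.zeros((*unit_grid.dims, 3))
        assert mot.dvf_shift_at_dmax(_dvf(unit_grid, disp), (5, 5, 5)) == 0.0

    def test_linear_gradient_matches_sphere_average(self, unit_grid):
        c = unit_grid.centers_mm()
        disp = np.zeros((*unit_grid.dims, 3))
        disp[..., 0] = 0.5 * c[..., 2]  # x-displacement grows with z
        point = (5.0, 5.0, 5.0)
        got = mot.dvf_shift_at_dmax(_dvf(unit_grid, disp), point, 1.0)
        sph = sphere_mask(unit_grid, point, 1.0)
        expected = np.mean(
            np.linalg.norm(disp[sph.membership], axis=-1)
        )
        assert got == pytest.approx(expected)

    def test_out_of_extent_rejected(self, unit_grid):
        disp = np.zeros((*unit_grid.dims, 3))
        with pytest.raises(Exception):
            mot.dvf_shift_at_dmax(_dvf(unit_grid, disp), (999, 0, 0))


class TestMDA:
    def test_identical_masks_zero(self, unit_grid):
        s = sphere_mask(unit_grid, (5, 5, 5), 3.0)
        assert mot.mean_distance_to_agreement(s, s) == 0.0

    def test_concentric_spheres(self):
        grid = VoxelGrid((-15, -15, -15), (1, 1, 1), (31, 31, 31))
        a = sphere_mask(grid, (0, 0, 0), 5.0)
        b = sphere_mask(grid, (0, 0, 0), 8.0)
        assert mot.mean_distance_to_agreement(a, b) == pytest.approx(3.0, abs=1.0)

    def test_matches_all_pairs_brute_force(self, unit_grid, rng):
        a = random_mask(unit_grid, rng, p=0.1)
        b = random_mask(unit_grid, rng, p=0.1)
        got = mot.mean_distance_to_agreement(a, b)
        pa, pb = mot.surface_voxels(a), mot.surface_voxels(b)
        d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)
        expected = (d.min(axis=1).mean() + d.min(axis=0).mean()) / 2
        assert got == pytest.approx(expected)

    def test_bounded_by_symmetric_hausdorff(self, unit_grid, rng):
        a = random_mask(unit_grid, rng, p=0.1)
        b = random_mask(unit_grid, rng, p=0.1)
        mda = mot.mean_distance_to_agreement(a, b)
        pa, pb = mot.surface_voxels(a), mot.surface_voxels(b)
        d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)
        hausdorff = max(d.min(axis=1).max(), d.min(axis=0).max())
        assert mda <= hausdorff + 1e-9


class TestHausdorffToV10:
    def test_point_inside_is_zero(self, unit_grid):
        v10 = sphere_mask(unit_grid, (5, 5, 5), 3.0)
        assert mot.hausdorff_to_v10((5.2, 4.9, 5.1), v10) == 0.0

    def test_point_at_known_distance(self, unit_grid):
        v10 = StructureMask(unit_grid, np.zeros(unit_grid.dims, bool))
        v10.membership[2, 2, 2] = True
        d = mot.hausdorff_to_v10((9.0, 2.0, 2.0), v10)
        assert d == pytest.approx(7.0, abs=np.sqrt(3) / 2)

    def test_matches_brute_force_min(self, unit_grid, rng):
        v10 = random_mask(unit_grid, rng, p=0.05)
        pt = np.array([3.3, 7.1, 2.2])
        got = mot.hausdorff_to_v10(pt, v10)
        expected = np.min(
            np.linalg.norm(v10.centers_mm() - pt, axis=1)
        )
        assert got == pytest.approx(expected) or got == 0.0

    def test_empty_v10_returns_missing_with_warning(self, unit_grid):
        empty = StructureMask(unit_grid, np.zeros(unit_grid.dims, bool))
        with pytest.warns(UserWarning):
            assert mot.hausdorff_to_v10((5, 5, 5), empty) is None


class TestWarpDose:
    def test_identity_field_equals_resample(self, unit_grid, rng):
        ds = random_dose(unit_grid, rng)
        dvf = _dvf(unit_grid, np.zeros((*unit_grid.dims, 3)))
        target = VoxelGrid((1.5, 2.5, 0.5), (1, 1, 1), (8, 8, 8))
        warped = mot.warp_dose(ds, _dvf(target, np.zeros((*target.dims, 3))),
                               target)
        direct = resample_volume(ds.dose, target, "trilinear")
        assert np.allclose(warped.dose.values, direct.values)

    def test_constant_shift_matches_analytic(self, unit_grid):
        c = unit_grid.centers_mm()
        vals = 50.0 + c[..., 0] + 2 * c[..., 1]  # linear in world coords
        ds = DoseStudy(ScalarVolume(unit_grid, vals, kind="dose"))
        disp = np.zeros((*unit_grid.dims, 3))
        disp[..., 0] = 2.0
        inner = VoxelGrid((2, 2, 2), (1, 1, 1), (6, 6, 6))
        warped = mot.warp_dose(ds, _dvf(inner, np.zeros((*inner.dims, 3)) + [2.0, 0, 0]),
                               inner)
        ci = inner.centers_mm()
        expected = 50.0 + (ci[..., 0] + 2.0) + 2 * ci[..., 1]
        assert np.allclose(warped.dose.values, expected, atol=1e-9)

    def test_direction_flag_checked(self, unit_grid, rng):
        ds = random_dose(unit_grid, rng)
        dvf = _dvf(unit_grid, np.zeros((*unit_grid.dims, 3)),
                   direction=("source", "subsequent"))
        with pytest.raises(ValueError):
            mot.warp_dose(ds, dvf, unit_grid, dose_space="source")

    def test_preserves_constant_fields(self, unit_grid, rng):
        ds = DoseStudy(ScalarVolume(unit_grid, np.full(unit_grid.dims, 42.0),
                                    kind="dose"))
        disp = rng.normal(scale=0.5, size=(*unit_grid.dims, 3))
        inner = VoxelGrid((3, 3, 3), (1, 1, 1), (5, 5, 5))
        warped = mot.warp_dose(ds, _dvf(inner, disp[:5, :5, :5]), inner)
        assert np.allclose(warped.dose.values, 42.0)


class TestAccumulate:
    def test_identical_fractions_unchanged(self, unit_grid, rng):
        ds = random_dose(unit_grid, rng)
        acc = mot.accumulate_fractions([ds] * 5)
        assert np.allclose(acc.dose.values, ds.dose.values)

    def test_wandering_hotspots_blur(self, unit_grid):
        from bronchodose.dosimetry import dmax_point

        a = np.full(unit_grid.dims, 100.0)
        b = np.full(unit_grid.dims, 100.0)
        a[2, 2, 2] = 110.0
        b[8, 8, 8] = 110.0
        mask = StructureMask(unit_grid, np.ones(unit_grid.dims, bool))
        da = DoseStudy(ScalarVolume(unit_grid, a, kind="dose"))
        db = DoseStudy(ScalarVolume(unit_grid, b, kind="dose"))
        acc = mot.accumulate_fractions([da, db])
        acc_max, _ = dmax_point(acc, mask)
        assert acc_max < 110.0  # hotspots at different points do not add up

    def test_voxelwise_mean_and_bounds(self, unit_grid, rng):
        doses = [random_dose(unit_grid, rng) for _ in range(4)]
        acc = mot.accumulate_fractions(doses)
        stack = np.stack([d.dose.values for d in doses])
        assert np.allclose(acc.dose.values, stack.mean(axis=0))
        assert np.all(acc.dose.values <= stack.max(axis=0) + 1e-12)
        assert np.all(acc.dose.values >= stack.min(axis=0) - 1e-12)


class TestDispersion:
    def test_identical_points_zero(self):
        assert mot.dmax_position_dispersion([(1, 2, 3)] * 4) == 0.0

    def test_two_points_half_distance(self):
        assert mot.dmax_position_dispersion([(0, 0, 0), (10, 0, 0)]) == \
            pytest.approx(5.0)

    def test_matches_brute_force(self, rng):
        pts = rng.normal(size=(20, 3)) * 10
        got = mot.dmax_position_dispersion(list(pts))
        expected = np.mean(np.linalg.norm(pts - pts.mean(axis=0), axis=1))
        assert got == pytest.approx(expected)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            mot.dmax_position_dispersion([(0, 0, 0)])
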