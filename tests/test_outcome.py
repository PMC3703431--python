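"""Voxelization, dice, symmetric surface distance, and T2 concordance timing."""

import numpy as np
import pytest
import trimesh

from strokeflow.outcome import (
    concordance_curves,
    dice_index,
    point_surface_distance,
    symmetric_distance,
    voxelize,
)
from strokeflow.surface_io import BinaryMask, TriangleSurface
from strokeflow.synthetic import generate_patient, make_icosphere, truth_scenario, PatientParams


def _box(side, center=(0.0, 0.0, 0.0)):
    m = trimesh.creation.box(extents=(side, side, side))
    m.apply_translation(center)
    return TriangleSurface(np.asarray(m.vertices), np.asarray(m.faces))


class TestVoxelize:
    def test_cube_volume_exact_up_to_shell(self):
        cube = _box(10.0)
        mask = voxelize(cube, 0.5)
        count = mask.n_foreground
        shell = 6 * (10 / 0.5) ** 2  # one-voxel surface shell
        assert abs(count - 8000) <= shell

    def test_sphere_volume_within_3_percent(self):
        sphere = make_icosphere(10.0, 3)
        mask = voxelize(sphere, 1.0)
        assert mask.volume_mm3 == pytest.approx(4.0 / 3.0 * np.pi * 1000, rel=0.03)

    def test_open_surface_rejected(self, sphere_small):
        holed = TriangleSurface(sphere_small.vertices, sphere_small.faces[:-1])
        with pytest.raises(ValueError, match="closed"):
            voxelize(holed, 1.0)


class TestDice:
    def test_identical_masks(self):
        mask = voxelize(make_icosphere(8.0, 2), 1.0)
        assert dice_index(mask, mask) == 1.0

    def test_disjoint_masks(self):
        a = _box(6.0, (0, 0, 0))
        b = _box(6.0, (40, 0, 0))
        origin = np.array([-10.0, -10, -10])
        shape = (60, 25, 25)
        assert dice_index(
            voxelize(a, 1.0, origin=origin, shape=shape),
            voxelize(b, 1.0, origin=origin, shape=shape),
        ) == 0.0

    def test_half_overlapping_cubes_give_half(self):
        """Equal cubes overlapping in exactly half their volume: dice = 0.5."""
        a = _box(10.0, (0, 0, 0))
        b = _box(10.0, (5.0, 0, 0))
        origin = np.array([-7.5, -7.5, -7.5])
        shape = (26, 16, 16)
        d = dice_index(
            voxelize(a, 1.0, origin=origin, shape=shape),
            voxelize(b, 1.0, origin=origin, shape=shape),
        )
        assert d == pytest.approx(0.5, abs=1e-12)

    def test_matches_brute_force_voxel_count(self, rng):
        a = voxelize(make_icosphere(8.0, 2), 1.0, origin=np.array([-10.0, -10, -10]), shape=(22, 22, 22))
        b = voxelize(
            TriangleSurface(make_icosphere(8.0, 2).vertices + 3.0, make_icosphere(8.0, 2).faces),
            1.0, origin=np.array([-10.0, -10, -10]), shape=(22, 22, 22),
        )
        inter = sum(
            1
            for i in range(22) for j in range(22) for k in range(22)
            if a.voxels[i, j, k] and b.voxels[i, j, k]
        )
        expect = 2 * inter / (a.n_foreground + b.n_foreground)
        assert dice_index(a, b) == pytest.approx(expect, abs=0)
        assert dice_index(a, b) == pytest.approx(dice_index(b, a), abs=0)

    def test_both_empty_warns_zero(self):
        empty = BinaryMask(np.zeros((4, 4, 4)), (1, 1, 1))
        with pytest.warns(UserWarning):
            assert dice_index(empty, empty) == 0.0

    def test_grid_mismatch_rejected(self):
        a = BinaryMask(np.ones((4, 4, 4)), (1, 1, 1))
        b = BinaryMask(np.ones((4, 4, 4)), (2, 1, 1))
        with pytest.raises(ValueError, match="grid"):
            dice_index(a, b)


class TestSymmetricDistance:
    def test_identical_surfaces_zero(self, sphere10):
        assert symmetric_distance(sphere10, sphere10) == 0.0

    def test_concentric_spheres(self):
        a = make_icosphere(10.0, 3)
        b = make_icosphere(12.0, 3)
        assert symmetric_distance(a, b) == pytest.approx(2.0, rel=0.05)

    def test_matches_brute_force_point_triangle_scan(self, rng):
        """Vectorized distance equals a per-pair trimesh closest-point scan to 1e-9."""
        base = make_icosphere(8.0, 1)
        a = TriangleSurface(base.vertices + rng.normal(0, 0.4, base.vertices.shape), base.faces)
        pts = rng.normal(0, 12, (25, 3))
        tri = a.vertices[a.faces]
        oracle = np.array([
            np.linalg.norm(
                trimesh.triangles.closest_point(tri, np.repeat(p[None], tri.shape[0], 0)) - p,
                axis=1,
            ).min()
            for p in pts
        ])
        np.testing.assert_allclose(point_surface_distance(pts, a), oracle, atol=1e-9)

    def test_symmetry_and_linear_scaling(self, rng):
        a = make_icosphere(9.0, 1)
        b = TriangleSurface(a.vertices * 1.3 + rng.normal(0, 1, 3), a.faces)
        d = symmetric_distance(a, b)
        assert d == pytest.approx(symmetric_distance(b, a), rel=1e-12)
        a3 = TriangleSurface(a.vertices * 3.0, a.faces)
        b3 = TriangleSurface(b.vertices * 3.0, b.faces)
        assert symmetric_distance(a3, b3) == pytest.approx(3 * d, rel=1e-9)


class TestConcordance:
    def test_static_scenario_matching_t2(self, sphere10):
        from strokeflow.flow import MomentaField, flow_forward
        from strokeflow.regression import EvolutionScenario

        mom = MomentaField.zero(sphere10.face_centers, 4, 15.0, 3.0, t0_hours=6.0)
        frames = flow_forward(sphere10.vertices, mom).point_trajectories
        scn = EvolutionScenario(
            baseline=sphere10, momenta=mom,
            surfaces_t=[sphere10.with_vertices(f) for f in frames],
            obs_times_hours=np.array([6.0, 18.0]),
        )
        cc = concordance_curves(scn, sphere10)
        np.testing.assert_allclose(cc.dice_t, 1.0)
        assert cc.t_dice == 6.0  # earliest time on ties

    def test_crossing_time_recovered_on_generator_truth(self):
        p = generate_patient(PatientParams(subdivisions=1, noise_sd=0.0), seed=7)
        scn = truth_scenario(p, "dwi")
        cc = concordance_curves(scn, p.t2_surface)
        t_true = p.truth["t2_cross_hours"]
        assert abs(cc.t_dice - t_true) <= 3.0
        assert abs(cc.t_dsym - t_true) <= 3.0

    def test_receding_surface_best_matches_at_start(self, patient_noise_free):
        """T2 fixed at the baseline of a monotonically departing lesion: both
        best-match times sit at the first timepoint."""
        scn = truth_scenario(patient_noise_free, "mtt")
        t2 = scn.surfaces_t[0]
        cc = concordance_curves(scn, t2)
        assert cc.t_dice == scn.times_hours[0]
        assert cc.t_dsym == scn.times_hours[0]

    def test_argmax_argmin_definitions(self, patient_noise_free):
        p = patient_noise_free
        scn = truth_scenario(p, "dwi")
        cc = concordance_curves(scn, p.t2_surface)
        i_dice = np.where(cc.times_hours == cc.t_dice)[0][0]
        i_dsym = np.where(cc.times_hours == cc.t_dsym)[0][0]
        assert np.all(cc.dice_t[i_dice] >= cc.dice_t)
        assert np.all(cc.dsym_t[i_dsym] <= cc.dsym_t)
        assert np.all((cc.dice_t >= 0) & (cc.dice_t <= 1))
        assert np.all(cc.dsym_t >= 0)

    def test_offset_t2_caps_dice_below_one(self):
        """The evolving lesion need not converge to the final boundary: with a
        displaced T2 the dice curve peaks strictly below 1 and is reported as-is."""
        p = generate_patient(
            PatientParams(subdivisions=1, noise_sd=0.0, t2_offset_mm=4.0), seed=3
        )
        scn = truth_scenario(p, "dwi")
        cc = concordance_curves(scn, p.t2_surface)
        assert cc.dice_t.max() < 1.0
        assert cc.dsym_t.min() > 0.0
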