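"""Regression functional, adjoint gradient, and piecewise-geodesic fitting."""

import numpy as np
import pytest

from strokeflow.currents import surface_to_current
from strokeflow.flow import MomentaField, kinetic_energy
from strokeflow.regression import (
    RegressionConfig,
    _objective_and_grad,
    fit_pairwise,
    fit_timeseries,
    lambda_v_from_surfaces,
    objective,
    sample_surface,
)
from strokeflow.surface_io import TriangleSurface
from strokeflow.synthetic import make_icosphere
from strokeflow.pipeline import fit_dice


class TestObjective:
    def test_zero_momenta_self_target_is_zero(self, sphere_small):
        cfg = RegressionConfig()
        mom = MomentaField.zero(sphere_small.face_centers, 4, 15.0, 3.0)
        target = surface_to_current(sphere_small, cfg.lambda_w)
        j = objective(mom, sphere_small, [(12.0, target)], cfg)
        assert j == pytest.approx(0.0, abs=1e-9)

    def test_zero_momenta_displaced_target(self, sphere_small):
        from strokeflow.currents import currents_dist2

        cfg = RegressionConfig()
        mom = MomentaField.zero(sphere_small.face_centers, 4, 15.0, 3.0)
        moved = TriangleSurface(sphere_small.vertices + 4.0, sphere_small.faces)
        target = surface_to_current(moved, cfg.lambda_w)
        j = objective(mom, sphere_small, [(12.0, target)], cfg)
        expect = currents_dist2(surface_to_current(sphere_small, cfg.lambda_w), target)
        assert j == pytest.approx(expect, rel=1e-12)

    def test_term_by_term_assembly(self, sphere_small, rng):
        """J equals gamma * kinetic energy + currents distance, each audited separately."""
        from strokeflow.currents import current_from_vertices, currents_dist2
        from strokeflow.flow import flow_forward

        cfg = RegressionConfig()
        momenta = rng.normal(0, 0.1, (4, sphere_small.n_faces, 3))
        mom = MomentaField.from_momenta(sphere_small.face_centers, momenta, 15.0, 3.0)
        moved = TriangleSurface(sphere_small.vertices * 1.1, sphere_small.faces)
        target = surface_to_current(moved, cfg.lambda_w)
        j = objective(mom, sphere_small, [(12.0, target)], cfg)
        deformed = flow_forward(sphere_small.vertices, mom).final
        fidelity = currents_dist2(
            current_from_vertices(deformed, sphere_small.faces, cfg.lambda_w), target
        )
        assert j == pytest.approx(cfg.gamma * kinetic_energy(mom) + fidelity, rel=1e-9)


class TestGradient:
    def test_adjoint_gradient_matches_finite_differences(self, sphere_small, rng):
        """Exact reverse-sweep gradient vs central differences, rel err < 1e-4."""
        cfg = RegressionConfig()
        src = sphere_small
        moved = TriangleSurface(src.vertices * 1.2 + 2.0, src.faces)
        target = surface_to_current(moved, cfg.lambda_w)
        x0, y0, faces = src.face_centers, src.vertices, src.faces
        momenta = rng.normal(0, 0.15, (3, x0.shape[0], 3))
        args = (x0, y0, faces, {3: target}, cfg.gamma, 12.0, 1.0)
        _, grad, _ = _objective_and_grad(momenta, *args)
        eps = 1e-6
        idx = [(0, 0, 0), (1, 7, 2), (2, 19, 1), (0, 11, 1), (1, 3, 0)]
        for i in idx:
            mp, mm = momenta.copy(), momenta.copy()
            mp[i] += eps
            mm[i] -= eps
            jp, _, _ = _objective_and_grad(mp, *args)
            jm, _, _ = _objective_and_grad(mm, *args)
            fd = (jp - jm) / (2 * eps)
            assert abs(fd - grad[i]) / max(abs(fd), 1e-12) < 1e-4


class TestPairwiseFit:
    def test_self_fit_is_near_identity(self, sphere_small):
        cfg = RegressionConfig()
        phi_self = fit_pairwise(sphere_small, sphere_small, cfg)
        moved = TriangleSurface(sphere_small.vertices + 5.0, sphere_small.faces)
        phi_moved = fit_pairwise(sphere_small, moved, cfg)
        e_self = kinetic_energy(phi_self.momenta)
        e_moved = kinetic_energy(phi_moved.momenta)
        assert e_self < 1e-6 * e_moved

    def test_translation_recovery(self, sphere10):
        target = TriangleSurface(sphere10.vertices + [5.0, 0, 0], sphere10.faces, sphere10.t_hours)
        phi = fit_pairwise(sphere10, target, RegressionConfig(lambda_v=20.0))
        err = np.linalg.norm(phi.deformed_source.vertices - target.vertices, axis=1).mean()
        assert err < 1.0

    def test_sphere_to_ellipsoid_dice(self, sphere10):
        target = TriangleSurface(
            sphere10.vertices * np.array([1.4, 1.0, 0.8]), sphere10.faces
        )
        phi = fit_pairwise(sphere10, target, RegressionConfig())
        from strokeflow.outcome import dice_index, voxelize

        pts = np.vstack([phi.deformed_source.vertices, target.vertices])
        origin = pts.min(axis=0) - 1.0
        shape = tuple(int(np.ceil(pts.max(axis=0)[k] - origin[k])) + 2 for k in range(3))
        d = dice_index(
            voxelize(phi.deformed_source, 1.0, origin=origin, shape=shape),
            voxelize(target, 1.0, origin=origin, shape=shape),
        )
        assert d >= 0.9

    def test_objective_monotone_over_accepted_iterations(self, phi_map):
        """Within each fidelity scale of the schedule, J only decreases."""
        history = phi_map.fit_info["history"]
        for lw in sorted({h["lambda_w"] for h in history}):
            js = [h["J"] for h in history if h["lambda_w"] == lw]
            assert all(b < a for a, b in zip(js, js[1:]))


class TestTimeseriesFit:
    def test_identical_surfaces_give_static_scenario(self, sphere_small):
        surfaces = [
            TriangleSurface(sphere_small.vertices, sphere_small.faces, t)
            for t in (6.0, 30.0, 60.0)
        ]
        scn = fit_timeseries(surfaces, RegressionConfig())
        from strokeflow.kinetics import signed_speed

        sp = signed_speed(scn)
        assert np.abs(sp.speeds).max() < 1e-4  # cm/3h

    def test_recovers_synthetic_growth(self, patient_noise_free, dwi_scenario):
        p = patient_noise_free
        assert fit_dice(dwi_scenario, p.dwi_surfaces[1]) >= 0.85
        assert fit_dice(dwi_scenario, p.dwi_surfaces[2]) >= 0.85

    def test_interval_objectives_decrease(self, dwi_scenario):
        for iv in dwi_scenario.fit_info["intervals"]:
            assert iv["J"] <= iv["J0"]

    def test_grid_spans_observations(self, patient_noise_free, dwi_scenario):
        times = patient_noise_free.times_hours
        expect_steps = int(round((times[-1] - times[0]) / 3.0))
        assert dwi_scenario.n_steps == expect_steps
        assert dwi_scenario.times_hours[0] == times[0]
        assert dwi_scenario.times_hours[-1] == times[-1]

    def test_no_normal_flips_along_fit(self, dwi_scenario):
        """Diffeomorphism proxy: no triangle normal reverses along the flow."""
        base_normals = dwi_scenario.surfaces_t[0].face_normals
        for surf in dwi_scenario.surfaces_t[1:]:
            dots = np.einsum("ij,ij->i", surf.face_normals, base_normals)
            assert np.all(dots > 0)

    def test_requires_increasing_times(self, sphere_small):
        s1 = TriangleSurface(sphere_small.vertices, sphere_small.faces, 10.0)
        s2 = TriangleSurface(sphere_small.vertices, sphere_small.faces, 5.0)
        with pytest.raises(ValueError, match="increasing"):
            fit_timeseries([s1, s2], RegressionConfig())

    def test_lambda_v_bounding_box_rule(self, sphere10):
        shifted = TriangleSurface(sphere10.vertices + [10.0, 0, 0], sphere10.faces)
        lv = lambda_v_from_surfaces([sphere10, shifted])
        assert lv == pytest.approx(0.30 * 30.0)  # x extent 30 mm is the longest edge


class TestSampleSurface:
    def test_endpoints_and_rounding(self, patient_noise_free, dwi_scenario):
        p = patient_noise_free
        t1 = p.times_hours[0]
        assert sample_surface(dwi_scenario, t1) is dwi_scenario.surfaces_t[0]
        near = sample_surface(dwi_scenario, t1 + 1.4)
        assert near is dwi_scenario.surfaces_t[0]  # rounds to nearest grid step
        final = sample_surface(dwi_scenario, p.times_hours[-1])
        assert final is dwi_scenario.surfaces_t[-1]

    def test_out_of_range_rejected(self, dwi_scenario):
        with pytest.raises(ValueError):
            sample_surface(dwi_scenario, 1e4)
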