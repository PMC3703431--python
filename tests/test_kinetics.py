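"""Signed speeds, high contraction/expansion areas, region transport, speed curves."""

import warnings

import numpy as np
import pytest

from strokeflow.flow import MomentaField, flow_forward
from strokeflow.kinetics import (
    RegionLabels,
    SpeedField,
    extract_regions,
    map_regions_to_baseline,
    mean_speed_curves,
    signed_speed,
    transfer_dwi_to_mtt,
)
from strokeflow.regression import EvolutionScenario
from strokeflow.surface_io import TriangleSurface
from strokeflow.synthetic import generate_patient, make_icosphere, truth_scenario, PatientParams


def _scenario_from_momenta(baseline, mom):
    frames = flow_forward(baseline.vertices, mom).point_trajectories
    surfaces = [
        baseline.with_vertices(f, t_hours=mom.t0_hours + i * mom.dt_hours)
        for i, f in enumerate(frames)
    ]
    return EvolutionScenario(
        baseline=baseline, momenta=mom, surfaces_t=surfaces,
        obs_times_hours=np.array([mom.times_hours[0], mom.times_hours[-1]]),
    )


def _radial_scenario(rate_mm_per_h=1.0, flip=False):
    from strokeflow.synthetic import radial_growth_scenario

    return radial_growth_scenario(rate_mm_per_h, flip_orientation=flip)


class TestSignedSpeed:
    def test_identity_scenario_all_zero(self, sphere10):
        mom = MomentaField.zero(sphere10.face_centers, 4, 15.0, 3.0)
        sp = signed_speed(_scenario_from_momenta(sphere10, mom))
        np.testing.assert_array_equal(sp.speeds, 0.0)

    def test_radial_growth_uniform_at_analytic_rate(self):
        """r(t) = 10 + 1t mm: signed speed = +1 mm/h = 0.3 cm/3h, uniform to 10%."""
        sp = signed_speed(_radial_scenario(1.0))
        assert np.all(sp.speeds > 0)
        np.testing.assert_allclose(sp.speeds, 0.3, rtol=0.10)

    def test_orientation_flip_flips_sign(self):
        sp = signed_speed(_radial_scenario(1.0, flip=True))
        assert np.all(sp.speeds < 0)


class TestExtractRegions:
    def test_uniform_speeds_flag_nothing(self):
        sp = SpeedField(np.full((2, 6), 0.5), np.arange(2.0))
        labels = extract_regions(sp, 0)
        assert not labels.high_expansion.any() and not labels.high_contraction.any()

    def test_hand_computed_threshold(self):
        """{1,1,1,1,10}: mean 2.8, SD 3.6, threshold 6.4 -> only the 10 flagged."""
        sp = SpeedField(np.array([[1.0, 1, 1, 1, 10]]), np.zeros(1))
        labels = extract_regions(sp, 0)
        np.testing.assert_array_equal(labels.high_expansion, [False] * 4 + [True])
        assert not labels.high_contraction.any()

    def test_pure_contraction_has_no_expansion_flags(self, rng):
        sp = SpeedField(-np.abs(rng.normal(1, 0.5, (1, 30))), np.zeros(1))
        labels = extract_regions(sp, 0)
        assert not labels.high_expansion.any()
        assert labels.high_contraction.any()

    def test_scale_equivariance(self, rng):
        s = rng.normal(0, 1, (1, 50))
        l1 = extract_regions(SpeedField(s, np.zeros(1)), 0)
        l2 = extract_regions(SpeedField(7.3 * s, np.zeros(1)), 0)
        np.testing.assert_array_equal(l1.high_expansion, l2.high_expansion)
        np.testing.assert_array_equal(l1.high_contraction, l2.high_contraction)

    def test_disjoint_flags_enforced(self):
        with pytest.raises(ValueError, match="both"):
            RegionLabels(np.array([True]), np.array([True]), 0)


class TestRegionTransport:
    def test_step_zero_labels_unchanged(self, patient_noise_free):
        scn = truth_scenario(patient_noise_free, "dwi")
        labels = extract_regions(signed_speed(scn), 0)
        mapped = map_regions_to_baseline(scn, labels)
        np.testing.assert_array_equal(mapped.high_expansion, labels.high_expansion)
        assert mapped.at_step == 0

    def test_empty_labels_stay_empty(self, patient_noise_free):
        scn = truth_scenario(patient_noise_free, "dwi")
        empty = RegionLabels(
            np.zeros(scn.baseline.n_faces, bool), np.zeros(scn.baseline.n_faces, bool), 3
        )
        mapped = map_regions_to_baseline(scn, empty)
        assert not mapped.high_expansion.any() and not mapped.high_contraction.any()

    def test_late_step_flags_fall_in_true_expansion_lobe(self, patient_noise_free):
        """Flags extracted late in the evolution map back inside the generating lobe."""
        p = patient_noise_free
        scn = truth_scenario(p, "dwi")
        sp = signed_speed(scn)
        labels = extract_regions(sp, sp.speeds.shape[0] // 2)
        mapped = map_regions_to_baseline(scn, labels)
        lobe = p.truth["dwi"]["expansion_lobe"]
        flagged = mapped.high_expansion
        assert flagged.any()
        assert (flagged & lobe).sum() / flagged.sum() >= 0.9

    def test_transfer_preserves_flags_across_phi(self, patient_noise_free, phi_map):
        scn = truth_scenario(patient_noise_free, "dwi")
        labels = extract_regions(signed_speed(scn), 0)
        out = transfer_dwi_to_mtt(phi_map, labels)
        np.testing.assert_array_equal(out.high_expansion, labels.high_expansion)

    def test_equatorial_band_transfers_to_equatorial_band(self, patient_noise_free, phi_map):
        """A DWI equatorial band lands on the MTT equator (nested-sphere geometry)."""
        p = patient_noise_free
        dwi = p.dwi_surfaces[0]
        c_dwi = dwi.vertices.mean(axis=0)
        lat_dwi = _latitude(dwi.face_centers, c_dwi)
        band = np.abs(lat_dwi) < np.deg2rad(20)
        labels = RegionLabels(np.zeros_like(band), band, 0)
        out = transfer_dwi_to_mtt(phi_map, labels)
        mtt_base = phi_map.deformed_source
        lat_mtt = _latitude(mtt_base.face_centers, mtt_base.vertices.mean(axis=0))
        inside = np.abs(lat_mtt[out.high_expansion]) < np.deg2rad(25)
        assert inside.mean() >= 0.8


def _latitude(points, center):
    rel = points - center
    return np.arcsin(rel[:, 2] / np.linalg.norm(rel, axis=1))


class TestMeanSpeedCurves:
    def test_identity_scenario_zero_curves(self, sphere10):
        mom = MomentaField.zero(sphere10.face_centers, 4, 15.0, 3.0)
        scn = _scenario_from_momenta(sphere10, mom)
        labels = RegionLabels(
            np.zeros(sphere10.n_faces, bool), np.ones(sphere10.n_faces, bool), 0
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            curves = mean_speed_curves(scn, labels)
        np.testing.assert_array_equal(curves["mean_speed_expanding"], 0.0)

    def test_radial_ball_flat_curve_at_known_rate(self):
        scn = _radial_scenario(1.0)
        labels = RegionLabels(
            np.zeros(scn.baseline.n_faces, bool), np.ones(scn.baseline.n_faces, bool), 0
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            curves = mean_speed_curves(scn, labels)
        np.testing.assert_allclose(curves["mean_speed_expanding"], 0.3, rtol=0.10)

    def test_two_lobe_sign_consistency(self, patient_noise_free):
        scn = truth_scenario(patient_noise_free, "dwi")
        labels = extract_regions(signed_speed(scn), 0)
        assert labels.high_expansion.any() and labels.high_contraction.any()
        curves = mean_speed_curves(scn, labels)
        assert np.all(curves["mean_speed_expanding"] >= 0)
        assert np.all(curves["mean_speed_contracting"] <= 0)

    def test_empty_label_set_warns_and_yields_nan(self, sphere10):
        mom = MomentaField.zero(sphere10.face_centers, 3, 15.0, 3.0)
        scn = _scenario_from_momenta(sphere10, mom)
        empty = RegionLabels(
            np.zeros(sphere10.n_faces, bool), np.zeros(sphere10.n_faces, bool), 0
        )
        with pytest.warns(UserWarning, match="no faces"):
            curves = mean_speed_curves(scn, empty)
        assert np.isnan(curves["mean_speed_expanding"]).all()


class TestGlobalSignConvention:
    def test_volume_growth_matches_mean_signed_speed(self, patient_noise_free):
        """Enclosed volume increases between steps iff the area-weighted mean
        signed speed at that step is positive (checked where clearly nonzero)."""
        scn = truth_scenario(patient_noise_free, "dwi")
        sp = signed_speed(scn)
        for step in range(0, sp.speeds.shape[0], 10):
            areas = np.linalg.norm(scn.surfaces_t[step].face_normals, axis=1)
            mean_speed = np.average(sp.speeds[step], weights=areas)
            dv = scn.surfaces_t[step + 1].volume - scn.surfaces_t[step].volume
            if abs(mean_speed) > 1e-4:
                assert np.sign(dv) == np.sign(mean_speed)

    def test_mtt_expands_faster_than_dwi(self, patient_noise_free):
        """Generator truth ordering (fast MTT, slow DWI) is recovered by the
        measured mean expansion speeds."""
        p = patient_noise_free
        means = {}
        for modality in ("dwi", "mtt"):
            scn = truth_scenario(p, modality)
            sp = signed_speed(scn)
            labels = extract_regions(sp, 0)
            curves = mean_speed_curves(scn, labels)
            means[modality] = np.nanmean(curves["mean_speed_expanding"])
        assert means["mtt"] > means["dwi"]
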