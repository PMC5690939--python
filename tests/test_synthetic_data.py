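"""Cohort generator: phantom geometry, noise calibration, determinism."""

from __future__ import annotations

import numpy as np
import pytest

from contourvar.contour_io import (
    StructureSetValidationError,
    structure_sets_allclose,
    validate_structure_set,
)
from contourvar.random_fields import GaussianScalarField
from contourvar.surface_distance import directed_mean_surface_distance, sample_surface
from contourvar.synthetic_data import (
    NoiseSpec,
    PhantomSpec,
    generate_phantom_truth,
    load_cohort,
    save_cohort,
    simulate_cohort,
    simulate_delineation,
)
from contourvar.variation_analysis import compute_via, compute_vio, compute_vt

HALF_NORMAL = np.sqrt(2.0 / np.pi)


class TestPhantomTruth:
    def test_ellipsoid_slice_radii_analytic(self):
        spec = PhantomSpec("ball", "ellipsoid", (10, 10, 10), (0, 0, 0),
                           slice_thickness_mm=3.0)
        ss = generate_phantom_truth(spec)
        for c in ss.contours("ball"):
            expected = np.sqrt(100.0 - c.z_mm ** 2)
            radii = np.linalg.norm(c.vertices, axis=1)
            assert np.allclose(radii, expected, atol=1e-6)

    def test_tube_identical_circles_every_plane(self):
        spec = PhantomSpec("tube", "tube", (5, 60), (2, -3, 10))
        ss = generate_phantom_truth(spec)
        contours = ss.contours("tube")
        assert len(contours) >= 3
        ref = contours[0].vertices
        for c in contours[1:]:
            assert np.array_equal(c.vertices, ref)

    def test_crescent_polygons_simple_and_valid(self):
        spec = PhantomSpec("parotid", "crescent", (22, 12, 9, 40), (0, 0, 0))
        ss = generate_phantom_truth(spec)
        assert validate_structure_set(ss).ok

    def test_too_thin_shape_errors(self):
        spec = PhantomSpec("sliver", "tube", (5, 4), (0, 0, 0),
                           slice_thickness_mm=3.0)
        with pytest.raises(ValueError, match="3 z planes"):
            generate_phantom_truth(spec)


class TestDelineation:
    def truth(self, radius=30.0):
        return generate_phantom_truth(
            PhantomSpec("organ", "tube", (radius, 60), (0, 0, 0)))

    def test_zero_noise_identity(self):
        t = self.truth()
        out = simulate_delineation(t, None, 0.0, seed=0)
        assert structure_sets_allclose(t, out, tol_mm=0.0)

    def test_session_noise_half_normal_calibration(self):
        """Directed mean distance to truth ~ sigma * sqrt(2/pi).

        Averaged over several session-field realizations: one smooth field
        draw carries a few-percent amplitude fluctuation of its own.
        """
        t = self.truth()
        truth_cloud = sample_surface(t, "organ", 0.5)
        means = []
        for seed in range(6):
            out = simulate_delineation(t, None, 1.0, seed=seed)
            res = directed_mean_surface_distance(
                sample_surface(out, "organ", 0.5), truth_cloud)
            assert res.n_primary >= 1000
            means.append(res.mean_mm)
        assert np.mean(means) == pytest.approx(HALF_NORMAL, rel=0.10)

    def test_same_seed_identical(self):
        t = self.truth()
        a = simulate_delineation(t, None, 1.0, seed=5)
        b = simulate_delineation(t, None, 1.0, seed=5)
        assert structure_sets_allclose(a, b, tol_mm=0.0)

    def test_collapse_raises_naming_plane(self):
        # the centroid clip floors shrinkage at 20% of the local radius,
        # so only a sub-millimetre structure can actually collapse below
        # the 1 mm^2 area guard
        tiny = generate_phantom_truth(
            PhantomSpec("small", "tube", (0.6, 12), (0, 0, 0)))
        bias = lambda pts: np.full(len(pts), -10.0)
        with pytest.raises(StructureSetValidationError, match="small"):
            simulate_delineation(tiny, bias, 0.0, seed=0)


class TestCohort:
    def test_zero_noise_exact_identities(self, zero_noise_cohort):
        for p in zero_noise_cohort.patients:
            truth = p.truth_ct1
            for role in ("ROI11", "ROI21"):
                assert structure_sets_allclose(p.sets[role], truth, tol_mm=0.0)
            for obs in (1, 2):
                assert structure_sets_allclose(
                    p.sets[f"ROI{obs}D"], p.sets[f"ROI{obs}1"], tol_mm=0.0)
            if "ROI1A" in p.sets:
                assert structure_sets_allclose(p.sets["ROI1A"], truth,
                                               tol_mm=0.0)

    def test_recontour_subset_has_configured_size(self, small_cohort):
        assert len(small_cohort.recontour_subset) == 3
        with_a = [p for p in small_cohort.patients if "ROI1A" in p.sets]
        assert [p.patient_id for p in with_a] == small_cohort.recontour_subset

    def test_deformed_exists_iff_ct2_exists(self, small_cohort):
        for p in small_cohort.patients:
            for obs in (1, 2):
                assert (f"ROI{obs}D" in p.sets) == (f"ROI{obs}2" in p.sets)

    def test_seeded_bundles_serialize_identically(self, tmp_path):
        phantoms = [PhantomSpec("o", "tube", (15, 30), (0, 0, 0))]
        noise = NoiseSpec(1.0, 0.5, 1.0, seed=99)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        save_cohort(simulate_cohort(phantoms, noise, 2, 1), d1)
        save_cohort(simulate_cohort(phantoms, noise, 2, 1), d2)
        for f1 in sorted(d1.rglob("*")):
            f2 = d2 / f1.relative_to(d1)
            if f1.is_file():
                assert f1.read_bytes() == f2.read_bytes(), f1.name

    def test_cohort_roundtrip_through_disk(self, tmp_path, small_cohort):
        save_cohort(small_cohort, tmp_path / "c")
        back = load_cohort(tmp_path / "c")
        assert back.patient_ids == small_cohort.patient_ids
        assert back.recontour_subset == small_cohort.recontour_subset
        p0, q0 = small_cohort.patients[0], back.patients[0]
        assert set(p0.sets) == set(q0.sets)
        for role in p0.sets:
            assert structure_sets_allclose(p0.sets[role], q0.sets[role],
                                           tol_mm=1e-9)

    def test_missing_rois_removed(self):
        phantoms = [PhantomSpec("a", "tube", (15, 30), (0, 0, 0)),
                    PhantomSpec("b", "tube", (15, 30), (40, 0, 0))]
        bundle = simulate_cohort(phantoms, NoiseSpec(0.5, 0.3, 0.5, seed=1),
                                 3, 1, missing={"p001": ["b"]})
        assert "b" not in bundle.patients[1].sets["ROI11"].roi_map
        assert "b" in bundle.patients[0].sets["ROI11"].roi_map


class TestNoiseSourceSeparability:
    """Exactly one noise source on: only the matching measurement moves."""

    phantoms = [PhantomSpec("organ", "tube", (25, 60), (0, 0, 0))]

    def measure(self, noise):
        bundle = simulate_cohort(self.phantoms, noise, n_patients=4,
                                 n_recontour=2)
        vio = np.mean([r.value_mm for r in compute_vio(bundle, "organ")])
        vt = np.mean([r.value_mm for r in compute_vt(bundle, "organ")])
        via = np.mean([r.value_mm for r in compute_via(bundle, "organ")])
        return vio, vt, via

    def test_interobserver_only(self):
        vio, vt, via = self.measure(NoiseSpec(2.0, 0.0, 0.0, seed=1))
        assert vio > 0.5
        assert vt < 0.05 and via < 0.05

    def test_deformation_only(self):
        vio, vt, via = self.measure(NoiseSpec(0.0, 0.0, 2.0, seed=2))
        assert vt > 0.5
        assert vio < 0.05 and via < 0.05

    def test_session_noise_enters_via_and_vt_consistently(self):
        # session noise is *part of* VT and VIO by construction (the whole
        # point of the quadrature decomposition); with sigma_intra alone,
        # VT carries no deformation component, so VT ~ VIA
        vio, vt, via = self.measure(NoiseSpec(0.0, 1.0, 0.0, seed=3))
        assert via > 0.5
        assert vt == pytest.approx(via, rel=0.25)


def test_interobserver_calibration_two_mm():
    """sigma_inter = 2, others 0: VIO ~ 2 * sqrt(2) * sqrt(2/pi) = 2.26."""
    bundle = simulate_cohort(
        [PhantomSpec("organ", "tube", (30, 60), (0, 0, 0))],
        NoiseSpec(2.0, 0.0, 0.0, seed=1), n_patients=20, n_recontour=5)
    vio = np.mean([r.value_mm for r in compute_vio(bundle, "organ")])
    assert vio == pytest.approx(2.0 * np.sqrt(2.0) * HALF_NORMAL, rel=0.15)
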