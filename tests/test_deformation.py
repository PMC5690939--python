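"""B-spline displacement fields: basis correctness, windows, randomness."""

from __future__ import annotations

from itertools import product

import numpy as np
import pytest

from contourvar.contour_io import structure_sets_allclose
from contourvar.deformation import (
    BSplineDisplacementField,
    FieldSpec,
    _bspline_basis,
    apply_to_structure,
    evaluate_field,
    focused_second_pass,
    random_smooth_field,
)
from contourvar.surface_distance import directed_mean_surface_distance, sample_surface
from tests.conftest import sphere_structure


def make_field(coeff, spacing=10.0, origin=(-40, -40, -40),
               support=((-30, -30, -30), (30, 30, 30)), taper=0.0):
    return BSplineDisplacementField(
        origin_mm=origin, grid_spacing_mm=(spacing,) * 3, coefficients=coeff,
        support_lower_mm=support[0], support_upper_mm=support[1],
        taper_mm=taper)


def naive_basis_sum(fld, point):
    """Oracle: direct summation over the 64 supporting basis terms."""
    u = (np.asarray(point) - fld.origin_mm) / fld.grid_spacing_mm
    cell = np.floor(u).astype(int)
    t = u - cell
    bx = _bspline_basis(np.array([t[0]]))[0]
    by = _bspline_basis(np.array([t[1]]))[0]
    bz = _bspline_basis(np.array([t[2]]))[0]
    ns = fld.lattice_shape
    out = np.zeros(3)
    for mx, my, mz in product(range(4), repeat=3):
        i = min(max(cell[0] - 1 + mx, 0), ns[0] - 1)
        j = min(max(cell[1] - 1 + my, 0), ns[1] - 1)
        k = min(max(cell[2] - 1 + mz, 0), ns[2] - 1)
        out += bx[mx] * by[my] * bz[mz] * fld.coefficients[i, j, k]
    return out


def test_zero_coefficients_zero_everywhere():
    fld = make_field(np.zeros((9, 9, 9, 3)))
    pts = np.random.default_rng(0).uniform(-60, 60, (200, 3))
    assert np.all(evaluate_field(fld, pts) == 0.0)


def test_partition_of_unity_constant_coefficients():
    coeff = np.tile(np.array([1.0, 0.0, 0.0]), (9, 9, 9, 1))
    fld = make_field(coeff)
    pts = np.random.default_rng(1).uniform(-25, 25, (100, 3))  # deep inside
    disp = evaluate_field(fld, pts)
    assert np.allclose(disp, [1.0, 0.0, 0.0], atol=1e-12)


def test_matches_naive_basis_sum_oracle():
    rng = np.random.default_rng(2)
    fld = make_field(rng.standard_normal((9, 9, 9, 3)))
    pts = rng.uniform(-28, 28, (100, 3))
    disp = evaluate_field(fld, pts)
    for p, d in zip(pts, disp):
        assert np.allclose(d, naive_basis_sum(fld, p), atol=1e-12)


def test_support_containment_exact_zero_outside():
    rng = np.random.default_rng(3)
    fld = make_field(rng.standard_normal((9, 9, 9, 3)), taper=5.0)
    # points beyond support + taper in at least one axis
    pts = np.array([[36.0, 0, 0], [0, -35.1, 0], [100, 100, 100],
                    [0, 0, 35.0001]])
    assert np.all(evaluate_field(fld, pts) == 0.0)


def test_monotone_amplitude_scaling():
    rng = np.random.default_rng(4)
    coeff = rng.standard_normal((9, 9, 9, 3))
    pts = rng.uniform(-29, 29, (50, 3))
    d1 = evaluate_field(make_field(coeff), pts)
    d3 = evaluate_field(make_field(3.0 * coeff), pts)
    assert np.allclose(d3, 3.0 * d1, atol=1e-12)


def test_apply_zero_field_is_identity():
    ss = sphere_structure(15.0, 3.0)
    fld = make_field(np.zeros((9, 9, 9, 3)))
    assert structure_sets_allclose(ss, apply_to_structure(fld, ss), tol_mm=0.0)


def test_pure_translation_moves_z_only():
    ss = sphere_structure(15.0, 3.0)
    coeff = np.tile(np.array([0.0, 0.0, 3.0]), (11, 11, 11, 1))
    fld = BSplineDisplacementField(
        origin_mm=(-50, -50, -50), grid_spacing_mm=(10, 10, 10),
        coefficients=coeff, support_lower_mm=(-40, -40, -40),
        support_upper_mm=(40, 40, 40), taper_mm=0.0)
    warped = apply_to_structure(fld, ss)
    for ca, cb in zip(ss.contours("sphere"), warped.contours("sphere")):
        assert cb.z_mm == pytest.approx(ca.z_mm + 3.0, abs=1e-9)
        assert np.allclose(cb.vertices, ca.vertices, atol=1e-9)


def test_radial_field_on_sphere_measured_distance():
    """A constructed constant-radial displacement is recovered by the
    distance statistic within 3%."""
    radius, delta = 20.0, 2.0
    ss = sphere_structure(radius, 1.0, n=720)
    # radial field sampled onto a fine lattice (spacing 4 mm)
    spacing = 4.0
    origin = np.array([-48.0, -48.0, -48.0])
    n = 25
    axes = [origin[i] + spacing * np.arange(n) for i in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    norms = np.maximum(np.linalg.norm(pts, axis=1), 1e-9)
    radial = pts / norms[:, None] * delta
    fld = BSplineDisplacementField(
        origin_mm=origin, grid_spacing_mm=(spacing,) * 3,
        coefficients=radial.reshape(n, n, n, 3),
        support_lower_mm=(-35, -35, -35), support_upper_mm=(35, 35, 35))
    warped = apply_to_structure(fld, ss)
    res = directed_mean_surface_distance(
        sample_surface(ss, "sphere", 0.5), sample_surface(warped, "sphere", 0.5))
    assert res.mean_mm == pytest.approx(delta, rel=0.03)


class TestRandomField:
    support = ((-30.0, -30.0, -30.0), (30.0, 30.0, 30.0))

    def test_zero_rms_gives_zero_field(self):
        fld = random_smooth_field(FieldSpec(0.0, 15.0, 1), *self.support)
        assert np.all(fld.coefficients == 0.0)

    def test_same_seed_bit_identical(self):
        f1 = random_smooth_field(FieldSpec(2.0, 15.0, 7), *self.support)
        f2 = random_smooth_field(FieldSpec(2.0, 15.0, 7), *self.support)
        assert np.array_equal(f1.coefficients, f2.coefficients)

    def test_probe_rms_matches_target(self):
        from contourvar.deformation import _probe_grid

        fld = random_smooth_field(FieldSpec(2.0, 15.0, 3), *self.support)
        probe = _probe_grid(np.asarray(self.support[0]),
                            np.asarray(self.support[1]))
        disp = evaluate_field(fld, probe)
        rms = np.sqrt(np.mean(np.sum(disp ** 2, axis=1)))
        assert 1.98 <= rms <= 2.02  # exact by construction on this grid


class TestFocusedSecondPass:
    def base(self, seed=5):
        return random_smooth_field(FieldSpec(2.0, 15.0, seed),
                                   (-30, -30, -30), (30, 30, 30))

    def focus(self):
        return sphere_structure(10.0, 2.0, roi="focus")

    def test_reduction_zero_unchanged(self):
        fld = self.base()
        out = focused_second_pass(fld, self.focus(), "focus", 0.0)
        pts = np.random.default_rng(1).uniform(-25, 25, (200, 3))
        assert np.allclose(evaluate_field(out, pts), evaluate_field(fld, pts),
                           atol=1e-12)

    def test_reduction_one_zeroes_focus_box(self):
        out = focused_second_pass(self.base(), self.focus(), "focus", 1.0)
        pts = np.random.default_rng(2).uniform(-9, 9, (200, 3))
        assert np.all(evaluate_field(out, pts) == 0.0)

    def test_partial_reduction_scales_rms_inside_box(self):
        fld = self.base()
        out = focused_second_pass(fld, self.focus(), "focus", 0.2)
        pts = np.random.default_rng(3).uniform(-9, 9, (2000, 3))
        rms_in = np.sqrt(np.mean(np.sum(evaluate_field(fld, pts) ** 2, axis=1)))
        rms_out = np.sqrt(np.mean(np.sum(evaluate_field(out, pts) ** 2, axis=1)))
        assert rms_out == pytest.approx(0.8 * rms_in, rel=0.02)

    def test_far_field_unchanged(self):
        fld = self.base()
        out = focused_second_pass(fld, self.focus(), "focus", 1.0)
        far = np.array([[29.0, 29.0, 29.0], [-29.0, 0.0, 28.0]])
        assert np.allclose(evaluate_field(out, far), evaluate_field(fld, far),
                           atol=1e-12)


def test_field_json_roundtrip(tmp_path):
    fld = random_smooth_field(FieldSpec(1.5, 20.0, 9), (-20, -20, -20),
                              (20, 20, 20))
    fld2 = focused_second_pass(fld, sphere_structure(8.0, 2.0, roi="f"),
                               "f", 0.3)
    path = tmp_path / "field.json"
    fld2.save(path)
    back = BSplineDisplacementField.load(path)
    pts = np.random.default_rng(0).uniform(-25, 25, (100, 3))
    assert np.allclose(evaluate_field(back, pts), evaluate_field(fld2, pts),
                       atol=1e-12)
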