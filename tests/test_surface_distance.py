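"""Distance statistic: sampling, oracle equivalence, analytic limits."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from contourvar.contour_io import StructureSet
from contourvar.surface_distance import (
    SurfacePointCloud,
    brute_force_nearest,
    directed_mean_surface_distance,
    sample_surface,
    symmetric_mean_surface_distance,
)
from tests.conftest import circle_contour, sphere_structure, square_contour


def cloud(points, spacing=0.5, name="c") -> SurfacePointCloud:
    return SurfacePointCloud(name, np.asarray(points, float), spacing)


def random_cloud(rng, n, scale=20.0) -> SurfacePointCloud:
    return cloud(rng.uniform(-scale, scale, size=(n, 3)))


class TestSampling:
    def test_unit_square_spacing_one_gives_corners(self, unit_square_ss):
        pc = sample_surface(unit_square_ss, "square", spacing_mm=1.0)
        assert len(pc) == 4
        corners = {(-0.5, -0.5), (0.5, -0.5), (0.5, 0.5), (-0.5, 0.5)}
        assert {(round(x, 9), round(y, 9)) for x, y, _ in pc.points} == corners

    def test_perimeter_conservation(self, unit_square_ss):
        pc = sample_surface(unit_square_ss, "square", spacing_mm=0.25)
        # point count x step ~ perimeter (4 mm)
        assert len(pc) * (4.0 / len(pc)) == pytest.approx(4.0)
        assert len(pc) >= 16

    def test_circle_count_matches_arclength_formula(self):
        ss = StructureSet("c", {"circle": [circle_contour(0.0, 10.0, n=60)]})
        pc = sample_surface(ss, "circle", spacing_mm=0.5)
        expected = int(np.ceil(2 * np.pi * 10.0 / 0.5))
        assert abs(len(pc) - expected) <= 1

    def test_two_planes_union_preserves_z(self):
        ss = StructureSet("t", {"r": [circle_contour(z, 5.0) for z in (0.0, 3.0)]})
        pc = sample_surface(ss, "r", spacing_mm=1.0)
        assert set(np.unique(pc.points[:, 2])) == {0.0, 3.0}

    def test_missing_roi_raises(self, unit_square_ss):
        with pytest.raises(KeyError):
            sample_surface(unit_square_ss, "nope")


class TestDirected:
    def test_identical_clouds_zero(self):
        rng = np.random.default_rng(0)
        a = random_cloud(rng, 40)
        res = directed_mean_surface_distance(a, a)
        assert res.mean_mm == 0.0 and res.max_mm == 0.0
        assert res.n_primary == 40

    def test_concentric_spheres_offset(self):
        inner = sample_surface(sphere_structure(20.0, 0.5, n=1024), "sphere", 0.5)
        outer = sample_surface(sphere_structure(22.0, 0.5, n=1024), "sphere", 0.5)
        res = directed_mean_surface_distance(inner, outer)
        assert res.mean_mm == pytest.approx(2.0, abs=0.05)

    @pytest.mark.parametrize("seed,na,nb", [(1, 50, 80), (2, 200, 37), (3, 5, 500)])
    def test_matches_bruteforce_oracle(self, seed, na, nb):
        rng = np.random.default_rng(seed)
        a, b = random_cloud(rng, na), random_cloud(rng, nb)
        fast = directed_mean_surface_distance(a, b)
        slow = brute_force_nearest(a, b)
        assert fast.mean_mm == pytest.approx(slow.mean_mm, abs=1e-12)
        assert fast.max_mm == pytest.approx(slow.max_mm, abs=1e-12)

    def test_point_order_irrelevant(self):
        rng = np.random.default_rng(4)
        a, b = random_cloud(rng, 60), random_cloud(rng, 60)
        perm = cloud(a.points[rng.permutation(60)])
        r1 = directed_mean_surface_distance(a, b)
        r2 = directed_mean_surface_distance(perm, b)
        assert r1.mean_mm == pytest.approx(r2.mean_mm, abs=1e-12)

    def test_asymmetry_exists(self):
        point = cloud([[0, 0, 0]])
        segment = cloud([[0, 0, 0], [10, 0, 0]])
        ab = directed_mean_surface_distance(point, segment).mean_mm
        ba = directed_mean_surface_distance(segment, point).mean_mm
        assert ab == 0.0 and ba == 5.0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        a, b = random_cloud(rng, 30), random_cloud(rng, 45)
        # random rotation via QR, plus translation, applied to BOTH clouds
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        t = rng.uniform(-50, 50, 3)
        ra = cloud(a.points @ q.T + t)
        rb = cloud(b.points @ q.T + t)
        before = directed_mean_surface_distance(a, b).mean_mm
        after = directed_mean_surface_distance(ra, rb).mean_mm
        assert after == pytest.approx(before, abs=1e-9)


class TestSymmetric:
    def test_is_mean_of_directed(self):
        rng = np.random.default_rng(5)
        a, b = random_cloud(rng, 30), random_cloud(rng, 70)
        ab = directed_mean_surface_distance(a, b).mean_mm
        ba = directed_mean_surface_distance(b, a).mean_mm
        sym = symmetric_mean_surface_distance(a, b)
        assert sym.mean_mm == pytest.approx(0.5 * (ab + ba), abs=1e-12)
        assert sym.direction == "symmetric"


class TestBruteForce:
    def test_tiny_cases_by_hand(self):
        one = cloud([[0, 0, 0]])
        other = cloud([[3, 4, 0]])
        res = brute_force_nearest(one, other)
        assert res.mean_mm == res.max_mm == 5.0
        line = cloud([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        shifted = cloud([[0, 0, 1], [1, 0, 1], [2, 0, 1]])
        res = brute_force_nearest(line, shifted)
        assert res.mean_mm == res.max_mm == 1.0

    def test_guard_refuses_oversize(self):
        big = cloud(np.zeros((10_001, 3)) + np.arange(10_001)[:, None])
        with pytest.raises(ValueError, match="guard"):
            brute_force_nearest(big, big)


def test_refinement_stability_on_smooth_phantoms():
    """Halving the sampling step changes the statistic by < 2%."""
    a = sphere_structure(20.0, 1.0, n=720)
    b = sphere_structure(23.0, 1.0, n=720)
    coarse = directed_mean_surface_distance(
        sample_surface(a, "sphere", 1.0), sample_surface(b, "sphere", 1.0))
    fine = directed_mean_surface_distance(
        sample_surface(a, "sphere", 0.5), sample_surface(b, "sphere", 0.5))
    assert abs(fine.mean_mm - coarse.mean_mm) / fine.mean_mm < 0.02
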