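"""Shared fixtures: small analytic structure sets and a reusable cohort."""

from __future__ import annotations

import numpy as np
import pytest

from contourvar.contour_io import PlanarContour, StructureSet
from contourvar.synthetic_data import (
    NoiseSpec,
    PhantomSpec,
    generate_phantom_truth,
    simulate_cohort,
)


def square_contour(z: float = 0.0, side: float = 10.0,
                   center=(0.0, 0.0)) -> PlanarContour:
    h = side / 2.0
    cx, cy = center
    return PlanarContour(z, np.array([
        [cx - h, cy - h], [cx + h, cy - h], [cx + h, cy + h], [cx - h, cy + h],
    ]))


def circle_contour(z: float, radius: float, n: int = 256,
                   center=(0.0, 0.0)) -> PlanarContour:
    theta = 2 * np.pi * np.arange(n) / n
    return PlanarContour(z, np.column_stack([
        center[0] + radius * np.cos(theta),
        center[1] + radius * np.sin(theta),
    ]))


def sphere_structure(radius: float, slice_mm: float = 1.0,
                     roi: str = "sphere", n: int = 512) -> StructureSet:
    contours = []
    k_max = int(np.floor(radius / slice_mm - 0.5))
    for k in range(-k_max - 1, k_max + 2):
        z = (k + 0.5) * slice_mm
        frac = 1.0 - (z / radius) ** 2
        if frac <= 0:
            continue
        r = radius * np.sqrt(frac)
        if r < 0.5:
            continue
        contours.append(circle_contour(z, r, n))
    return StructureSet(study_id=f"sphere{radius:g}", roi_map={roi: contours})


@pytest.fixture
def unit_square_ss() -> StructureSet:
    return StructureSet(study_id="sq",
                        roi_map={"square": [square_contour(0.0, 1.0)]})


@pytest.fixture(scope="session")
def small_cohort():
    """Six patients, two ROIs, all noise sources active; reused read-only."""
    phantoms = [
        PhantomSpec("organ_tube", "tube", (20, 48), (0, 0, 0)),
        PhantomSpec("organ_ball", "ellipsoid", (16, 18, 15), (60, 0, 10)),
    ]
    noise = NoiseSpec(sigma_inter_mm=1.2, sigma_intra_mm=0.6,
                      sigma_def_mm=1.5, seed=42)
    return simulate_cohort(phantoms, noise, n_patients=6, n_recontour=3)


@pytest.fixture(scope="session")
def zero_noise_cohort():
    phantoms = [PhantomSpec("organ", "tube", (20, 48), (0, 0, 0))]
    noise = NoiseSpec(0.0, 0.0, 0.0, seed=7)
    return simulate_cohort(phantoms, noise, n_patients=4, n_recontour=2)
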