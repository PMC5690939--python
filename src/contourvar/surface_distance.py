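"""The directed mean surface distance between two ROI surfaces.

The statistic is an adaptation of the Hausdorff distance used for contour
comparison in registration QA: every point sampled on the *primary* surface
is matched to its closest point on the *secondary* surface in 3D, and the
mean of those closest distances summarises the separation between the two
surfaces (the maximum is the classic directed Hausdorff distance and is
reported as a diagnostic).  Surfaces are the stacked contour rings
themselves, resampled at uniform arc length; there is no inter-slice mesh
and no end caps, matching planar RT-STRUCT data.

Nearest-neighbour queries use an exact KD-tree; ``brute_force_nearest``
provides the all-pairs oracle the accelerated path is tested against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.spatial import cKDTree

from contourvar.contour_io import StructureSet

__all__ = [
    "SurfacePointCloud",
    "DistanceResult",
    "sample_surface",
    "directed_mean_surface_distance",
    "symmetric_mean_surface_distance",
    "brute_force_nearest",
]

#: default arc-length sampling step, an order of magnitude below the
#: smallest variation this statistic is used to resolve (~0.9 mm)
DEFAULT_SPACING_MM = 0.5

#: refuse all-pairs evaluation beyond this size per cloud
BRUTE_FORCE_GUARD = 10_000


@dataclass
class SurfacePointCloud:
    """3D point samples of one ROI surface."""

    roi_name: str
    points: np.ndarray  # (n, 3) mm
    source_spacing_mm: float

    def __post_init__(self) -> None:
        p = np.asarray(self.points, dtype=float)
        if p.ndim != 2 or p.shape[1] != 3 or len(p) < 1:
            raise ValueError("points must be a non-empty (n, 3) array")
        if not np.all(np.isfinite(p)):
            raise ValueError("points must be finite")
        if not self.source_spacing_mm > 0:
            raise ValueError("source_spacing_mm must be > 0")
        self.points = p

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class DistanceResult:
    """Mean and maximum closest distance from a primary to a secondary cloud."""

    mean_mm: float
    max_mm: float
    n_primary: int
    direction: Literal["directed", "symmetric"]

    def __post_init__(self) -> None:
        if not (0.0 <= self.mean_mm <= self.max_mm + 1e-12):
            raise ValueError("requires 0 <= mean_mm <= max_mm")
        if self.n_primary < 1:
            raise ValueError("n_primary must be >= 1")


def _resample_ring(vertices: np.ndarray, spacing_mm: float) -> np.ndarray:
    """Resample a closed polygon ring at uniform arc length.

    The step is <= ``spacing_mm`` and the number of samples is never below
    the vertex count, so refinement only ever adds points.
    """
    closed = np.vstack([vertices, vertices[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    perimeter = cum[-1]
    n = max(len(vertices), int(math.ceil(perimeter / spacing_mm)))
    s = np.arange(n) * (perimeter / n)
    x = np.interp(s, cum, closed[:, 0])
    y = np.interp(s, cum, closed[:, 1])
    return np.column_stack([x, y])


def sample_surface(ss: StructureSet, roi: str,
                   spacing_mm: float = DEFAULT_SPACING_MM) -> SurfacePointCloud:
    """Sample an ROI surface as the union of its resampled contour rings.

    Each polygon's perimeter is resampled at a uniform arc-length step
    <= ``spacing_mm``; z values are those of the stored planes (no
    inter-slice interpolation, no end-cap discs).
    """
    if spacing_mm <= 0:
        raise ValueError("spacing_mm must be > 0")
    contours = ss.contours(roi)  # KeyError if missing
    chunks = []
    for c in contours:
        xy = _resample_ring(c.vertices, spacing_mm)
        z = np.full((len(xy), 1), c.z_mm)
        chunks.append(np.hstack([xy, z]))
    return SurfacePointCloud(roi_name=roi, points=np.vstack(chunks),
                             source_spacing_mm=spacing_mm)


def directed_mean_surface_distance(primary: SurfacePointCloud,
                                   secondary: SurfacePointCloud) -> DistanceResult:
    """Mean (and max) 3D distance from each primary point to its closest
    secondary point.

    Deterministic and independent of point order.  The mean is the surface
    separation statistic used throughout the variation analysis; the max is
    the classic directed Hausdorff distance.
    """
    tree = cKDTree(secondary.points)
    d, _ = tree.query(primary.points, k=1, workers=-1)
    return DistanceResult(mean_mm=float(np.mean(d)), max_mm=float(np.max(d)),
                          n_primary=len(primary), direction="directed")


def symmetric_mean_surface_distance(a: SurfacePointCloud,
                                    b: SurfacePointCloud) -> DistanceResult:
    """Arithmetic mean of the two directed means (sensitivity diagnostic)."""
    ab = directed_mean_surface_distance(a, b)
    ba = directed_mean_surface_distance(b, a)
    return DistanceResult(mean_mm=0.5 * (ab.mean_mm + ba.mean_mm),
                          max_mm=max(ab.max_mm, ba.max_mm),
                          n_primary=len(a) + len(b), direction="symmetric")


def brute_force_nearest(primary: SurfacePointCloud,
                        secondary: SurfacePointCloud) -> DistanceResult:
    """All-pairs oracle with the same contract as the accelerated path.

    Refuses clouds larger than 10^4 points each; chunking keeps memory
    bounded without changing the exhaustive arithmetic.
    """
    if len(primary) > BRUTE_FORCE_GUARD or len(secondary) > BRUTE_FORCE_GUARD:
        raise ValueError(
            f"brute force guard exceeded ({len(primary)} x {len(secondary)}; "
            f"limit {BRUTE_FORCE_GUARD} per cloud)"
        )
    mins = np.empty(len(primary))
    step = 512
    for i in range(0, len(primary), step):
        block = primary.points[i : i + step]
        diff = block[:, None, :] - secondary.points[None, :, :]
        dist = np.sqrt(np.sum(diff * diff, axis=2))
        mins[i : i + step] = dist.min(axis=1)
    return DistanceResult(mean_mm=float(np.mean(mins)), max_mm=float(np.max(mins)),
                          n_primary=len(primary), direction="directed")


def batch_distances(ss_a: StructureSet, ss_b: StructureSet,
                    rois: list[str] | None = None,
                    spacing_mm: float = DEFAULT_SPACING_MM,
                    direction: Literal["directed", "symmetric"] = "directed"):
    """Per-ROI distance table between two structure sets.

    Returns a pandas DataFrame with columns
    (roi, direction, mean_mm, max_mm, n_primary); ``ss_a`` is primary.
    """
    import pandas as pd

    if rois is None:
        rois = [r for r in ss_a.roi_names if r in ss_b.roi_map]
    rows = []
    for roi in rois:
        pa = sample_surface(ss_a, roi, spacing_mm)
        pb = sample_surface(ss_b, roi, spacing_mm)
        if direction == "directed":
            res = directed_mean_surface_distance(pa, pb)
        else:
            res = symmetric_mean_surface_distance(pa, pb)
        rows.append({"roi": roi, "direction": res.direction,
                     "mean_mm": res.mean_mm, "max_mm": res.max_mm,
                     "n_primary": res.n_primary})
    return pd.DataFrame(rows)
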