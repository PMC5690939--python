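"""Smooth B-spline displacement fields applied to contours.

The deformable-registration step of the analysis is represented by a known
displacement field rather than an optimized registration: a cubic
tensor-product B-spline lattice, windowed so the displacement is exactly
zero outside a stated support box plus a smooth taper band.  Random fields
with a prescribed RMS amplitude stand in for residual registration error;
a "focused second pass" scales the field down inside one ROI's bounding
box, emulating a refinement registration restricted to that region.

Because the field is known, every downstream recovery test has exact ground
truth — which an optimized black-box registration could never provide.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from itertools import product
from pathlib import Path

import numpy as np

from contourvar.contour_io import PlanarContour, StructureSet, validate_structure_set

__all__ = [
    "BSplineDisplacementField",
    "FieldSpec",
    "evaluate_field",
    "apply_to_structure",
    "random_smooth_field",
    "focused_second_pass",
]


def _bspline_basis(t: np.ndarray) -> np.ndarray:
    """Uniform cubic B-spline basis values; columns sum to one.

    Returns shape (len(t), 4) for the four control points supporting a
    point with local coordinate ``t`` in [0, 1).
    """
    t2, t3 = t * t, t * t * t
    b0 = (1 - t) ** 3 / 6.0
    b1 = (3 * t3 - 6 * t2 + 4) / 6.0
    b2 = (-3 * t3 + 3 * t2 + 3 * t + 1) / 6.0
    b3 = t3 / 6.0
    return np.stack([b0, b1, b2, b3], axis=1)


def _smoothstep(x: np.ndarray) -> np.ndarray:
    """Quintic smoothstep: 0 at 0, 1 at 1, C2 everywhere."""
    x = np.clip(x, 0.0, 1.0)
    return x * x * x * (x * (6 * x - 15) + 10)


def _box_window(points: np.ndarray, lower: np.ndarray, upper: np.ndarray,
                taper_mm: float) -> np.ndarray:
    """1 inside the box, smooth decay to exactly 0 beyond box + taper."""
    outside = np.maximum(lower - points, points - upper)  # (n, 3); <=0 inside
    d = np.max(outside, axis=1)
    if taper_mm <= 0:
        return (d <= 0).astype(float)
    return 1.0 - _smoothstep(d / taper_mm)


@dataclass
class FocusRegion:
    """Multiplicative local rescaling of a field inside a padded box."""

    lower_mm: np.ndarray
    upper_mm: np.ndarray
    scale: float
    blend_mm: float

    def factor(self, points: np.ndarray) -> np.ndarray:
        w = _box_window(points, np.asarray(self.lower_mm),
                        np.asarray(self.upper_mm), self.blend_mm)
        return 1.0 - (1.0 - self.scale) * w


@dataclass
class BSplineDisplacementField:
    """Cubic tensor-product B-spline displacement field on a regular lattice.

    ``coefficients`` has shape (nx, ny, nz, 3): one 3D displacement vector
    per control point.  Displacement is windowed to be exactly zero outside
    ``support_lower/upper`` plus ``taper_mm``; optional focus regions scale
    the field locally (second-pass emulation).
    """

    origin_mm: np.ndarray
    grid_spacing_mm: np.ndarray
    coefficients: np.ndarray
    support_lower_mm: np.ndarray
    support_upper_mm: np.ndarray
    taper_mm: float = 0.0
    focus_regions: list[FocusRegion] = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        self.grid_spacing_mm = np.asarray(self.grid_spacing_mm, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.support_lower_mm = np.asarray(self.support_lower_mm, dtype=float)
        self.support_upper_mm = np.asarray(self.support_upper_mm, dtype=float)
        if self.coefficients.ndim != 4 or self.coefficients.shape[3] != 3:
            raise ValueError("coefficients must have shape (nx, ny, nz, 3)")
        if any(n < 4 for n in self.coefficients.shape[:3]):
            raise ValueError("cubic support needs >= 4 control points per axis")
        if not np.all(self.grid_spacing_mm > 0):
            raise ValueError("grid spacing must be positive")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("coefficients must be finite")
        if self.taper_mm < 0:
            raise ValueError("taper width must be >= 0")

    @property
    def lattice_shape(self) -> tuple[int, int, int]:
        return self.coefficients.shape[:3]

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        return evaluate_field(self, points)

    # -- serialization ------------------------------------------------------

    def to_json_obj(self) -> dict:
        return {
            "origin_mm": self.origin_mm.tolist(),
            "grid_spacing_mm": self.grid_spacing_mm.tolist(),
            "lattice_shape": list(self.lattice_shape),
            "coefficients": self.coefficients.ravel().tolist(),
            "support_lower_mm": self.support_lower_mm.tolist(),
            "support_upper_mm": self.support_upper_mm.tolist(),
            "taper_mm": self.taper_mm,
            "focus_regions": [
                {"lower_mm": np.asarray(f.lower_mm).tolist(),
                 "upper_mm": np.asarray(f.upper_mm).tolist(),
                 "scale": f.scale, "blend_mm": f.blend_mm}
                for f in self.focus_regions
            ],
            "seed": self.seed,
        }

    @classmethod
    def from_json_obj(cls, obj: dict) -> "BSplineDisplacementField":
        shape = tuple(obj["lattice_shape"]) + (3,)
        return cls(
            origin_mm=obj["origin_mm"],
            grid_spacing_mm=obj["grid_spacing_mm"],
            coefficients=np.asarray(obj["coefficients"]).reshape(shape),
            support_lower_mm=obj["support_lower_mm"],
            support_upper_mm=obj["support_upper_mm"],
            taper_mm=obj["taper_mm"],
            focus_regions=[
                FocusRegion(np.asarray(f["lower_mm"]), np.asarray(f["upper_mm"]),
                            f["scale"], f["blend_mm"])
                for f in obj.get("focus_regions", [])
            ],
            seed=obj.get("seed"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_obj(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "BSplineDisplacementField":
        return cls.from_json_obj(json.loads(Path(path).read_text()))


@dataclass
class FieldSpec:
    """Controls for a random smooth field: target RMS, smoothness, seed."""

    rms_amplitude_mm: float
    correlation_length_mm: float
    seed: int

    def __post_init__(self) -> None:
        if self.rms_amplitude_mm < 0:
            raise ValueError("rms_amplitude_mm must be >= 0")
        if not self.correlation_length_mm > 0:
            raise ValueError("correlation_length_mm must be > 0")


def evaluate_field(fld: BSplineDisplacementField,
                   points: np.ndarray) -> np.ndarray:
    """Evaluate the displacement at 3D points (shape (n, 3) -> (n, 3)).

    Standard cubic FFD interpolation: the point with lattice coordinate u
    in cell i is supported by control points i-1..i+2 weighted by the
    uniform cubic basis (a partition of unity); indices are clamped at the
    lattice edge.  The result is multiplied by the support window and any
    focus-region factors.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("points must have shape (n, 3)")
    if not np.all(np.isfinite(points)):
        raise ValueError("points must be finite")
    nx, ny, nz = fld.lattice_shape
    u = (points - fld.origin_mm) / fld.grid_spacing_mm
    cell = np.floor(u).astype(int)
    t = u - cell
    bases = [_bspline_basis(t[:, ax]) for ax in range(3)]
    ns = (nx, ny, nz)
    idx = [np.clip(cell[:, ax][:, None] + np.arange(-1, 3)[None, :], 0, ns[ax] - 1)
           for ax in range(3)]
    disp = np.zeros_like(points)
    for mx, my, mz in product(range(4), repeat=3):
        w = bases[0][:, mx] * bases[1][:, my] * bases[2][:, mz]
        disp += w[:, None] * fld.coefficients[idx[0][:, mx], idx[1][:, my],
                                              idx[2][:, mz]]
    disp *= _box_window(points, fld.support_lower_mm, fld.support_upper_mm,
                        fld.taper_mm)[:, None]
    for region in fld.focus_regions:
        disp *= region.factor(points)[:, None]
    return disp


def apply_to_structure(fld: BSplineDisplacementField, ss: StructureSet,
                       warnings: list | None = None) -> StructureSet:
    """Warp every contour vertex by the field, keeping contours planar.

    Each displaced contour is re-projected onto the plane at the mean
    displaced z of its vertices; the maximum projection distance and any
    displaced contour that became non-simple are recorded in ``warnings``
    as (roi, z_mm, message) tuples (the distance statistic tolerates
    non-simple rings, so the contour is kept).
    """
    report_to = warnings if warnings is not None else []
    # one batched field evaluation for every vertex in the set
    keys = [(name, i) for name in ss.roi_names
            for i in range(len(ss.contours(name)))]
    all_pts = np.vstack([ss.contours(name)[i].points_3d() for name, i in keys])
    all_moved = all_pts + fld.evaluate(all_pts)
    offsets = np.cumsum([0] + [ss.contours(name)[i].n_vertices
                               for name, i in keys])
    moved_by_key = {
        key: all_moved[offsets[j]:offsets[j + 1]]
        for j, key in enumerate(keys)
    }
    roi_map: dict[str, list[PlanarContour]] = {}
    for name in ss.roi_names:
        out = []
        for i, c in enumerate(ss.contours(name)):
            moved = moved_by_key[(name, i)]
            zs = moved[:, 2]
            # already planar (zero or pure-translation field): keep z exact
            z_new = float(zs[0]) if np.ptp(zs) == 0.0 else float(np.mean(zs))
            proj = float(np.max(np.abs(moved[:, 2] - z_new)))
            if proj > 0.5:
                report_to.append(
                    (name, c.z_mm,
                     f"planarity projection moved a vertex by {proj:.3f} mm"))
            out.append(PlanarContour(z_mm=z_new, vertices=moved[:, :2]))
        roi_map[name] = out
    warped = StructureSet(study_id=ss.study_id, roi_map=roi_map)
    vrep = validate_structure_set(warped)
    for roi, z, msg in vrep.errors:
        if "not simple" in msg:
            report_to.append((roi, z, "displaced contour is not simple"))
    return warped


def _lattice_for_box(lower: np.ndarray, upper: np.ndarray,
                     spacing_mm: float, taper_mm: float):
    """Origin and shape of a lattice covering box + taper with a spare shell."""
    lo = lower - taper_mm - 2.0 * spacing_mm
    hi = upper + taper_mm + 2.0 * spacing_mm
    shape = np.maximum(np.ceil((hi - lo) / spacing_mm).astype(int) + 2, 4)
    return lo, tuple(int(n) for n in shape)


def _probe_grid(lower: np.ndarray, upper: np.ndarray, n_per_axis: int = 12):
    axes = [np.linspace(lower[ax], upper[ax], n_per_axis) for ax in range(3)]
    g = np.meshgrid(*axes, indexing="ij")
    return np.column_stack([a.ravel() for a in g])


def random_smooth_field(spec: FieldSpec,
                        support_lower_mm,
                        support_upper_mm,
                        taper_mm: float = 10.0) -> BSplineDisplacementField:
    """Seeded random field rescaled to an exact RMS amplitude.

    Control-point displacements are drawn i.i.d. Gaussian on a lattice
    whose spacing is the correlation length, then globally rescaled so the
    RMS displacement *magnitude* over a dense probe grid inside the support
    box equals ``rms_amplitude_mm`` (exactly, by construction).  Same seed,
    same field.
    """
    lower = np.asarray(support_lower_mm, dtype=float)
    upper = np.asarray(support_upper_mm, dtype=float)
    origin, shape = _lattice_for_box(lower, upper, spec.correlation_length_mm,
                                     taper_mm)
    rng = np.random.default_rng(spec.seed)
    coeff = rng.standard_normal(size=shape + (3,))
    fld = BSplineDisplacementField(
        origin_mm=origin,
        grid_spacing_mm=np.full(3, spec.correlation_length_mm),
        coefficients=coeff,
        support_lower_mm=lower,
        support_upper_mm=upper,
        taper_mm=taper_mm,
        seed=spec.seed,
    )
    if spec.rms_amplitude_mm == 0.0:
        fld.coefficients = np.zeros_like(coeff)
        return fld
    probe = _probe_grid(lower, upper)
    disp = fld.evaluate(probe)
    rms = float(np.sqrt(np.mean(np.sum(disp * disp, axis=1))))
    fld.coefficients = coeff * (spec.rms_amplitude_mm / rms)
    return fld


def focused_second_pass(fld: BSplineDisplacementField, focus_ss: StructureSet,
                        focus_roi: str, reduction: float,
                        pad_mm: float = 10.0,
                        blend_mm: float = 5.0) -> BSplineDisplacementField:
    """Model a refinement registration restricted to one ROI.

    Displacement inside the focus ROI's padded bounding box is scaled by
    (1 - reduction); it is unchanged far away and smoothly blended across
    ``blend_mm`` just outside the box.  The pad (default 10 mm) keeps the
    ROI surface — including its delineation-noise excursions — inside the
    fully reduced region.
    """
    if not 0.0 <= reduction <= 1.0:
        raise ValueError("reduction must be in [0, 1]")
    contours = focus_ss.contours(focus_roi)
    if not contours:
        raise ValueError(f"focus ROI {focus_roi!r} is empty")
    lower, upper = focus_ss.bounding_box(focus_roi)
    region = FocusRegion(lower_mm=lower - pad_mm, upper_mm=upper + pad_mm,
                         scale=1.0 - reduction, blend_mm=blend_mm)
    return replace(fld, coefficients=fld.coefficients.copy(),
                   focus_regions=list(fld.focus_regions) + [region])
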