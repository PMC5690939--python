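"""Seeded synthetic cohorts realizing the two-CT, two-observer contour schema.

Each simulated patient carries eight contour roles on two CT geometries:

========  =========================================================
ROI11     observer 1's contour on CT1 (primary for every comparison)
ROI21     observer 2's contour on CT1
ROI12     observer 1's contour on CT2
ROI22     observer 2's contour on CT2
ROI1D     ROI12 propagated back to CT1 by the (imperfect) registration
ROI2D     ROI22 propagated back to CT1
ROI1A     observer 1's recontour on CT1 (subset of patients)
ROI2A     observer 2's recontour on CT1
========  =========================================================

Noise model.  Each observer carries a *persistent* smooth bias field (SD
``sigma_inter_mm``) applied along the boundary normal for every contour
they draw on a given patient — one independent field per (observer,
patient) pair, fixed across all of that observer's sessions on that
patient.  Bias therefore cancels within an observer and accumulates
between observers, which is what makes intraobserver variation
structurally smaller than interobserver variation, while cohort-level
means still converge with patient count.  Every delineation session adds
a fresh smooth field (SD ``sigma_intra_mm``).  CT2 anatomy is CT1 anatomy
warped by a random smooth B-spline field; propagation back to CT1 is
modeled as *exact* inversion composed with a known residual B-spline field
whose per-axis RMS is ``sigma_def_mm`` (so the boundary-normal residual
displacement has SD ``sigma_def_mm``).  Because inversion is exact by
construction, CT2-side delineations are generated in CT1-frame geometry
and forward-warped, giving exact ground truth for every error source.

Randomness.  One master seed feeds a :class:`numpy.random.SeedSequence`;
one child is spawned per patient, and each patient child spawns a fixed
tuple of streams (anatomy jitter, anatomical-change field, residual
field, one per delineation session, one per observer bias), so any part
of a cohort is reproducible bit-for-bit from the master seed alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Callable, Iterable, Literal, Sequence

import numpy as np
import yaml

from contourvar.contour_io import (
    PlanarContour,
    StructureSet,
    StructureSetValidationError,
    ValidationReport,
    read_structure_set,
    validate_structure_set,
    write_structure_set,
)
from contourvar.deformation import (
    BSplineDisplacementField,
    FieldSpec,
    apply_to_structure,
    focused_second_pass,
    random_smooth_field,
)
from contourvar.random_fields import GaussianScalarField, ZeroField
from contourvar.surface_distance import _resample_ring

__all__ = [
    "PhantomSpec",
    "NoiseSpec",
    "PatientData",
    "CohortBundle",
    "generate_phantom_truth",
    "simulate_delineation",
    "simulate_cohort",
    "head_neck_phantoms",
    "pelvis_phantoms",
    "head_neck_noise",
    "pelvis_noise",
    "save_cohort",
    "load_cohort",
]

#: arc-length spacing of phantom truth polygons (mm)
TRUTH_ARC_SPACING_MM = 0.5

#: polygon area below which a delineation counts as collapsed (mm^2)
COLLAPSE_AREA_MM2 = 1.0

#: smoothness of the patient-to-patient anatomical change field (mm)
ANATOMY_CORRELATION_MM = 40.0

#: smoothness of the residual registration-error field (mm)
RESIDUAL_CORRELATION_MM = 25.0


@dataclass
class PhantomSpec:
    """Analytic organ stand-in sliced into planar contours.

    shapes and ``size_mm``:
      * ``ellipsoid`` — (a, b, c) semi-axes (eyes, bladder, prostate ...)
      * ``tube`` — (radius, length) along z (cord, rectum, larynx ...)
      * ``crescent`` — (outer_radius, inner_radius, inner_offset, length)
        along z (parotid-like concave cross-section)
    """

    roi_name: str
    shape: Literal["ellipsoid", "tube", "crescent"]
    size_mm: tuple
    center_mm: tuple = (0.0, 0.0, 0.0)
    slice_thickness_mm: float = 3.0

    def __post_init__(self) -> None:
        if self.slice_thickness_mm <= 0:
            raise ValueError("slice_thickness_mm must be > 0")
        n = {"ellipsoid": 3, "tube": 2, "crescent": 4}[self.shape]
        if len(self.size_mm) != n:
            raise ValueError(f"{self.shape} needs {n} size parameters")
        if any(s <= 0 for s in self.size_mm):
            raise ValueError("all size parameters must be > 0")


@dataclass
class NoiseSpec:
    """Magnitudes of the three boundary-noise sources plus simulation control.

    ``sigma_inter_mm``: SD of each observer's persistent bias field;
    ``sigma_intra_mm``: SD of per-session delineation noise;
    ``sigma_def_mm``: per-axis RMS of the residual registration-error field
    (equivalently, SD of the boundary-normal residual displacement);
    ``correlation_length_mm``: smoothness of all boundary noise fields;
    ``second_pass_reduction``: fractional shrinkage of the residual inside
    ROIs that receive a focused second registration pass.
    """

    sigma_inter_mm: float
    sigma_intra_mm: float
    sigma_def_mm: float
    correlation_length_mm: float = 10.0
    second_pass_reduction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma_inter_mm", "sigma_intra_mm", "sigma_def_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.correlation_length_mm > 0:
            raise ValueError("correlation_length_mm must be > 0")
        if not 0.0 <= self.second_pass_reduction <= 1.0:
            raise ValueError("second_pass_reduction must be in [0, 1]")


@dataclass
class PatientData:
    """All contour roles for one simulated patient plus ground truth."""

    patient_id: str
    sets: dict[str, StructureSet]
    truth_ct1: StructureSet
    truth_ct2: StructureSet
    #: CT2 delineations expressed in CT1 frame (the exact-inverse pullback);
    #: ROIiD differs from pullback[i] only by the injected residual field
    pullback: dict[int, StructureSet]

    def has_role(self, role: str) -> bool:
        return role in self.sets


@dataclass
class CohortBundle:
    """A realized cohort: per-patient contour roles and the ground truth."""

    patients: list[PatientData]
    phantoms: list[PhantomSpec]
    ground_truth_params: NoiseSpec
    recontour_subset: list[str]
    second_pass_rois: tuple[str, ...] = ()
    anatomical_rms_mm: float = 4.0

    @property
    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]

    @property
    def roi_names(self) -> list[str]:
        return [p.roi_name for p in self.phantoms]


# ---------------------------------------------------------------------------
# phantom truth
# ---------------------------------------------------------------------------


def _circle(cx: float, cy: float, rx: float, ry: float) -> np.ndarray:
    n = max(16, int(np.ceil(2 * np.pi * max(rx, ry) / TRUTH_ARC_SPACING_MM)))
    theta = 2 * np.pi * np.arange(n) / n
    return np.column_stack([cx + rx * np.cos(theta), cy + ry * np.sin(theta)])


def _crescent_xy(cx: float, cy: float, outer_r: float, inner_r: float,
                 offset: float) -> np.ndarray:
    from shapely.geometry import Point

    q_out = max(8, int(np.ceil((np.pi / 2) * outer_r / TRUTH_ARC_SPACING_MM)))
    q_in = max(8, int(np.ceil((np.pi / 2) * inner_r / TRUTH_ARC_SPACING_MM)))
    outer = Point(cx, cy).buffer(outer_r, quad_segs=q_out)
    inner = Point(cx + offset, cy).buffer(inner_r, quad_segs=q_in)
    shape = outer.difference(inner)
    if shape.is_empty or shape.geom_type != "Polygon":
        raise ValueError("crescent parameters do not yield a single polygon")
    xy = np.asarray(shape.exterior.coords)[:-1]
    # shapely exteriors are CCW for valid polygons; resample to uniform arc
    return _resample_ring(xy, TRUTH_ARC_SPACING_MM)


def generate_phantom_truth(spec: PhantomSpec, seed: int = 0) -> StructureSet:
    """Slice an analytic shape into planar polygons.

    Deterministic (the seed is accepted for interface symmetry but the
    geometry is analytic).  Polygon vertices sit at <= 0.5 mm arc spacing;
    slicing is symmetric about the shape centre and never lands exactly on
    a degenerate apex.  Raises if fewer than 3 planes intersect the shape.
    """
    cx, cy, cz = spec.center_mm
    dt = spec.slice_thickness_mm
    contours: list[PlanarContour] = []
    if spec.shape == "ellipsoid":
        a, b, c = spec.size_mm
        k_max = int(np.floor(c / dt - 0.5))
        for k in range(-k_max - 1, k_max + 2):
            z = cz + (k + 0.5) * dt
            frac = 1.0 - ((z - cz) / c) ** 2
            if frac <= 0:
                continue
            r = float(np.sqrt(frac))
            if min(a, b) * r < 3.0:  # skip degenerate apex slivers
                continue
            contours.append(PlanarContour(z, _circle(cx, cy, a * r, b * r)))
    elif spec.shape == "tube":
        radius, length = spec.size_mm
        k_max = int(np.floor(length / (2 * dt) - 0.5))
        for k in range(-k_max - 1, k_max + 2):
            z = cz + (k + 0.5) * dt
            if abs(z - cz) > length / 2:
                continue
            contours.append(PlanarContour(z, _circle(cx, cy, radius, radius)))
    elif spec.shape == "crescent":
        outer_r, inner_r, offset, length = spec.size_mm
        xy = _crescent_xy(cx, cy, outer_r, inner_r, offset)
        k_max = int(np.floor(length / (2 * dt) - 0.5))
        for k in range(-k_max - 1, k_max + 2):
            z = cz + (k + 0.5) * dt
            if abs(z - cz) > length / 2:
                continue
            contours.append(PlanarContour(z, xy.copy()))
    else:  # pragma: no cover - guarded by PhantomSpec
        raise ValueError(f"unknown shape {spec.shape!r}")
    if len(contours) < 3:
        raise ValueError(
            f"phantom {spec.roi_name!r} intersects fewer than 3 z planes"
        )
    return StructureSet(study_id=f"truth:{spec.roi_name}",
                        roi_map={spec.roi_name: contours})


def _merge(study_id: str, sets: Iterable[StructureSet]) -> StructureSet:
    roi_map: dict[str, list[PlanarContour]] = {}
    for ss in sets:
        for name in ss.roi_names:
            roi_map[name] = ss.roi_map[name]
    return StructureSet(study_id=study_id, roi_map=roi_map)


# ---------------------------------------------------------------------------
# delineation
# ---------------------------------------------------------------------------


def _outward_normals(vertices: np.ndarray) -> np.ndarray:
    """Per-vertex outward unit normals of a CCW polygon (in-plane)."""
    nxt = np.roll(vertices, -1, axis=0)
    prv = np.roll(vertices, 1, axis=0)
    tangent = nxt - prv
    norm = np.linalg.norm(tangent, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    tangent /= norm
    return np.column_stack([tangent[:, 1], -tangent[:, 0]])


def simulate_delineation(truth: StructureSet,
                         bias_field: Callable[[np.ndarray], np.ndarray] | None,
                         sigma_session_mm: float,
                         seed,
                         correlation_length_mm: float = 10.0) -> StructureSet:
    """One observer's delineation act: truth plus coherent boundary noise.

    Every boundary vertex moves along its local outward (in-plane) normal
    by ``bias_field(vertex) + session(vertex)`` where ``session`` is a
    fresh seeded smooth Gaussian field with pointwise SD
    ``sigma_session_mm``.  With zero bias and zero sigma the output equals
    the truth exactly.

    Raises
    ------
    StructureSetValidationError
        If a displaced polygon collapses (area < 1 mm^2), naming the plane.
    """
    session = (GaussianScalarField(sigma_session_mm, correlation_length_mm, seed)
               if sigma_session_mm > 0 else ZeroField())
    bias = bias_field if bias_field is not None else ZeroField()
    # batch the field evaluations over every vertex in the set
    ccw_verts: dict[tuple[str, int], np.ndarray] = {}
    pts_chunks = []
    for name in truth.roi_names:
        for i, c in enumerate(truth.contours(name)):
            verts = c.vertices
            if c.signed_area_mm2() < 0:  # enforce CCW so normals face outward
                verts = verts[::-1]
            ccw_verts[(name, i)] = verts
            pts_chunks.append(
                np.hstack([verts, np.full((len(verts), 1), c.z_mm)]))
    all_pts = np.vstack(pts_chunks)
    all_offsets = np.asarray(bias(all_pts)) + np.asarray(session(all_pts))
    bounds = np.cumsum([0] + [len(v) for v in ccw_verts.values()])
    roi_map: dict[str, list[PlanarContour]] = {}
    collapse = ValidationReport()
    for j, ((name, i), verts) in enumerate(ccw_verts.items()):
        c = truth.contours(name)[i]
        offset = all_offsets[bounds[j]:bounds[j + 1]]
        # an observer's contour never collapses through the structure core:
        # inward noise is clipped at 80% of the local centroid distance
        # (inactive except on sub-centimetre apex slices)
        centroid_dist = np.linalg.norm(verts - verts.mean(axis=0), axis=1)
        offset = np.maximum(offset, -0.8 * centroid_dist)
        moved = verts + offset[:, None] * _outward_normals(verts)
        new = PlanarContour(c.z_mm, moved)
        if abs(new.signed_area_mm2()) < COLLAPSE_AREA_MM2:
            collapse.errors.append(
                (name, c.z_mm, "delineation collapsed polygon (< 1 mm^2)"))
        roi_map.setdefault(name, []).append(new)
    if collapse.errors:
        raise StructureSetValidationError(collapse)
    return StructureSet(study_id=truth.study_id + ":delineated", roi_map=roi_map)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


def _jitter_phantom(spec: PhantomSpec, rng: np.random.Generator,
                    center_sd_mm: float, size_sd: float) -> PhantomSpec:
    center = tuple(np.asarray(spec.center_mm) + rng.normal(0, center_sd_mm, 3))
    factors = np.clip(1.0 + rng.normal(0, size_sd, len(spec.size_mm)), 0.75, 1.25)
    size = tuple(float(s * f) for s, f in zip(spec.size_mm, factors))
    return PhantomSpec(spec.roi_name, spec.shape, size, center,
                       spec.slice_thickness_mm)


def _seed_int(seq: np.random.SeedSequence) -> int:
    return int(seq.generate_state(1)[0] & 0x7FFFFFFF)


def simulate_cohort(phantoms: Sequence[PhantomSpec],
                    noise: NoiseSpec,
                    n_patients: int,
                    n_recontour: int = 5,
                    second_pass_rois: Sequence[str] = (),
                    anatomical_rms_mm: float = 4.0,
                    jitter_center_sd_mm: float = 8.0,
                    jitter_size_sd: float = 0.08,
                    missing: dict[str, Iterable[str]] | None = None) -> CohortBundle:
    """Generate a full cohort realizing the contour schema.

    Per patient: CT1 truth is the (jittered) phantom set; CT2 truth is CT1
    truth warped by a random anatomical-change field; observer contours on
    both CTs carry persistent observer bias plus fresh session noise;
    propagated contours ROIiD equal the CT2 delineation pulled back exactly
    and perturbed by one known residual field per patient (shared by both
    observers, as one registration serves the whole study).  ROIs listed in
    ``second_pass_rois`` additionally get ROIiD2 from the residual scaled by
    (1 - second_pass_reduction) inside that ROI.  The first ``n_recontour``
    patients also get same-CT recontours ROIiA.

    ``missing`` optionally removes named ROIs from given patients (the
    skip-and-log path downstream), mimicking structures absent from real
    cohorts.
    """
    if n_recontour > n_patients:
        raise ValueError("n_recontour must be <= n_patients")
    unknown = set(second_pass_rois) - {p.roi_name for p in phantoms}
    if unknown:
        raise ValueError(f"second_pass_rois not in phantoms: {sorted(unknown)}")
    master = np.random.SeedSequence(noise.seed)
    patient_seeds = master.spawn(n_patients)
    patients: list[PatientData] = []
    recontour_ids: list[str] = []
    missing = {k: set(v) for k, v in (missing or {}).items()}
    for p_index in range(n_patients):
        pid = f"p{p_index:03d}"
        streams = patient_seeds[p_index].spawn(11)
        (jitter_seq, anat_seq, resid_seq, s11, s21, pull1_seq, pull2_seq,
         a1_seq, a2_seq, bias1_seq, bias2_seq) = streams
        # observer bias: one smooth field per (observer, patient), held
        # fixed across every session that observer performs on this patient
        # so it cancels within-observer (VIA, VT) and accumulates between
        # observers (VIO)
        biases = {
            obs: (GaussianScalarField(noise.sigma_inter_mm,
                                      noise.correlation_length_mm, seq)
                  if noise.sigma_inter_mm > 0 else ZeroField())
            for obs, seq in ((1, bias1_seq), (2, bias2_seq))
        }
        rng = np.random.default_rng(jitter_seq)
        local = [_jitter_phantom(p, rng, jitter_center_sd_mm, jitter_size_sd)
                 for p in phantoms]
        truth1 = _merge(f"{pid}:CT1", [generate_phantom_truth(p) for p in local])
        lower, upper = truth1.bounding_box()
        anat = random_smooth_field(
            FieldSpec(anatomical_rms_mm, ANATOMY_CORRELATION_MM,
                      _seed_int(anat_seq)),
            lower - 15.0, upper + 15.0)
        truth2 = apply_to_structure(anat, truth1)
        truth2.study_id = f"{pid}:CT2"
        residual = random_smooth_field(
            FieldSpec(np.sqrt(3.0) * noise.sigma_def_mm,
                      RESIDUAL_CORRELATION_MM, _seed_int(resid_seq)),
            lower - 15.0, upper + 15.0)
        residual2 = residual
        for roi in second_pass_rois:
            residual2 = focused_second_pass(residual2, truth1, roi,
                                            noise.second_pass_reduction)
        sets: dict[str, StructureSet] = {}
        pullback: dict[int, StructureSet] = {}
        session_seeds = {(1, "s1"): s11, (2, "s1"): s21,
                         (1, "pull"): pull1_seq, (2, "pull"): pull2_seq,
                         (1, "a"): a1_seq, (2, "a"): a2_seq}
        for obs in (1, 2):
            delin = lambda seq: simulate_delineation(
                truth1, biases[obs], noise.sigma_intra_mm, seq,
                noise.correlation_length_mm)
            sets[f"ROI{obs}1"] = delin(session_seeds[(obs, "s1")])
            pull = delin(session_seeds[(obs, "pull")])
            pullback[obs] = pull
            sets[f"ROI{obs}2"] = apply_to_structure(anat, pull)
            sets[f"ROI{obs}D"] = apply_to_structure(residual, pull)
            if second_pass_rois:
                sets[f"ROI{obs}D2"] = apply_to_structure(residual2, pull)
            if p_index < n_recontour:
                sets[f"ROI{obs}A"] = delin(session_seeds[(obs, "a")])
        if p_index < n_recontour:
            recontour_ids.append(pid)
        for roi in missing.get(pid, ()):  # mimic un-contoured structures
            for ss in list(sets.values()) + [truth1, truth2] + list(pullback.values()):
                ss.roi_map.pop(roi, None)
        patients.append(PatientData(pid, sets, truth1, truth2, pullback))
    return CohortBundle(patients=patients, phantoms=list(phantoms),
                        ground_truth_params=noise,
                        recontour_subset=recontour_ids,
                        second_pass_rois=tuple(second_pass_rois),
                        anatomical_rms_mm=anatomical_rms_mm)


# ---------------------------------------------------------------------------
# presets mirroring the study design (30 HN patients / 10 ROIs,
# 20 pelvic patients / 3 ROIs, recontour subset of 5, two observers)
# ---------------------------------------------------------------------------


def head_neck_phantoms() -> list[PhantomSpec]:
    """Ten stylized head-and-neck organs-at-risk.

    Sizes are stylized: thin structures (cord, optic nerves) are thicker
    than anatomy so preset-level boundary noise cannot collapse a slice.
    """
    return [
        PhantomSpec("anterior_oral_cavity", "ellipsoid", (25, 18, 14), (0, 15, 40)),
        PhantomSpec("brainstem", "ellipsoid", (10, 11, 25), (0, -70, 95)),
        PhantomSpec("cord", "tube", (8, 120), (0, -80, -10)),
        PhantomSpec("left_eye", "ellipsoid", (12, 12, 12), (32, 25, 110)),
        PhantomSpec("right_eye", "ellipsoid", (12, 12, 12), (-32, 25, 110)),
        PhantomSpec("larynx", "tube", (18, 50), (0, -20, 5)),
        PhantomSpec("left_optic_nerve", "tube", (7.5, 30), (15, 8, 108)),
        PhantomSpec("right_optic_nerve", "tube", (7.5, 30), (-15, 8, 108)),
        PhantomSpec("left_parotid", "crescent", (22, 12, 9, 40), (55, -40, 55)),
        PhantomSpec("right_parotid", "crescent", (22, 12, 9, 40), (-55, -40, 55)),
    ]


def pelvis_phantoms() -> list[PhantomSpec]:
    """Three stylized male-pelvis structures."""
    return [
        PhantomSpec("prostate", "ellipsoid", (22, 24, 20), (0, 0, 0)),
        PhantomSpec("bladder", "ellipsoid", (40, 35, 32), (0, 35, 45)),
        PhantomSpec("rectum", "tube", (14, 70), (0, -45, 5)),
    ]


def head_neck_noise(seed: int = 0) -> NoiseSpec:
    """Default head-and-neck noise magnitudes (mm)."""
    return NoiseSpec(sigma_inter_mm=1.5, sigma_intra_mm=0.7, sigma_def_mm=1.5,
                     correlation_length_mm=10.0, second_pass_reduction=0.0,
                     seed=seed)


def pelvis_noise(seed: int = 0) -> NoiseSpec:
    """Default pelvic noise magnitudes (mm); second pass shrinks the
    residual by 15% inside the focused ROIs."""
    return NoiseSpec(sigma_inter_mm=2.0, sigma_intra_mm=1.3, sigma_def_mm=2.8,
                     correlation_length_mm=10.0, second_pass_reduction=0.15,
                     seed=seed)


# ---------------------------------------------------------------------------
# on-disk cohort layout: one directory per patient of JSON structure sets
# plus a YAML manifest with specs, seeds and ground-truth parameters
# ---------------------------------------------------------------------------


def save_cohort(bundle: CohortBundle, directory: str | Path) -> None:
    """Write the cohort as a directory tree of JSON structure sets.

    Layout: ``<dir>/manifest.yaml`` plus ``<dir>/<patient>/<role>.json`` for
    every contour role, with ground truth under ``truth_ct1/truth_ct2`` and
    the exact-inverse pullbacks under ``pullback_1/pullback_2``.  Output is
    deterministic: identical bundles serialize byte-identically.
    """
    from contourvar.contour_io import _to_json_obj
    import json

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for patient in bundle.patients:
        pdir = directory / patient.patient_id
        pdir.mkdir(exist_ok=True)
        named = dict(patient.sets)
        named["truth_ct1"] = patient.truth_ct1
        named["truth_ct2"] = patient.truth_ct2
        named["pullback_1"] = patient.pullback[1]
        named["pullback_2"] = patient.pullback[2]
        for role in sorted(named):
            text = json.dumps(_to_json_obj(named[role]), sort_keys=True,
                              separators=(",", ":"))
            (pdir / f"{role}.json").write_text(text + "\n")
    manifest = {
        "phantoms": [
            {"roi_name": p.roi_name, "shape": p.shape,
             "size_mm": list(p.size_mm), "center_mm": list(p.center_mm),
             "slice_thickness_mm": p.slice_thickness_mm}
            for p in bundle.phantoms
        ],
        "ground_truth_params": {
            "sigma_inter_mm": bundle.ground_truth_params.sigma_inter_mm,
            "sigma_intra_mm": bundle.ground_truth_params.sigma_intra_mm,
            "sigma_def_mm": bundle.ground_truth_params.sigma_def_mm,
            "correlation_length_mm":
                bundle.ground_truth_params.correlation_length_mm,
            "second_pass_reduction":
                bundle.ground_truth_params.second_pass_reduction,
            "seed": bundle.ground_truth_params.seed,
        },
        "recontour_subset": list(bundle.recontour_subset),
        "second_pass_rois": list(bundle.second_pass_rois),
        "anatomical_rms_mm": bundle.anatomical_rms_mm,
        "patients": [p.patient_id for p in bundle.patients],
    }
    (directory / "manifest.yaml").write_text(
        yaml.safe_dump(manifest, sort_keys=True))


def load_cohort(directory: str | Path) -> CohortBundle:
    """Read a cohort previously written by :func:`save_cohort`."""
    import json
    from contourvar.contour_io import _from_json_obj

    directory = Path(directory)
    manifest = yaml.safe_load((directory / "manifest.yaml").read_text())
    phantoms = [PhantomSpec(p["roi_name"], p["shape"], tuple(p["size_mm"]),
                            tuple(p["center_mm"]), p["slice_thickness_mm"])
                for p in manifest["phantoms"]]
    noise = NoiseSpec(**manifest["ground_truth_params"])
    patients = []
    for pid in manifest["patients"]:
        pdir = directory / pid
        loaded = {}
        for path in sorted(pdir.glob("*.json")):
            loaded[path.stem] = _from_json_obj(
                json.loads(path.read_text()), str(path))
        pullback = {1: loaded.pop("pullback_1"), 2: loaded.pop("pullback_2")}
        truth1 = loaded.pop("truth_ct1")
        truth2 = loaded.pop("truth_ct2")
        patients.append(PatientData(pid, loaded, truth1, truth2, pullback))
    return CohortBundle(patients=patients, phantoms=phantoms,
                        ground_truth_params=noise,
                        recontour_subset=list(manifest["recontour_subset"]),
                        second_pass_rois=tuple(manifest["second_pass_rois"]),
                        anatomical_rms_mm=manifest["anatomical_rms_mm"])
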