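"""Reading, writing and validating radiotherapy structure sets.

A structure set is a collection of named regions of interest (ROIs), each a
z-ordered stack of closed planar polygons in patient-based millimetre
coordinates (x = patient-left, y = patient-posterior, z = patient-superior).
Two on-disk dialects are supported: a canonical JSON format and a DICOM
RT-STRUCT adapter (CLOSED_PLANAR contours only).  All downstream geometry
relies on the conventions established here: implicit polygon closure
(last vertex connects back to the first; a duplicated closing vertex in a
file is normalized away on read) and millimetre patient coordinates with no
voxel indices anywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon

__all__ = [
    "PlanarContour",
    "StructureSet",
    "ValidationReport",
    "StructureSetError",
    "StructureSetFormatError",
    "StructureSetValidationError",
    "read_structure_set",
    "write_structure_set",
    "validate_structure_set",
]

#: tolerance below which two consecutive vertices count as duplicates (mm)
DUPLICATE_TOL_MM = 1e-9

#: polygons with less area than this are suspicious (warning, not error)
TINY_AREA_MM2 = 1.0


class StructureSetError(Exception):
    """Base class for structure-set I/O problems."""


class StructureSetFormatError(StructureSetError):
    """The file could not be parsed in the requested format."""


class StructureSetValidationError(StructureSetError):
    """The structure set violates a geometric or structural invariant."""

    def __init__(self, report: "ValidationReport"):
        self.report = report
        lines = [f"  {roi} @ z={z}: {msg}" for roi, z, msg in report.errors]
        super().__init__("invalid structure set:\n" + "\n".join(lines))


@dataclass
class PlanarContour:
    """A closed planar polygon at a fixed z plane.

    The polygon is implicitly closed: the last vertex connects back to the
    first.  ``vertices`` is an (n, 2) float array of (x, y) mm coordinates.
    """

    z_mm: float
    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array of (x, y) mm")
        # normalize a duplicated closing vertex (both conventions occur in
        # the wild; internally closure is always implicit)
        if len(v) >= 2 and np.linalg.norm(v[0] - v[-1]) <= DUPLICATE_TOL_MM:
            v = v[:-1]
        self.vertices = v
        self.z_mm = float(self.z_mm)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def perimeter_mm(self) -> float:
        edges = np.diff(np.vstack([self.vertices, self.vertices[:1]]), axis=0)
        return float(np.linalg.norm(edges, axis=1).sum())

    def signed_area_mm2(self) -> float:
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return float(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def points_3d(self) -> np.ndarray:
        """Vertices as an (n, 3) array with the constant z appended."""
        z = np.full((len(self.vertices), 1), self.z_mm)
        return np.hstack([self.vertices, z])


@dataclass
class StructureSet:
    """Named ROIs, each a stack of :class:`PlanarContour` sorted by z."""

    study_id: str
    roi_map: dict[str, list[PlanarContour]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, contours in self.roi_map.items():
            self.roi_map[name] = sorted(contours, key=lambda c: c.z_mm)

    @property
    def roi_names(self) -> list[str]:
        return sorted(self.roi_map)

    def contours(self, roi: str) -> list[PlanarContour]:
        if roi not in self.roi_map:
            raise KeyError(f"ROI {roi!r} not present in study {self.study_id!r}")
        return self.roi_map[roi]

    def bounding_box(self, roi: str | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned (lower, upper) corners in mm of one ROI or all."""
        names = [roi] if roi is not None else self.roi_names
        pts = np.vstack([c.points_3d() for n in names for c in self.contours(n)])
        return pts.min(axis=0), pts.max(axis=0)


@dataclass
class ValidationReport:
    """Located invariant breaches; empty ``errors`` means accepted."""

    errors: list[tuple[str, float, str]] = field(default_factory=list)
    warnings: list[tuple[str, float, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def _contour_is_simple(c: PlanarContour) -> bool:
    if c.n_vertices < 3:
        return False
    return _ShapelyPolygon(c.vertices).is_valid


def validate_structure_set(ss: StructureSet) -> ValidationReport:
    """Check every geometric and structural invariant of a structure set.

    Deterministic and order-independent: the report is identical however the
    ROIs were inserted.  Errors cover non-empty-ness, vertex counts,
    consecutive-duplicate vertices, finiteness, z ordering, and polygon
    simplicity; each is located by ROI name and z plane.
    """
    report = ValidationReport()
    for name in sorted(ss.roi_map):
        contours = ss.roi_map[name]
        if not contours:
            report.errors.append((name, float("nan"), "ROI has no contours"))
            continue
        last_z = None
        for c in contours:
            z = c.z_mm
            if not np.isfinite(z) or not np.all(np.isfinite(c.vertices)):
                report.errors.append((name, z, "non-finite coordinate"))
                continue
            if c.n_vertices < 3:
                report.errors.append(
                    (name, z, f"contour has {c.n_vertices} vertices (< 3)")
                )
                continue
            closed = np.vstack([c.vertices, c.vertices[:1]])
            steps = np.linalg.norm(np.diff(closed, axis=0), axis=1)
            if np.any(steps <= DUPLICATE_TOL_MM):
                report.errors.append((name, z, "consecutive duplicate vertices"))
                continue
            if not _contour_is_simple(c):
                report.errors.append((name, z, "polygon is not simple"))
                continue
            if abs(c.signed_area_mm2()) < TINY_AREA_MM2:
                report.warnings.append((name, z, "polygon area below 1 mm^2"))
            if last_z is not None and z < last_z:
                report.errors.append((name, z, "z planes not sorted"))
            last_z = z
    return report


def _require_valid(ss: StructureSet) -> None:
    report = validate_structure_set(ss)
    if not ss.roi_map:
        report.errors.append(("<structure set>", float("nan"), "no ROIs"))
    if not report.ok:
        raise StructureSetValidationError(report)


# ---------------------------------------------------------------------------
# JSON dialect: {"study_id": str, "rois": {name: [{"z": float, "xy": [[x,y],..]}]}}
# ---------------------------------------------------------------------------


def _to_json_obj(ss: StructureSet) -> dict:
    return {
        "study_id": ss.study_id,
        "rois": {
            name: [
                {"z": c.z_mm, "xy": [[float(x), float(y)] for x, y in c.vertices]}
                for c in ss.roi_map[name]
            ]
            for name in sorted(ss.roi_map)
        },
    }


def _from_json_obj(obj: dict, source: str) -> StructureSet:
    try:
        study_id = str(obj["study_id"])
        roi_map: dict[str, list[PlanarContour]] = {}
        for name, contours in obj["rois"].items():
            roi_map[name] = [
                PlanarContour(z_mm=c["z"], vertices=np.asarray(c["xy"], dtype=float))
                for c in contours
            ]
    except (KeyError, TypeError, ValueError) as exc:
        raise StructureSetFormatError(f"{source}: malformed JSON dialect ({exc})")
    return StructureSet(study_id=study_id, roi_map=roi_map)


# ---------------------------------------------------------------------------
# DICOM RT-STRUCT adapter (CLOSED_PLANAR contours, mm triplets)
# ---------------------------------------------------------------------------


def _read_rtstruct(path: Path) -> StructureSet:
    import pydicom

    try:
        ds = pydicom.dcmread(str(path))
    except Exception as exc:  # pydicom raises several parse error types
        raise StructureSetFormatError(f"{path}: not parseable as DICOM ({exc})")
    if getattr(ds, "Modality", None) != "RTSTRUCT":
        raise StructureSetFormatError(f"{path}: DICOM file is not an RTSTRUCT")
    names = {
        int(item.ROINumber): str(item.ROIName)
        for item in ds.StructureSetROISequence
    }
    roi_map: dict[str, list[PlanarContour]] = {}
    for roi_item in ds.ROIContourSequence:
        name = names[int(roi_item.ReferencedROINumber)]
        contours: list[PlanarContour] = []
        for c in getattr(roi_item, "ContourSequence", []):
            if str(c.ContourGeometricType) != "CLOSED_PLANAR":
                raise StructureSetFormatError(
                    f"{path}: unsupported contour type {c.ContourGeometricType} "
                    f"in ROI {name!r}"
                )
            data = np.asarray([float(v) for v in c.ContourData]).reshape(-1, 3)
            z = float(np.mean(data[:, 2]))
            contours.append(PlanarContour(z_mm=z, vertices=data[:, :2]))
        roi_map[name] = contours
    return StructureSet(study_id=str(getattr(ds, "StructureSetLabel", path.stem)),
                        roi_map=roi_map)


def _write_rtstruct(ss: StructureSet, path: Path) -> None:
    import pydicom
    from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.RTStructureSetStorage
    meta.MediaStorageSOPInstanceUID = generate_uid(entropy_srcs=[ss.study_id])
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTSTRUCT"
    ds.StructureSetLabel = ss.study_id
    ds.StructureSetROISequence = []
    ds.ROIContourSequence = []
    for number, name in enumerate(ss.roi_names, start=1):
        roi = Dataset()
        roi.ROINumber = number
        roi.ROIName = name
        roi.ReferencedFrameOfReferenceUID = generate_uid(entropy_srcs=[ss.study_id])
        ds.StructureSetROISequence.append(roi)
        rc = Dataset()
        rc.ReferencedROINumber = number
        rc.ContourSequence = []
        for c in ss.roi_map[name]:
            item = Dataset()
            item.ContourGeometricType = "CLOSED_PLANAR"
            item.NumberOfContourPoints = c.n_vertices
            triplets = []
            for x, y in c.vertices:
                triplets += [f"{x:.3f}", f"{y:.3f}", f"{c.z_mm:.3f}"]
            item.ContourData = triplets
            rc.ContourSequence.append(item)
        ds.ROIContourSequence.append(rc)
    ds.save_as(str(path), enforce_file_format=True)


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------

Format = Literal["json", "rtstruct"]


def read_structure_set(path: str | Path, format: Format = "json") -> StructureSet:
    """Read a structure set from ``path`` and validate it.

    Parameters
    ----------
    path:
        File to read.
    format:
        ``"json"`` for the canonical dialect, ``"rtstruct"`` for DICOM
        RT-STRUCT (CLOSED_PLANAR geometry, coordinates in mm).

    Raises
    ------
    StructureSetFormatError
        If the file cannot be parsed in the named format.
    StructureSetValidationError
        If a contour breaches a geometric invariant (open/degenerate
        polygons are never silently accepted).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "json":
        try:
            with open(path) as fh:
                obj = json.load(fh)
        except json.JSONDecodeError as exc:
            raise StructureSetFormatError(
                f"{path}: invalid JSON at byte {exc.pos} ({exc.msg})"
            )
        ss = _from_json_obj(obj, str(path))
    elif format == "rtstruct":
        ss = _read_rtstruct(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    _require_valid(ss)
    return ss


def write_structure_set(ss: StructureSet, path: str | Path,
                        format: Format = "json") -> None:
    """Write ``ss`` to ``path``; validation happens before any bytes hit disk.

    JSON output is deterministic (sorted keys, repr-faithful floats) so
    writing the same structure set twice yields byte-identical files.
    """
    _require_valid(ss)
    path = Path(path)
    if format == "json":
        text = json.dumps(_to_json_obj(ss), sort_keys=True,
                          separators=(",", ":"))
        path.write_text(text + "\n")
    elif format == "rtstruct":
        _write_rtstruct(ss, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def structure_sets_allclose(a: StructureSet, b: StructureSet,
                            tol_mm: float = 1e-9) -> bool:
    """True when both sets hold the same ROIs with vertices within ``tol_mm``."""
    if a.roi_names != b.roi_names:
        return False
    for name in a.roi_names:
        ca, cb = a.roi_map[name], b.roi_map[name]
        if len(ca) != len(cb):
            return False
        for pa, pb in zip(ca, cb):
            if abs(pa.z_mm - pb.z_mm) > tol_mm:
                return False
            if pa.vertices.shape != pb.vertices.shape:
                return False
            if not np.allclose(pa.vertices, pb.vertices, rtol=0, atol=tol_mm):
                return False
    return True
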