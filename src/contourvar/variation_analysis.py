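"""Per-contour-pair variation measurements VIO, VT, VIA from a cohort.

All comparisons use the directed mean surface distance with the CT1
original contour (ROI11 or ROI21) as the primary surface:

* VIO — ROI11 vs ROI21, one record per patient;
* VT  — ROIi1 vs ROIiD for each observer, two records per patient, so the
  VT sample size is twice the VIO sample size;
* VIA — ROIi1 vs ROIiA for each observer on the recontour subset
  (default 5 patients, hence 10 records);
* VDEF_TRUE — the generator's ground truth: the CT2 pullback vs the
  propagated contour, isolating the injected residual registration error.

Patients missing an ROI are skipped and logged (never imputed); the per-ROI
record count N therefore varies exactly the way real cohorts' do.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from contourvar.surface_distance import (
    DEFAULT_SPACING_MM,
    directed_mean_surface_distance,
    sample_surface,
    symmetric_mean_surface_distance,
)
from contourvar.synthetic_data import CohortBundle, PatientData

__all__ = [
    "VariationRecord",
    "SummaryRow",
    "compute_vio",
    "compute_vt",
    "compute_via",
    "compute_vdef_true",
    "summarize",
    "records_to_frame",
    "summaries_to_frame",
]

logger = logging.getLogger(__name__)

Quantity = Literal["VIO", "VT", "VT2", "VIA", "VDEF_TRUE", "VDEF2_TRUE"]


@dataclass
class VariationRecord:
    """One measured surface distance between two contour roles."""

    patient_id: str
    roi: str
    quantity: Quantity
    observer: int | None  # None for VIO (needs both observers)
    value_mm: float
    n_points: int

    def __post_init__(self) -> None:
        if self.value_mm < 0:
            raise ValueError("value_mm must be >= 0")
        if (self.observer is None) != (self.quantity == "VIO"):
            raise ValueError("observer is None exactly for VIO records")


@dataclass
class SummaryRow:
    """Mean +/- SD cell for one (roi, quantity) group."""

    roi: str
    quantity: Quantity
    n: int
    mean_mm: float
    sd_mm: float
    single_sample: bool = False  # sd is 0 by convention when n == 1

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd_mm < 0:
            raise ValueError("sd_mm must be >= 0")


def _distance(primary_ss, secondary_ss, roi: str, spacing_mm: float,
              symmetric: bool):
    pa = sample_surface(primary_ss, roi, spacing_mm)
    pb = sample_surface(secondary_ss, roi, spacing_mm)
    if symmetric:
        return symmetric_mean_surface_distance(pa, pb)
    return directed_mean_surface_distance(pa, pb)


def _patients_with(bundle: CohortBundle, roi: str,
                   roles: Sequence[str]) -> list[PatientData]:
    found = []
    for p in bundle.patients:
        if all(r in p.sets and roi in p.sets[r].roi_map for r in roles):
            found.append(p)
        else:
            logger.info("skipping patient %s for roi %s (missing one of %s)",
                        p.patient_id, roi, list(roles))
    if not found:
        raise ValueError(f"ROI {roi!r} absent for every patient")
    return found


def compute_vio(bundle: CohortBundle, roi: str,
                spacing_mm: float = DEFAULT_SPACING_MM,
                symmetric: bool = False) -> list[VariationRecord]:
    """Interobserver variation: observer 1 vs observer 2 on CT1.

    One record per patient; observer 1's contour is primary (a symmetric
    mode is available as a sensitivity check).
    """
    records = []
    for p in _patients_with(bundle, roi, ("ROI11", "ROI21")):
        res = _distance(p.sets["ROI11"], p.sets["ROI21"], roi, spacing_mm,
                        symmetric)
        records.append(VariationRecord(p.patient_id, roi, "VIO", None,
                                       res.mean_mm, res.n_primary))
    return records


def compute_vt(bundle: CohortBundle, roi: str,
               spacing_mm: float = DEFAULT_SPACING_MM,
               symmetric: bool = False,
               second_pass: bool = False) -> list[VariationRecord]:
    """Total variation: original CT1 contour vs propagated CT2 contour.

    Two records per patient (one per observer), ROIi1 primary.  With
    ``second_pass=True`` the focused-registration contour ROIiD2 is the
    secondary and records carry quantity ``VT2``.
    """
    suffix = "D2" if second_pass else "D"
    quantity: Quantity = "VT2" if second_pass else "VT"
    records = []
    for p in _patients_with(bundle, roi, (f"ROI1{suffix}", f"ROI2{suffix}")):
        for obs in (1, 2):
            res = _distance(p.sets[f"ROI{obs}1"], p.sets[f"ROI{obs}{suffix}"],
                            roi, spacing_mm, symmetric)
            records.append(VariationRecord(p.patient_id, roi, quantity, obs,
                                           res.mean_mm, res.n_primary))
    return records


def compute_via(bundle: CohortBundle, roi: str,
                spacing_mm: float = DEFAULT_SPACING_MM,
                symmetric: bool = False) -> list[VariationRecord]:
    """Intraobserver variation: original vs recontour on CT1 (subset)."""
    if not bundle.recontour_subset:
        raise ValueError("cohort has no recontour subset")
    subset = [p for p in bundle.patients
              if p.patient_id in set(bundle.recontour_subset)]
    records = []
    for p in subset:
        if not all(f"ROI{o}A" in p.sets and roi in p.sets[f"ROI{o}A"].roi_map
                   for o in (1, 2)):
            logger.info("skipping recontour patient %s for roi %s",
                        p.patient_id, roi)
            continue
        for obs in (1, 2):
            res = _distance(p.sets[f"ROI{obs}1"], p.sets[f"ROI{obs}A"], roi,
                            spacing_mm, symmetric)
            records.append(VariationRecord(p.patient_id, roi, "VIA", obs,
                                           res.mean_mm, res.n_primary))
    if not records:
        raise ValueError(f"no recontours available for ROI {roi!r}")
    return records


def compute_vdef_true(bundle: CohortBundle, roi: str,
                      spacing_mm: float = DEFAULT_SPACING_MM,
                      second_pass: bool = False) -> list[VariationRecord]:
    """Ground-truth registration error: CT2 pullback vs propagated contour.

    Available only for synthetic cohorts (the pullback is generator
    internal state); this is the reference the quadrature decomposition is
    validated against.
    """
    suffix = "D2" if second_pass else "D"
    quantity: Quantity = "VDEF2_TRUE" if second_pass else "VDEF_TRUE"
    records = []
    for p in _patients_with(bundle, roi, (f"ROI1{suffix}", f"ROI2{suffix}")):
        for obs in (1, 2):
            res = _distance(p.pullback[obs], p.sets[f"ROI{obs}{suffix}"], roi,
                            spacing_mm, symmetric=False)
            records.append(VariationRecord(p.patient_id, roi, quantity, obs,
                                           res.mean_mm, res.n_primary))
    return records


def summarize(records: Iterable[VariationRecord]) -> list[SummaryRow]:
    """Group records by (roi, quantity) into mean and sample SD (n-1).

    No rounding happens here; rounding is presentation-only and applied by
    the reporting layer.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to summarize")
    groups: dict[tuple[str, str], list[float]] = {}
    for r in records:
        groups.setdefault((r.roi, r.quantity), []).append(r.value_mm)
    rows = []
    for (roi, quantity) in sorted(groups):
        values = np.asarray(groups[(roi, quantity)])
        n = len(values)
        sd = float(np.std(values, ddof=1)) if n > 1 else 0.0
        rows.append(SummaryRow(roi=roi, quantity=quantity, n=n,
                               mean_mm=float(np.mean(values)), sd_mm=sd,
                               single_sample=(n == 1)))
    return rows


def records_to_frame(records: Iterable[VariationRecord]):
    """Tidy DataFrame, one row per record."""
    import pandas as pd

    return pd.DataFrame([
        {"patient_id": r.patient_id, "roi": r.roi, "quantity": r.quantity,
         "observer": "n/a" if r.observer is None else r.observer,
         "value_mm": r.value_mm, "n_points": r.n_points}
        for r in records
    ])


def summaries_to_frame(rows: Iterable[SummaryRow]):
    """Tidy DataFrame, one row per summary cell."""
    import pandas as pd

    return pd.DataFrame([
        {"roi": s.roi, "quantity": s.quantity, "n": s.n,
         "mean_mm": s.mean_mm, "sd_mm": s.sd_mm,
         "single_sample": s.single_sample}
        for s in rows
    ])
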