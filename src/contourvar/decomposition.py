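"""Quadrature decomposition of total variation and margin synthesis.

Total variation VT mixes two independent components: intraobserver
delineation noise VIA and residual registration error Edef.  Treating them
as independent population uncertainties gives the quadrature relation

    Edef = sqrt(VT^2 - VIA^2)

applied *per VT sample* against the ROI-level mean VIA (the intraobserver
sample is too small for per-patient pairing), so Edef inherits VT's sample
size and has a meaningful SD.  A negative discriminant is clamped to zero
and explicitly counted — never silently imagined away.  The combined
planning margin for a propagated contour is the quadrature sum

    margin = sqrt(Edef^2 + VIO^2)

using the second-pass Edef2 where a focused registration exists (the
default, configurable).  Rounding is presentation-only: half away from
zero to one decimal, applied to otherwise unrounded means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from contourvar.variation_analysis import SummaryRow, VariationRecord, summarize

__all__ = [
    "DecompositionResult",
    "edef_per_sample",
    "decompose",
    "combined_margin",
    "second_pass_reduction",
    "round_half_away",
]


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (1.25 -> 1.3, -1.25 -> -1.3)."""
    factor = 10.0 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def edef_per_sample(vt_value_mm: float, via_mean_mm: float) -> tuple[float, bool]:
    """One Edef sample: sqrt(max(vt^2 - via^2, 0)) with a clamp flag."""
    if vt_value_mm < 0 or via_mean_mm < 0:
        raise ValueError("inputs must be >= 0")
    disc = vt_value_mm ** 2 - via_mean_mm ** 2
    if disc <= 0:
        # vt == via == 0 is a genuine zero, not a clamp
        return 0.0, via_mean_mm > 0
    return math.sqrt(disc), False


def combined_margin(edef_mean_mm: float, vio_mean_mm: float) -> float:
    """Quadrature sum sqrt(Edef^2 + VIO^2), the combined expansion in mm."""
    if edef_mean_mm < 0 or vio_mean_mm < 0:
        raise ValueError("inputs must be >= 0")
    return math.hypot(edef_mean_mm, vio_mean_mm)


def second_pass_reduction(edef_mean_mm: float, edef2_mean_mm: float) -> float:
    """Percent decrease of the registration error after the focused pass."""
    if edef_mean_mm <= 0:
        raise ValueError("percent reduction undefined for Edef = 0")
    return 100.0 * (edef_mean_mm - edef2_mean_mm) / edef_mean_mm


@dataclass
class DecompositionResult:
    """Per-ROI decomposition: measured moments, Edef samples, margin."""

    roi: str
    vt_mean_mm: float
    vt_sd_mm: float
    via_mean_mm: float
    vio_mean_mm: float
    vio_sd_mm: float
    edef_records: list[float]
    edef_mean_mm: float
    edef_sd_mm: float
    clamped_count: int
    margin_mm: float
    edef2_records: list[float] = field(default_factory=list)
    edef2_mean_mm: float | None = None
    edef2_sd_mm: float | None = None
    clamped_count_2: int = 0
    margin_uses_second_pass: bool = True

    @property
    def n_edef(self) -> int:
        return len(self.edef_records)


def _edef_from_records(vt_records: Sequence[VariationRecord],
                       via_mean_mm: float) -> tuple[list[float], int]:
    samples, clamped = [], 0
    for r in vt_records:
        value, flag = edef_per_sample(r.value_mm, via_mean_mm)
        samples.append(value)
        clamped += int(flag)
    return samples, clamped


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    sd = float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0
    return float(np.mean(arr)), sd


def decompose(vt_records: Sequence[VariationRecord],
              via_summary: SummaryRow,
              vio_summary: SummaryRow,
              vt2_records: Sequence[VariationRecord] | None = None,
              margin_uses_second_pass: bool = True) -> DecompositionResult:
    """Decompose one ROI's measured variations into Edef and a margin.

    ``vt_records`` are the per-contour VT samples; ``via_summary`` and
    ``vio_summary`` are the matching ROI's summary cells.  When second-pass
    VT2 records exist, Edef2 is computed the same way and (by default)
    feeds the margin instead of Edef.
    """
    if not vt_records:
        raise ValueError("no VT records")
    rois = {r.roi for r in vt_records} | {via_summary.roi, vio_summary.roi}
    if vt2_records:
        rois |= {r.roi for r in vt2_records}
    if len(rois) != 1:
        raise ValueError(f"mixed ROIs in decomposition inputs: {sorted(rois)}")
    roi = rois.pop()
    if via_summary.quantity != "VIA" or vio_summary.quantity != "VIO":
        raise ValueError("summaries must be the VIA and VIO cells")

    vt_mean, vt_sd = _mean_sd([r.value_mm for r in vt_records])
    edef_samples, clamped = _edef_from_records(vt_records, via_summary.mean_mm)
    edef_mean, edef_sd = _mean_sd(edef_samples)

    edef2_samples: list[float] = []
    edef2_mean = edef2_sd = None
    clamped2 = 0
    if vt2_records:
        edef2_samples, clamped2 = _edef_from_records(vt2_records,
                                                     via_summary.mean_mm)
        edef2_mean, edef2_sd = _mean_sd(edef2_samples)

    margin_component = (edef2_mean if (margin_uses_second_pass
                                       and edef2_mean is not None)
                        else edef_mean)
    return DecompositionResult(
        roi=roi,
        vt_mean_mm=vt_mean, vt_sd_mm=vt_sd,
        via_mean_mm=via_summary.mean_mm,
        vio_mean_mm=vio_summary.mean_mm, vio_sd_mm=vio_summary.sd_mm,
        edef_records=edef_samples, edef_mean_mm=edef_mean, edef_sd_mm=edef_sd,
        clamped_count=clamped,
        margin_mm=combined_margin(margin_component, vio_summary.mean_mm),
        edef2_records=edef2_samples, edef2_mean_mm=edef2_mean,
        edef2_sd_mm=edef2_sd, clamped_count_2=clamped2,
        margin_uses_second_pass=margin_uses_second_pass,
    )
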