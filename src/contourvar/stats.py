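"""Two-sample t-tests comparing registration error against interobserver
variation, and the three-way significance classification.

Per ROI, the Edef sample (typically 2N contours) is compared with the VIO
sample (N patients) by an independent two-sample t-test at alpha = 0.05,
two-tailed.  The default is the classic pooled-variance Student statistic;
Welch's variant is available and worth inspecting because the two groups
have unequal sizes and, often, unequal variances.  No multiple-testing
correction is applied to the per-ROI verdicts; a Holm-adjusted column is
offered as clearly-labelled supplementary output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["ComparisonResult", "two_sample_t", "classify", "holm_adjust"]

Variant = Literal["pooled", "welch"]
Verdict = Literal["edef_less", "not_different", "edef_greater"]


@dataclass
class ComparisonResult:
    """Outcome of one ROI's Edef-vs-VIO comparison."""

    roi: str
    n_edef: int
    n_vio: int
    t_stat: float
    dof: float
    p_value: float
    alpha: float
    verdict: Verdict
    mean_edef_mm: float
    mean_vio_mm: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


def two_sample_t(group_a: Sequence[float], group_b: Sequence[float],
                 variant: Variant = "pooled") -> tuple[float, float, float]:
    """Independent two-sample t-test; returns (t, dof, two-tailed p).

    ``pooled`` is the classic Student statistic with dof = n_a + n_b - 2;
    ``welch`` uses the Welch-Satterthwaite degrees of freedom.  Degenerate
    groups with zero variance and equal means give (0, dof, 1) rather than
    a NaN.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("groups must be finite")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    equal_var = variant == "pooled"
    if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
        dof = float(len(a) + len(b) - 2)
        if np.mean(a) == np.mean(b):
            return 0.0, dof, 1.0
        sign = 1.0 if np.mean(a) > np.mean(b) else -1.0
        return sign * np.inf, dof, 0.0
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.df), float(res.pvalue)


def classify(roi: str, edef_records: Sequence[float],
             vio_records: Sequence[float], alpha: float = 0.05,
             variant: Variant = "pooled") -> ComparisonResult:
    """Three-way verdict: is registration error below, indistinguishable
    from, or above interobserver variation?

    ``not_different`` when p >= alpha; otherwise the sign of
    (mean Edef - mean VIO) picks the verdict.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    t, dof, p = two_sample_t(edef_records, vio_records, variant)
    mean_e = float(np.mean(edef_records))
    mean_v = float(np.mean(vio_records))
    if p >= alpha:
        verdict: Verdict = "not_different"
    elif mean_e < mean_v:
        verdict = "edef_less"
    else:
        verdict = "edef_greater"
    return ComparisonResult(roi=roi, n_edef=len(edef_records),
                            n_vio=len(vio_records), t_stat=t, dof=dof,
                            p_value=p, alpha=alpha, verdict=verdict,
                            mean_edef_mm=mean_e, mean_vio_mm=mean_v)


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values (supplementary output only)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted.tolist()
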