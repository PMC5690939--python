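"""Bar-chart rendering of the Edef-vs-VIO comparison (error bars = 1 SD)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_comparison"]


def plot_comparison(result, path: str | Path) -> None:
    """Grouped bars of mean Edef and mean VIO per ROI with 1-SD error bars."""
    decs = result.decompositions
    rois = sorted(decs)
    x = np.arange(len(rois))
    width = 0.38
    edef = [decs[r].edef_mean_mm for r in rois]
    edef_sd = [decs[r].edef_sd_mm for r in rois]
    vio = [decs[r].vio_mean_mm for r in rois]
    vio_sd = [decs[r].vio_sd_mm for r in rois]
    fig, ax = plt.subplots(figsize=(max(6, 1.0 * len(rois)), 4))
    ax.bar(x - width / 2, edef, width, yerr=edef_sd, capsize=3,
           label="registration error (Edef)")
    ax.bar(x + width / 2, vio, width, yerr=vio_sd, capsize=3,
           label="interobserver variation (VIO)")
    ax.set_xticks(x)
    ax.set_xticklabels(rois, rotation=45, ha="right")
    ax.set_ylabel("mean surface distance (mm)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
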