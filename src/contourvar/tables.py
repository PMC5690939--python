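"""Published summary values and the arithmetic cross-check against them.

The package ships a transcription of the published per-ROI summary tables
(mean +/- SD of VT, VIA, Edef, Edef2, VIO and the combined margin, in mm)
for ten head-and-neck and three pelvic structures.  ``reproduce_tables``
re-derives every derived cell from the printed inputs — Edef from the
quadrature relation on (VT, VIA), the margin from (Edef or Edef2, VIO) —
rounds for presentation, and diffs against the printed values.  Rows whose
printed derived value cannot be reproduced from their own printed inputs
(a rounded-input artifact in the source tables) are flagged, not patched.
"""

from __future__ import annotations

from importlib.resources import files

import numpy as np
import pandas as pd

from contourvar.decomposition import combined_margin, edef_per_sample, round_half_away

__all__ = ["load_printed_tables", "reproduce_tables", "combined_margin_range"]


def load_printed_tables() -> pd.DataFrame:
    """The transcribed published summary tables as a tidy DataFrame (mm)."""
    path = files("contourvar").joinpath("data/printed_tables.csv")
    with path.open() as fh:
        return pd.read_csv(fh)


def reproduce_tables(table: pd.DataFrame | None = None,
                     use_second_pass: bool = True) -> pd.DataFrame:
    """Recompute Edef and the combined margin from printed inputs and diff.

    Adds, per structure:

    * ``edef_recomputed`` — sqrt(VT^2 - VIA^2) from the printed means,
      rounded to one decimal, with ``edef_match`` against the printed Edef;
    * ``margin_recomputed`` — sqrt(Edef^2 + VIO^2) from the printed means
      (second-pass Edef2 where available, when ``use_second_pass``),
      rounded likewise, with ``margin_match`` against the printed margin.

    Mismatches are genuine inconsistencies of the printed rows with their
    own rounded inputs; they are reported so nobody mistakes them for
    implementation error.
    """
    df = (table if table is not None else load_printed_tables()).copy()
    required = {"structure", "vt_mean", "via_mean", "edef_mean", "vio_mean",
                "margin_printed"}
    if not required <= set(df.columns):
        raise ValueError(f"fixture missing columns: {sorted(required - set(df.columns))}")

    edef_raw = [edef_per_sample(vt, via)[0]
                for vt, via in zip(df["vt_mean"], df["via_mean"])]
    df["edef_recomputed"] = [round_half_away(v) for v in edef_raw]
    df["edef_match"] = np.isclose(df["edef_recomputed"], df["edef_mean"])

    margins = []
    used_second = []
    for _, row in df.iterrows():
        edef2 = row.get("edef2_mean", np.nan)
        use2 = use_second_pass and np.isfinite(edef2)
        component = edef2 if use2 else row["edef_mean"]
        margins.append(round_half_away(combined_margin(component,
                                                       row["vio_mean"])))
        used_second.append(bool(use2))
    df["margin_recomputed"] = margins
    df["margin_uses_second_pass"] = used_second
    df["margin_match"] = np.isclose(df["margin_recomputed"],
                                    df["margin_printed"])
    return df


def combined_margin_range(use_second_pass: bool = True) -> dict[str, tuple[float, float]]:
    """(min, max) recomputed combined margin per anatomical site (mm)."""
    df = reproduce_tables(use_second_pass=use_second_pass)
    out = {}
    for site, group in df.groupby("site"):
        out[str(site)] = (float(group["margin_recomputed"].min()),
                         float(group["margin_recomputed"].max()))
    return out
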