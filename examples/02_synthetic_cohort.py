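"""Generate a small synthetic cohort and measure its contour variations.

Ten patients, one tube-shaped organ, with known noise magnitudes:
interobserver bias SD 1.5 mm, per-session noise SD 0.7 mm, residual
registration error SD 1.5 mm.  VIO / VT / VIA are the interobserver,
total, and intraobserver mean surface distances of the contour schema.
"""

import numpy as np

from contourvar.synthetic_data import NoiseSpec, PhantomSpec, simulate_cohort
from contourvar.variation_analysis import (
    compute_via, compute_vio, compute_vt, summarize,
)

bundle = simulate_cohort(
    phantoms=[PhantomSpec("cordlike", "tube", (12, 80))],
    noise=NoiseSpec(sigma_inter_mm=1.5, sigma_intra_mm=0.7, sigma_def_mm=1.5,
                    seed=1),
    n_patients=10,
    n_recontour=5,
)

records = (compute_vio(bundle, "cordlike") + compute_vt(bundle, "cordlike")
           + compute_via(bundle, "cordlike"))
for row in summarize(records):
    print(f"{row.quantity:>4}: n={row.n:3d}  "
          f"{row.mean_mm:.2f} +/- {row.sd_mm:.2f} mm")
# Expect VIA < VIO (observer bias cancels within an observer) and the
# VT sample twice the size of the VIO sample (one record per observer).
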