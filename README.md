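# contourvar

**Contour-propagation uncertainty analysis for deformable image
registration (DIR) QA in radiotherapy planning.**

When contours are propagated from one CT to another through a deformable
registration — for adaptive re-planning or atlas-based auto-segmentation —
the propagated structure carries two entangled uncertainties: the residual
error of the registration itself and the ordinary variability of human
delineation.  `contourvar` implements the analysis that separates them and
turns them into a planning margin, for physicists and researchers
evaluating DIR workflows.

## The statistics

All contour comparisons use a **directed mean surface distance**: every
point sampled on the primary surface is matched to its closest point on
the secondary surface in 3D, and the per-point minima are averaged (the
maximum is the classic directed Hausdorff distance, reported as a
diagnostic).  With two observers contouring the same organs on two CTs
(CT2 deformably registered to CT1), three variations are measured per ROI:

| quantity | comparison | meaning |
|---|---|---|
| V<sub>IO</sub> | observer 1 vs observer 2, same CT | interobserver variation |
| V<sub>IA</sub> | original vs recontour, same observer, same CT | intraobserver variation |
| V<sub>T</sub>  | original CT1 contour vs propagated CT2 contour | total variation |

V<sub>T</sub> mixes intraobserver noise with residual registration error
E<sub>def</sub>; treating them as independent population uncertainties
gives the quadrature decomposition and the combined margin

```
Edef   = sqrt(VT^2 − VIA^2)          (per VT sample, ROI-level mean VIA)
margin = sqrt(Edef^2 + VIO^2)        (second-pass Edef2 when available)
```

Per ROI, the E<sub>def</sub> and V<sub>IO</sub> samples are compared with
an independent two-sample t-test (α = 0.05) and classified as
significantly less / not different / significantly greater.

Because no clinical cohort ships with the package, a **seeded synthetic
cohort generator** realizes the full contour schema (eight contour roles
per patient) from analytic organ phantoms with *known* interobserver,
intraobserver and registration-error magnitudes — so every stage of the
pipeline, including the quadrature decomposition itself, is validated
against ground truth.

## A worked example

`examples/02_synthetic_cohort.py` generates ten patients with one
tube-shaped organ and noise magnitudes σ_inter = 1.5 mm, σ_intra = 0.7 mm,
σ_def = 1.5 mm, then measures the variations:

```
 VIA: n= 10  0.79 +/- 0.09 mm
 VIO: n= 10  1.98 +/- 0.23 mm
  VT: n= 20  1.70 +/- 0.21 mm
```

What the numbers mean: intraobserver variation (0.79 mm ≈
0.7·√2·√(2/π)) is well below interobserver variation, because each
observer's persistent bias cancels against itself but not against the
other observer's; the V<sub>T</sub> sample is twice the V<sub>IO</sub>
sample (one record per observer per patient); and
√(V<sub>T</sub>² − V<sub>IA</sub>²) ≈ 1.5 mm recovers the injected
registration-error magnitude.

Other example scripts: `01_surface_distance.py` (the distance statistic on
concentric spheres), `03_reproduce_published_tables.py` (arithmetic
cross-check of published summary tables, including the rows that are
inconsistent with their own printed inputs), `04_full_pipeline.py`
(cohort → decomposition → margins → verdicts, with a focused second
registration pass on bladder and rectum).

There is also a thin CLI over the same library:

```
contourvar generate --preset pelvis --patients 20 --seed 1 --out cohort/
contourvar run --cohort-dir cohort/ --out analysis/
contourvar measure primary.json secondary.json --out distances.csv
contourvar reproduce-tables
```

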