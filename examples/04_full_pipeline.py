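"""End-to-end analysis on the pelvis preset (scaled to 8 patients).

Generates the three-structure pelvic cohort with a focused second
registration pass on bladder and rectum, then runs distances ->
quadrature decomposition -> margins -> t-test verdicts and writes the
report bundle (records/summary/margins/comparisons CSV + manifest).
"""

from contourvar.decomposition import second_pass_reduction
from contourvar.pipeline import RunConfig, run

result = run(RunConfig(preset="pelvis", n_patients=8, n_recontour=4,
                       seed=1, output_dir="scratch/pelvis_demo"))

print(result.margins.to_string(index=False))
print()
for roi, dec in result.decompositions.items():
    line = (f"{roi:>9}: Edef {dec.edef_mean_mm:.2f} mm "
            f"(clamped {dec.clamped_count})")
    if dec.edef2_mean_mm is not None:
        pct = second_pass_reduction(dec.edef_mean_mm, dec.edef2_mean_mm)
        line += f"  second pass {dec.edef2_mean_mm:.2f} mm (-{pct:.1f}%)"
    print(line)
print()
print(result.comparisons[["roi", "p_value", "verdict"]].to_string(index=False))
# margin_mm is the quadrature sum sqrt(Edef^2 + VIO^2) per ROI, using the
# second-pass Edef2 for the focused structures; the verdict says whether
# registration error is significantly below/above interobserver variation.
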