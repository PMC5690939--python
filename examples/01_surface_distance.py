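"""Directed mean surface distance between two ROI surfaces.

Builds two concentric sphere phantoms 2 mm apart, samples their contour
stacks at 0.5 mm arc length, and measures the separation.  The mean of the
per-point closest distances is the statistic used for all variation
measurements; the max is the classic directed Hausdorff distance.
"""

from contourvar import directed_mean_surface_distance, sample_surface
from contourvar.synthetic_data import PhantomSpec, generate_phantom_truth

inner = generate_phantom_truth(
    PhantomSpec("organ", "ellipsoid", (20, 20, 20), slice_thickness_mm=1.0))
outer = generate_phantom_truth(
    PhantomSpec("organ", "ellipsoid", (22, 22, 22), slice_thickness_mm=1.0))

a = sample_surface(inner, "organ", spacing_mm=0.5)
b = sample_surface(outer, "organ", spacing_mm=0.5)
res = directed_mean_surface_distance(a, b)

print(f"primary points : {res.n_primary}")
print(f"mean distance  : {res.mean_mm:.3f} mm   (geometric truth: 2.000 mm)")
print(f"max distance   : {res.max_mm:.3f} mm")
# The mean recovers the 2 mm shell separation; the max is slightly larger
# because contour stacks approximate the sphere surface near the poles.
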