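# Methods

## The measurement model

A structure set is a collection of named ROIs, each a z-ordered stack of
closed planar polygons in patient-based millimetre coordinates
(x patient-left, y patient-posterior, z patient-superior).  Polygons are
implicitly closed; multiple disjoint polygons may share a z plane; voxel
indices never appear in the data model, since the two CTs of a
contour-propagation study differ in field of view and slice thickness and
millimetre patient space is their only shared frame.

### Surface distance

The variation statistic is a directed mean surface distance.  Each
polygon's perimeter is resampled at uniform arc length (step ≤ 0.5 mm by
default, never fewer samples than vertices); an ROI surface is the union
of its resampled rings — no inter-slice mesh, no end caps, matching what
planar RT-STRUCT data actually contain.  For each point of the *primary*
surface the Euclidean distance to the nearest *secondary* point is found
with an exact KD-tree (an all-pairs brute-force oracle with the identical
contract backs the test suite), and the mean over primary points is
reported; the maximum is the directed Hausdorff distance.

The statistic is directed by design, and the orientation is fixed
globally: the CT1 original contour (ROI11 or ROI21) is always primary.
A symmetric mode (mean of the two directed means) exists as a sensitivity
diagnostic.  Point-to-point rather than point-to-segment distances are
used; the refinement-stability test bounds the discretization this
induces (< 2% change on halving the sampling step).  The default 0.5 mm
step is an order of magnitude below the smallest variation of interest
(~0.9 mm).

### Variation quantities and bookkeeping

Per ROI: V_IO compares the two observers' CT1 contours (one record per
patient); V_T compares each observer's CT1 original with their propagated
CT2 contour (two records per patient, so |V_T| = 2·|V_IO|); V_IA compares
original and recontour on a recontour subset (default 5 patients, 10
records).  Patients missing an ROI are skipped and logged, never imputed,
so per-ROI N varies exactly as real cohorts' do.  Summaries are mean and
sample SD (n−1); a single-record group reports SD 0 and is flagged.

### Quadrature decomposition and margins

E_def = sqrt(max(V_T² − V_IA², 0)) is applied per V_T sample against the
ROI-level *mean* V_IA — the only construction consistent with reporting
E_def at the V_T sample size with an SD, given that per-patient V_IA
exists only for the recontour subset.  Negative discriminants are clamped
to zero and counted explicitly; clamp counts surface in every report.
The combined planning margin is sqrt(E_def² + V_IO²), using the
second-pass E_def2 where a focused registration exists (configurable).
Quadrature inputs are never rounded; presentation rounding is half away
from zero to one decimal, applied last.

Bias of the estimator: because sqrt is concave and the V_IA mean is itself
estimated from 10 samples, per-sample quadrature subtraction carries a
small negative bias that grows as σ_intra approaches the deformation
signal; measured on the (σ_intra, σ_def) ∈ {0.5,1,2}×{1,2,3} mm grid at
30 patients it ranges from −2% to −11%, partly offset by the clamp's
positive bias.  The recovery tests assert the 15% envelope.

### Statistics

E_def vs V_IO per ROI: independent two-sample t-test, two-tailed,
α = 0.05, pooled variance by default with Welch's variant computed
alongside (the groups have unequal sizes, typically 2N vs N, and often
unequal variances, so the choice is material and both are reported).
Verdicts: `not_different` when p ≥ α, otherwise the sign of the mean
difference.  No multiple-testing correction is applied to the verdicts;
a Holm-adjusted column is emitted as clearly-labelled supplementary
output.

## The deformation model

Registration is represented by *known* displacement fields, never by an
optimized registration: a cubic tensor-product B-spline lattice (the
standard FFD basis, a partition of unity), windowed to be exactly zero
outside a support box plus a quintic-smoothstep taper band.  Random
fields draw i.i.d. Gaussian control-point vectors on a lattice whose
spacing is the correlation length, then rescale globally so the RMS
displacement magnitude over a fixed probe grid equals the target exactly.
A focused second registration pass is modelled as local error reduction:
the field is scaled by (1 − reduction) inside the focus ROI's bounding
box padded by 10 mm (so the ROI surface, including its noise excursions,
sees the full reduction) and blended smoothly outside.

Deformed contours are kept planar by re-projecting each contour onto the
plane at its mean displaced z; projections beyond 0.5 mm and contours
that become non-simple are recorded as warnings, not hidden.

## The synthetic cohort generator

The generator defines the study conditions: two observers, two CTs per
patient, eight contour roles (originals, CT2 contours, propagated
contours, recontours), 30-patient/10-ROI head-and-neck and
20-patient/3-ROI pelvis presets with a 5-patient recontour subset.

**Phantoms.**  Analytic shapes sliced at 3 mm (the CT protocols'
thickness): ellipsoids (eyes, brainstem, oral cavity, prostate, bladder),
tubes (cord, larynx, optic nerves, rectum), and a crescent cross-section
(parotids).  Sizes are stylized rather than anatomical — in particular
thin structures (cord 8 mm, optic nerves 7.5 mm radius) are thicker than
anatomy so preset-level boundary noise cannot collapse an apex polygon;
ellipsoid slicing skips apex slices thinner than 3 mm for the same
reason.  Per patient, phantom centres are jittered (SD 8 mm) and sizes
scaled (SD 8%), emulating anatomical variability.

**Noise.**  All boundary noise acts along the local outward in-plane
normal and is spatially smooth: stationary Gaussian fields with
squared-exponential covariance (correlation length 10 mm — the
coherence scale of human delineation error is about a centimetre),
realized by random Fourier features (384 features; pointwise SD exact to
a few percent, C-infinity, seeded).  Three sources:

* **observer bias** (σ_inter, HN preset 1.5 mm / pelvis 2.0 mm): one
  field per (observer, patient) pair, fixed across every session that
  observer performs on that patient.  Persistence within the pair makes
  bias cancel in within-observer comparisons (V_IA, V_T) and accumulate
  between observers (V_IO) — V_IA < V_IO emerges structurally.  Drawing
  per patient rather than once per cohort keeps cohort means ergodic: a
  single field realization has several-percent amplitude fluctuation
  that would otherwise bias a whole cohort coherently.
* **session noise** (σ_intra, 0.7 / 1.3 mm): a fresh field per
  delineation act.
* **registration residual** (σ_def, 1.5 / 2.8 mm): an isotropic 3D
  B-spline field (correlation 25 mm) rescaled so its per-axis RMS is
  σ_def, making the boundary-normal residual SD equal σ_def — the
  calibration under which V_T² ≈ V_IA² + (deformation distance)² closes.
  One residual field per patient, shared by both observers' propagated
  contours (one registration serves the study).

Inward noise is clipped at 80% of the vertex-to-centroid distance — an
observer's contour never collapses through the structure's core; the clip
is inactive on cross-sections above ~1 cm, so calibrations are
unaffected.  Preset magnitudes were chosen once to land the measured
summaries in the ranges reported for clinical cohorts; they are tuning,
not inference.

**CT2 and propagation.**  CT2 anatomy is CT1 anatomy warped by a random
anatomical-change field (RMS 4 mm, correlation 40 mm).  Propagation back
to CT1 is modelled as *exact* inversion composed with the residual field:
CT2-side delineations are generated in CT1-frame geometry ("pullback")
and forward-warped to produce the CT2 contours, while the propagated
contour is pullback + residual.  This sidesteps numerical inversion of a
B-spline field and gives exact ground truth (V_DEF_TRUE: pullback vs
propagated) for every recovery test.  The side effect — delineation noise
applied in CT1-frame rather than CT2-frame geometry — is second-order for
smooth anatomical fields.

**Determinism.**  One master seed feeds a `SeedSequence`; one child per
patient, each spawning a fixed tuple of streams (jitter, anatomy field,
residual field, one per session, one per observer bias).  Identical seeds
produce byte-identical serialized cohorts.

### What the generator does and does not emulate

It reproduces the *structure* of the study — the contour schema, the
sample-size bookkeeping, spatially coherent observer disagreement, a
persistent-bias mechanism that makes intraobserver variation smaller than
interobserver variation, and a controllable registration residual.  It
does not emulate image content, intensity-driven registration failure
modes, anatomically realistic organ shapes, time trends, or
structured/systematic observer disagreement at specific anatomical
boundaries.  Passing tests therefore demonstrate that the *analysis
pipeline* is correct and well calibrated under known noise, not that any
particular clinical DIR system achieves these numbers.

## Numerical choices

* Validation errors are precise and located (ROI, z plane); polygon
  simplicity is checked with exact geometric predicates.
* JSON is the canonical format (sorted keys, repr-faithful floats,
  byte-deterministic writes); DICOM RT-STRUCT is an adapter preserving
  coordinates to the 10^-3 mm decimal-string precision.
* Nearest-neighbour search is exact (KD-tree), never approximate;
  equality with the brute-force oracle to 10^-12 mm is a tested property.
* Zero-variance t-test groups with equal means return (t=0, p=1) rather
  than NaN.
* Degenerate planarization (zero or pure-translation fields) keeps z
  coordinates bit-exact instead of re-averaging.

## Problem sizes used in validation

Stochastic validations run at desk scale, chosen to estimate each
quantity's expectation well while keeping the suite quick: calibration
cohorts of 20–30 patients on single-organ phantoms, the 3×3 noise grid at
30 patients, the flat-limit calibration at 10^4 surface points, type-I
calibration at 1000 t-test replicates, and the full 30-patient/10-ROI
head-and-neck preset once for the structural bookkeeping check.

## Known limitations

* The per-sample quadrature estimator is biased low when intraobserver
  noise dominates the deformation signal (see above); this is a property
  of the estimator itself, inherited by any analysis built on it.
* Surfaces are ring stacks: distances between structures whose slice
  planes disagree (propagated contours) include a z-discretization
  component; it affects V_T and the ground-truth deformation distance
  coherently, so decomposition closes, but absolute values depend mildly
  on slice thickness.
* The second-pass model is parametric error reduction, not
  re-registration; recovered percent reductions are compressed by a few
  points relative to the injected field scaling because the
  z-discretization floor does not scale with the field.
* Interobserver bias has no systematic anatomical structure (e.g., both
  observers mis-placing the same boundary), which in real data makes
  V_IO an underestimate of true delineation error.
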