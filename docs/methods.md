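# Methods

This note documents the models behind `itvsim`, the parameters that matter,
the numerical choices, and what the simulation does and does not capture.

## Phantom and motion model

The phantom is a rigid sphere (default radius 1.5 cm) of target intensity 0
embedded in uniform lung medium of intensity −700 (CT-number-like, unitless;
only the contrast matters because segmentation thresholds are relative).
The target centre follows

    z(t) = A · cos(2πt/T + φ₀)

along the superior–inferior (SI) axis, with amplitude *A* (half
peak-to-peak; the sweep uses A = 0.5…2.0 cm so the motion *range* is
1–4 cm) and period T = 4 s (15 cycles/min). Optional lateral and
anterior–posterior components oscillate in phase, giving straight-line 3-D
paths for "virtual patient" runs; per-cycle period/amplitude jitter (seeded,
drawn independently per respiratory cycle so evaluation order never
matters) emulates irregular breathing. Defaults are jitter-free and fully
deterministic.

The grid is 0.1 × 0.1 cm in-plane with 0.125 cm slices (matching a 1.25 mm
slice width) and is auto-sized to contain the target at maximum excursion
plus a 1.5 cm pad (covering the largest margin used, 1 cm). Rasterization
marks voxels whose centres lie inside the sphere (with a ~1e-9 cm²
squared-distance slack so surface voxels never flip with coordinate
rounding — this keeps rasterization exactly translation-equivariant);
an optional partial-volume mode blends the boundary linearly over one mean
voxel width.

## 4DCT acquisition model

The respiratory cycle is divided into 10 uniform phase bins centred on
their labels, with the 0% bin centred on the cosine maximum (maximum
inhale) and 50% on maximum exhale. Each bin image is the uniform time
average of 8 rasterized snapshots at sub-interval midpoints inside the bin,
emulating reconstruction from projection data spanning the bin. Residual
intra-bin motion therefore blurs the target edge; with a 50% threshold the
segmented extent of a bin corresponds to the bin's *median* target
position, so the extreme-phase GTV centroids sit at ±A·cos(3π/80) ≈ ±0.993A
rather than exactly ±A. A snapshot-at-bin-centre mode is available
(`AcquisitionConfig(mode="center")`).

MIP and AIP are voxelwise maximum and mean over the 10 binned phases only
(projections from pre-binning snapshots are deliberately out of scope).

## Free-breathing scan model

The scanner parameters of the emulated free-breathing helical scan are not
fully determined by the scenario it models, so the model is explicitly
parameterized (`ScanModel`). Default: contiguous 2 cm axial slabs (16
slices × 1.25 mm, a 16-slice unit) acquired sequentially inferior→superior
at 0.5 s per slab (couch speed 4 cm/s), each slab being the uniform time
average of 8 snapshots over its acquisition window. Averaging is what
produces the interplay artifact's density loss: fast-moving target edges
average toward lung density and fall below the segmentation threshold, so
fast targets image truncated or distorted. A pure snapshot-per-slice model
was rejected because it conserves target density exactly and shows no
truncation. Because a single scan's respiratory start phase is arbitrary,
experiments sweep 8 uniformly spaced start phases and report per-phase and
mean results.

### A caveat on mean free-breathing volumes

For start phases where the scan plane travels *with* the ascending target,
the target stays near the plane for a long time and is imaged stretched;
the apparent-length excess grows like v/(v − v_target) (hyperbolically as
the target speed approaches the couch speed), whereas the compression for
opposing phases is bounded. Averaged over uniformly spaced start phases the
stretch excess outweighs the truncation loss, so the *mean* FB PTV volume
is roughly flat-to-slightly-increasing with motion range in this model
(6 of 8 start phases individually show the declining truncated target, and
couch speeds of 4–5.5 cm/s with slab- or rotation-window averaging all
behave the same way). Mean FB *Dice* agreement against the gold standard
does decline monotonically with range, and FB is the least faithful
strategy at every range. Single physical scans (one random start phase per
range, the realistic acquisition) most often land in the truncation regime.

## Delineation

Manual contouring is emulated by thresholding at 50% of the image's
dynamic range (the lung→target contrast) and keeping the largest connected
component (6-connectivity; ties broken toward the lowest label). A single
fixed relative threshold is reproducible where an observer is not; it
reproduces the gold-standard phantom volumes to a few percent. An image
with no contrast or no supra-threshold voxel yields an empty mask and an
`EmptyMaskWarning`, never an exception.

Strategies (PTV construction):

| strategy | ITV | margin |
|---|---|---|
| GS | union of 10 phase GTVs | 5 mm isotropic |
| FB | FB GTV (no ITV) | 5 mm axial, 10 mm SI |
| FB-Aug | FB GTV ∪ GTV₀% ∪ GTV₅₀% | 5 mm isotropic |
| AIP / MIP | projection GTV | 5 mm isotropic |

Boolean operations require exactly matching grids (tolerance 1e-6 cm); no
implicit resampling is performed.

### Margin morphology

Margins dilate with an *ellipsoidal* structuring element with semi-axes
(axial, axial, SI) in physical units, giving the rounded shoulders of
treatment-planning-system expansions (whether clinical systems expand
ellipsoidally or per-axis is not observable from volumes alone; ellipsoidal
was chosen and is what the capsule oracle assumes). Discretization matters
at 1–2 mm voxels: growing from the voxel-centre point cloud under-reaches
the physical margin by a curvature-dependent fraction of a voxel (−3% on
the 5 mm-grown sphere), while treating voxels as solid cubes over-reaches
(+9%). `expand_margin` therefore reconstructs the boundary at sub-voxel
resolution — trilinear upsampling of the binary field by a factor 3,
thresholded at 0.5 — and evaluates the margin-scaled Euclidean distance
transform on the fine grid before resampling at the original voxel centres.
Residual volume error is ≈1% at default resolution with no tuned constants.
A zero margin is the identity; work is confined to the padded bounding box
of the mask.

Under threshold segmentation the MIP mask is *exactly* the union of the
per-phase masks (a voxel's maximum exceeds the threshold iff some phase
does), so the MIP strategy coincides with the gold standard on the phantom
(R = 1.00, DSC = 1.00). Observer-based contouring on MIP images instead
tends to slightly over-include, which is why measured MIP ratios in the
emulated scenario's physical counterpart run a couple of percent high.
AIP behaves differently: its 50%-threshold target is the region occupied at
least half of the cycle, which shrinks in the middle ranges and changes
shape (a near-dumbbell) once the amplitude exceeds the target radius — AIP
volume is therefore *not* monotone in range under a fixed relative
threshold, unlike observer contours drawn at a generous lung window.

## Metrics

All overlap statistics are voxel-count based on a common grid. DSC of two
empty masks is defined as 1.0 (identical sets) and of one empty mask as 0.0;
these conventions only arise in degenerate tests. The capsule oracle
(4/3)πr³ + πr²L is exposed as `capsule_volume` and is linear in L with
slope πr². `motion_vector` is the Euclidean norm of per-axis displacement
components. For virtual patients, `ground_truth_m` is the norm of the
per-axis motion *amplitudes* (half peak-to-peak); the full
extrema-to-extrema displacement is recoverable from `centroid_extrema`
(clinical motion vectors in the cohort table follow the extrema
convention).

## Clinical cohort table

The packaged 17-patient table (checksum-validated on load) records motion
vector M ∈ [0.1, 2.2] cm, gold-standard PTV volume, and per-strategy
(R, DSC). Summaries are the arithmetic mean and standard deviation over the
17 patients; the sample convention (ddof = 1) is the default and both are
available — the published DSC spreads match ddof = 1, the FB-Aug ratio
spread matches ddof = 0. The ±10% acceptance window uses inclusive bounds
([0.90, 1.10], with a 1e-9 slack against float parsing), the unique
convention consistent with all three reproducible window percentages
(14/17, 11/17, 7/17); percentages round to the nearest integer. The FB
window percentage computed from the table is 24% (4/17) under any natural
boundary convention. One table row (patient 11, AIP) contains an R–DSC
pair that is mutually inconsistent (DSC ≤ 2R/(1+R) is violated); the table
is transcribed as printed.

## What the simulation does not capture

Rigid, non-deforming spherical target; uniform lung background with no
neighbouring soft tissue (MIP segmentation is therefore best-case); perfect
phase sorting (no irregular-breathing rebinning artifacts unless jitter is
enabled); no CT reconstruction physics (no sinograms, scatter, noise or
cardiac motion); threshold segmentation instead of observer contours — the
largest single source of difference from clinical numbers, most visible for
AIP. Clinical DSC/R values are taken from the cohort table, not recomputed
from patient images. Passing phantom tests shows the geometry, binning,
morphology and statistics are right; it does not certify performance on
deformable, irregular clinical targets.

## Problem sizes and determinism

Default experiment: four amplitudes, ~61 × 61 × (49–81) voxel grids, 10
bins × 8 snapshots, 8 start phases; the full sweep runs in well under a
minute on one CPU. All randomness (jitter only) flows from a single integer
seed; default runs are bit-reproducible.
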