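# Methods

## Scope and model

`halovasc` quantifies thin microvessels (cross-sections ≈1–75 µm²,
i.e. below ~10 µm diameter for round vessels) in 3D fluorescence stacks
of wall-stained tumor vasculature. Three descriptors are computed per
caliber class and sample: percent volume V%, the normalized volumetric
Halo index nHv (spatial dispersion), and wall/skeleton/lumen voxel
counts with their ratios. The underlying assumptions:

- vessels are bright on a dark background and only their walls are
  stained, so vessels appear as hollow tubes;
- the stack is, after resampling, an isotropic voxel grid, so pixel
  areas and dilation cycles are geometrically meaningful;
- vessel caliber can be *approximated* by the minimal Cartesian
  cross-section of the filled vessel (see Limitations).

## Preprocessing

**Isotropic resampling.** Output slice count is
`round(n_z × axial_pitch / lateral_pitch)`; interpolation is linear along
z (`order` configurable), intensities clamped to [0, 255]. Applying the
transform to an isotropic stack is the identity, so the operation is
idempotent.

**Slice contrast.** A slice is min–max stretched to 0–255 only when its
dynamic range strictly exceeds `min_dynamic_range` = 30 grey levels.
The strict gate keeps signal-free slices (pure background noise, range
typically well under 30) from having their noise amplified. Values are
rounded to nearest.

**Binarization.** The Rényi-entropy criterion of the standard
three-order family: entropy-maximizing thresholds at Rényi orders 1/2, 1
(Shannon limit) and 2 are combined with the β-weight rule (weights keyed
on whether candidates agree within 5 grey levels, blended by the
histogram mass between the outer candidates). One threshold is computed
from the pooled whole-stack histogram — per-slice thresholds
(`per_slice=True`) are available but cause slice-to-slice flicker in the
binary volume. Foreground is `voxel > threshold`. Ties in the entropy
curve resolve to the first maximizer; entropies below 1e-12 are snapped
to zero so degenerate two-level histograms behave deterministically.
The implementation is validated bin-exactly against an independent
re-derivation in the test suite.

## Caliber classification

1. **Particle filter.** A 26-connected component is deleted when the
   largest area among all of its 2D 8-connected in-slice components,
   over the three Cartesian orientations, is `< min_area_px` (default
   4 px ≈ 1 µm² at 0.54 µm pitch; the inequality is strict, so a 2×2×2
   cube with 4 px sections survives). Thin but long filaments survive
   through their lengthwise sections.
2. **Vessel fill.** 2D holes are filled independently in every slice of
   all three orientations and the results unioned with the input. A
   single 3D fill would miss tubes open at the stack faces; the
   slice-wise union also closes tubes oblique to one orientation via the
   other two. The operation is extensive and, on tubular structures,
   idempotent.
3. **Minimal Cartesian cross-section.** Per foreground voxel, the
   minimum over the three orientations of the area of the 2D 8-connected
   component containing it. Computed on the *filled* volume, so wall
   voxels inherit the section of their whole vessel rather than of their
   own 1-px wall.
4. **Binning.** Half-open bins `[lower, upper)` on pixel areas; the
   default preset (4, 8, 16, 32, 64, 128, 256 px) carries µm² labels
   `round(bound × pitch²)` = 1, 2, 5, 9, 19, 37, 75 at 0.54 µm. Areas
   at or above the top bound (large vessels) or below the bottom bound
   are excluded with label 0. Three further presets interleave the
   default in geometric progression (21 classes in total across the
   four) for redundant classification; the first set is the default.
5. **Wall/lumen.** Per-class wall masks are class masks ∩ unfilled
   input; lumen = filled − wall, a proxy for patent vessels.

Connectivity conventions (2D: 8-connected foreground, 3D: 26-connected)
follow common practice in this kind of image analysis; they are fixed
here and documented rather than configurable per call.

## Skeletonization

Filled vessels are thinned with Lee's decision-tree medial-axis
algorithm (the 3D path of `skimage.morphology.skeletonize`). The
skeleton is 1 voxel wide, a subset of the input, and preserves topology
(component count and loops; verified on cylinder and torus phantoms by
Euler characteristic). The whole volume is skeletonized once and the
skeleton split afterwards by the caliber map, so vessels are not cut at
class boundaries. Because a straight tube's skeleton count equals its
length ±end effects regardless of radius, `wall/skeleton` reads as
staining per unit vessel length and `lumen/wall` as an inverse wall
thickness — the two artifact controls for differential staining. Zero
denominators yield NaN, never silent division.

## Dispersion (Hv, nHv)

Rhombicuboctahedral dilation alternates the 6-neighbor 3D cross (odd
cycles) and the 3×3×3 cube (even cycles), approximating spherical growth
on the grid; growth clips at stack faces. The fill curve records
foreground counts per cycle from cycle 0; the volumetric Halo index is
the interpolated fractional cycle count at which the curve crosses the
target fraction (default 0.90):

    Hv = (c−1) + (target − f_{c−1}) / (f_c − f_{c−1}),

with Hv = 0 when the initial fraction already meets the target. The
cohort normalization count is the largest initial foreground count among
all volumes analyzed together (all per-class volumes of a run share one
normalization, making nHv comparable across classes and samples);
`norm_cycles` applies the same interpolation rule to absolute counts, and
nHv = Hv − norm_cycles. Choices that matter:

- **Parity** cross-first (configurable): Hv depends on it, so it is part
  of a run's recorded provenance.
- **Fractional norm_cycles** (default): integer truncation would add
  ±1-cycle quantization noise; `integer_norm=True` preserves the
  whole-cycle alternative.
- **Empty classes** propagate NaN (missing by design): the dispersion of
  an absent vessel class is not 0.
- Samples in one cohort must share stack dimensions; mismatches raise.

The dilation engine is verified cycle-by-cycle against a brute-force
shift-union oracle on random volumes, and the 3×3×3 center-voxel case is
checked against the hand-enumerated curve (counts 1, 7, 27; Hv = 1.865).

## Cohort statistics

Medians and 25–75% IQR (linear interpolation between order statistics)
summarize each treatment × class cell; nHv departs from normality, hence
medians rather than means. Pairwise comparisons: Welch's unequal-variance
t-test (two-tailed) on V%; unpaired Wilcoxon rank-sum on nHv, exact for
combined n ≤ 20 without ties, tie-corrected normal approximation
otherwise (the method used is recorded in the output). Star coding is
strict: p < 0.05/0.01/0.001. No multiple-testing correction is applied
by default — the significance grid reports raw per-cell p-values. Each
sample's relationship between quantity and dispersion across classes is
fit by least squares as nHv = a·V%² + b·V% + c with R²; the fit needs ≥3
distinct abscissae. Cells with insufficient data (absent classes,
degenerate samples) are flagged NaN/"na".

A reader for per-sample/per-class spreadsheet exports
(`read_metrics_workbook`) plus `fit_per_sample` re-runs the quadratic
fits on tabulated values; tests exercise it on synthetic workbooks
generated at test time.

## Synthetic phantoms

The generator emulates what the pipeline consumes: digital cylinders
(a voxel belongs to a tube if its center is within the radius of the
centerline segment — documented because class boundaries depend on it),
hollow when `wall_px < radius` with only the annulus bright, Gaussian
intensity noise clamped to [0, 255], homogeneous (uniform anchors) or
clustered (parent/offspring) layouts, and optional dim spherical blobs
mimicking intracellular staining. Blobs are rendered additively (stain
never darkens a pixel) and after the walls, so a blob-bearing phantom
shares its vessels bit-for-bit with the blob-free phantom of the same
seed. Anchors keep a radial margin from the faces so each tube's full
cross-section fits the stack and its ground-truth class is exact;
`snap_anchors=True` places centers on the lattice for exact digital-disc
arithmetic. Default intensities (walls 200 ± 10 on background 15 ± 3)
emulate well-stained vessels over a dark confocal background in which
signal-free slices stay below the 30-grey-level contrast gate. Matched
point-pattern phantoms (`point_phantom`, uniform vs parent/offspring at
exactly equal counts) isolate layout effects for dispersion tests.

What the phantoms do *not* emulate: branching, curvature, the
microscope's PSF and depth-dependent attenuation, shrinkage, and —
importantly — the biological coupling between vessel amount, caliber and
spatial arrangement in real perinecrotic tumor tissue. Random tube
layouts therefore do not reproduce the tight quadratic V%–nHv
relationship seen in real control tumors (the per-sample R² the
acceptance script reports for a random phantom cohort is an honest
consequence, typically ~0.5–0.7); passing tests validate the machinery,
not that synthetic tissue behaves like tumors.

## Problem sizes

Tests and the acceptance script use 20³–48³ stacks, 8 samples per arm
and 20 phantom pairs — sizes chosen so the digital-geometry ground truth
stays exact and the full suite runs in seconds while exercising every
code path; all operations scale directly to acquisition-sized stacks
(hundreds of voxels per edge).

## Known limitations

- The minimal Cartesian section over- or under-states a tilted tube's
  true cross-section by up to √2 at 45° tilt (factor 1/cos θ); calibers
  are indicative, not diameter estimates. Treatment comparisons are
  unaffected as long as treatments do not selectively reorient vessels.
- Hole filling cannot close a tube whose lumen is open to the background
  in all three orientations simultaneously (e.g. a short oblique stub at
  a corner).
- The Rényi threshold is histogram-global; strong depth-dependent
  attenuation would need per-slice thresholds (`per_slice=True`) at the
  cost of slice flicker.
- nHv is comparable only within one cohort (shared stack geometry and
  normalization count).
- Skeleton voxel output of the thinning algorithm is not bit-identical
  across implementations of the same algorithm family; all downstream
  guarantees are therefore topological and metric, not voxel-exact.
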