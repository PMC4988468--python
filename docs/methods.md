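# Methods

This note records the models, parameter choices, numerical conventions and
known limitations behind mesomap, in the spirit of a methods appendix.

## Coordinate and angle conventions

All tabulated coordinates are in μm with the origin at the image top-left
and y increasing downward (image convention). Pixel (row, col) maps to
(y, x) = (row, col) · `pixel_size_um`. Orientation angles live in the
frontal (section) plane with 0° = dorsal (−y), 90° = lateral (+x),
180° = ventral (+y), i.e. `angle = atan2(dx, −dy)`; the convention string
travels with every `OrientationSample` and can be redefined, e.g. by
`remap_to_distal_edge`, which rotates a sample so a stated distal-edge
direction maps to 180° (useful after shelf elevation, when the distal
edge points medially rather than ventrally). All circular statistics are
rotation invariant, so re-referencing never changes a test result.

## Synthetic tissue generator

The generator emulates the statistical structure of confocal sections of
embryonic palatal mesenchyme; it is the oracle for every downstream test.

* **Point process.** Dart-throwing (random sequential adsorption run to
  near-saturation: sampling stops after 2,500 consecutive rejections)
  with exclusion radius r(x) = 0.93 · s(x), where s is the local target
  spacing field. The constant was calibrated once by simulating the
  saturated process at constant spacing: the mean nearest-neighbour
  distance of the accepted set is 1.078 × the exclusion radius (5 seeds,
  200×200 μm), so r = s/1.078 makes realized spacing track the target;
  measured fields come out within ~1% of target. A soft-core process was
  chosen over a Poisson process because nuclei cannot interpenetrate;
  saturation makes density deterministic (≈ 0.68/r² points per unit
  area), which the density-scaling tests rely on. Candidates are
  accepted against the mean of the two local radii, so graded spacing
  fields pack correctly on both sides of a gradient. Points are
  generated strictly inside the domain polygon; there is no toroidal
  wrap, so fields carry real boundaries like tissue does.
* **Default study conditions.** 150×150 μm square domain at 10 μm target
  spacing → 170–190 nuclei per frame (the 100–200-cell regime of a
  typical validation region), labelling probability 0.4, nucleus radius
  3.0 ± 0.4 μm, pixel size 0.38 μm/px (typical for a 40× oil objective
  at 1024×1024; configurable, and asserted nowhere), background noise
  sd 5 on an 8-bit scale.
* **Rendering.** Each nucleus is an isotropic Gaussian with
  σ = radius/1.5 and peak 200, drawn with `max` compositing so touching
  nuclei form plateaus rather than summed hot spots; the label channel
  uses σ scaled by 0.7 and peak 150 inside labelled nuclei only.
  Intensities are clipped to the bit depth after adding Gaussian noise.
  With these defaults the global threshold 20 sits ~4 noise SDs above
  background and well below blob interiors. Blobs spanning < 2 px
  trigger an unresolvable-nuclei warning.
* **Seeding.** One global seed fans out through `numpy.random.SeedSequence`
  children to the placement, labelling, orientation, rendering and
  per-section stages, so each stage is independently reproducible and
  all outputs are bit-identical for a fixed seed.
* **Serial sections.** Each section is generated independently in the
  reference frame (sections 16 μm apart in the source protocol are
  uncorrelated at 10 μm nuclear spacing, so independence is the right
  model) and carried into its own raw frame by the inverse of its known
  rigid transform; `align_and_pool` applies the forward transforms back.
* **What it does not emulate.** No optics (PSF, depth attenuation,
  stitching seams), no nuclear shape anisotropy or intensity
  heterogeneity, no segmentation-adversarial clumping beyond soft-core
  contact, no correlation between label state and geometry, and no 3D
  structure. Passing counts on these panels therefore demonstrates that
  the recipe implementation is faithful and internally consistent — not
  that it would hit the same error bounds on real histology.

## Segmentation and label scoring

The nucleus recipe is: 3×3 median despeckle; global threshold (≥ 20);
binary erosion by 1 px (3×3 structuring element); watershed on the
Euclidean distance transform seeded at its regional maxima with minimum
seed separation of one expected nucleus radius (3 μm ≈ 8 px), which
separates touching pairs without shattering smooth blobs; strict area
filter (area < 9 μm² removed). Centroids are intensity-independent
(binary-mask centroids). Three steps of the source protocol ran on
proprietary tools; their open equivalents here are the median filter
(despeckle), marker-controlled watershed (touching-object separation),
and a moving-window mean-offset rule for the local-contrast threshold:
a pixel is label-positive when its intensity exceeds the local mean over
a 51-px window by more than the base threshold (10). These are standard
substitutes of equivalent intent, not claimed identical to the originals.

Label scoring restricts analysis to segmented nucleus masks, applies the
local-contrast threshold, removes components < 9 μm², fills holes,
dilates once (3×3) and clips back to the nucleus masks, filters at 9 μm²
again, and calls a nucleus positive on any ≥ 1 px overlap with a
surviving object (no overlap fraction is specified by the protocol; 1 px
is the most permissive deterministic rule). Both thresholds default to
an 8-bit scale — the protocol does not state a bit depth — and are
configurable along with every other parameter in `SegmentationParams`.

## Packing and proliferation maps

`delaunay_neighbors` wraps scipy's Qhull Delaunay triangulation;
cocircular ties resolve by Qhull's exact predicates. The raw packing
s_i is the mean incident-edge length; smoothing averages s over the cell
plus one corona by default. The protocol sentence defining the smoothing
is ambiguous between one and two coronas; both are implemented
(`smooth_depth`), with one corona as the default because deeper smoothing
visibly blurs the 8→14 μm gradients the maps exist to show. The
proliferation index uses the double corona as a *set* (no double
counting), so permuting point order never changes L_i.

**Hull handling.** Convex-hull cells have edges dominated by the tissue
boundary, not by packing. Hull cells are flagged; their raw values are
excluded from neighbours' smoothing averages by default
(`include_hull=True` restores plain averaging), from regional means, and
from colour autoscaling. Because smoothing has radius 1, boundary
contamination reaches one step inside the hull, so `interior_points`
defaults to graph distance > 2 from the hull; map statistics (e.g. the
gradient-recovery correlation) are read there. On synthetic gradient
fields this raises recovery r from ~0.7 (boundary-contaminated) to
0.90–0.99.

Pooling applies the per-section rigid transforms, concatenates, merges
points closer than 1e−6 μm (duplicates break triangulation predicates),
and expects callers to re-triangulate — pooling three sections of equal
density shrinks mean spacing by ≈ 1/√3, which the tests verify. Voronoi
tiles are closed at infinity by extending ridge rays far beyond the data
span and clipping to the domain polygon (or to the convex hull buffered
by the median nearest-neighbour distance when no domain is given); tile
areas then sum to the domain area to relative 1e−6. Colour ranges default
to the [2.5, 97.5] percentile of non-hull values, with a fixed-range
option for cross-stage comparability. Group comparisons use Welch's
unequal-variance two-sided t-test (the protocol says only "t-test";
Welch is the safer default), with p = 1 by convention when both groups
are constant and equal.

## Circular statistics

One-sample Watson U² uses the closed form on sorted normalized angles
u_i = θ_i/360; equispaced angles attain the analytic minimum 1/(12n)
exactly (tested to 1e−14). The asymptotic p-value is the exponential
series 2 Σ (−1)^(m−1) exp(−2m²π²U²), truncated when terms fall below
1e−10 and floored at that tolerance; a Monte-Carlo option resamples
uniform angles. The two-sample statistic is the classical rank form
U² = nm/N² Σ(d_k − d̄)² on the pooled circular ordering, with tie groups
taking the group-final CDF difference (midrank convention); p-values by
the same asymptotic series or by seeded permutation of pooled labels
(default 9,999). Calibration: both tests hold their 5% level within
[0.035, 0.065] over 2,000 null simulations at n = 50, and reject
κ = 2 von Mises alternatives at α = 0.01 in ≥ 95% of simulations.
P-values are reported raw; a Bonferroni correction is deliberately not
applied by default because multi-group circular ANOVA analogues are not
well developed and consumers should see the uncorrected values they are
told to treat conservatively.

Angle extraction excludes projections shorter than 0.5 μm (a near-axial
nucleus→Golgi offset carries no reliable in-plane direction); excluded
counts are reported on the sample rather than silently dropped. Rosettes
use half-open 30° bins [a, a+30°), so every angle lands in exactly one
bin, and radius √count so sector area is proportional to frequency.

## Shelf morphometry

The boundary line is the infinite line through the two annotated
landmarks; protrusion is the perpendicular distance from the distal
point to it ("through the centre" in the source description is read as
this perpendicular axis — the construction the measurement arrows
depict). If the perpendicular foot falls outside the landmark segment a
warning is raised and the infinite line is used. Thickness intersects
the outline with the line perpendicular to the protrusion axis at
protrusion/4 from the distal edge; when the cut crosses the outline more
than twice, the chord containing the axis station is used. The distal
point is annotator-supplied, with an automatic fallback to the outline
vertex farthest from the boundary line. Both measures are rigid-motion
invariant to 1e−9 and scale-equivariant; on rectangles
protrusion × thickness equals the area exactly. Landmarks must lie
within 1 μm of the outline. Stage summaries report mean ± SD (SD, not
SEM, and labelled as such), Welch t-tests per stage, and the usual
star classes; antero-posterior averaging is the unweighted mean over
supplied serial sections.

## Pipeline

`PipelineConfig` is a strict pydantic model (unknown keys rejected,
lossless YAML round-trip). `run_pipeline` executes synth → render →
segment → score → pool → maps → rosette and writes a provenance log
(config hash, package version, per-stage counts). Determinism: all CSV
outputs are byte-identical across re-runs with the same config.

## Problem sizes

Validation panels use ten 150×150 μm images (~180 nuclei each) per
recipe; oracle equivalence uses 100 random fields of 10–40 points
against an O(n⁴) empty-circumcircle enumeration; calibration uses 2,000
null simulations at n = 50 and 500-simulation power runs; gradient and
step-field recovery use single fields of ~500 and ~2,100 cells. These
sizes give stable statistics (binomial SEs well inside the tested
margins) while keeping the full suite fast.
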