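# mesomap

Spatial-cellular analysis of embryonic mesenchyme in 2D tissue sections,
built around the cell biology of palatal shelf development (where failure
of shelf outgrowth, elevation or fusion produces cleft palate). The
package answers three questions about a stained section: *how densely are
cells packed, where are they proliferating, and which way are they
polarized?* — plus gross shelf morphometry, all validated against a
synthetic tissue generator with complete ground truth.

## What it computes

**Nucleus segmentation and label scoring.** Nuclear-stain (DAPI) images
are segmented by: 3×3 median despeckle → global threshold (default 20 on
8-bit) → 1-px erosion → watershed separation of touching objects on the
distance transform → removal of objects < 9 μm². S-phase label (IddU/BrdU)
positivity is scored inside the segmented nuclei with a local-contrast
threshold (pixel > local mean + 10), speckle filtering at 9 μm², hole
filling, and dilate-and-clip consolidation of patchy staining.

**Cell-packing maps.** Nucleus centroids are the nodes of a Delaunay
triangulation; the local packing at cell *i* is the mean length *s*ᵢ of
its incident edges, smoothed over the cell and its neighbours:

&nbsp;&nbsp;&nbsp;&nbsp;*s̄*ᵢ = mean { *s*ⱼ : *j* ∈ {*i*} ∪ N(*i*) }

**Proliferation-index maps.** The local labelling index over the *double
corona* Rᵢ = {*i*} ∪ N(*i*) ∪ N(N(*i*)) is

&nbsp;&nbsp;&nbsp;&nbsp;*L*ᵢ = |labelled ∩ Rᵢ| / |Rᵢ| ∈ [0, 1]

Serial sections are registered by supplied rigid transforms, pooled, and
re-triangulated so both maps average across sections; values are rendered
as Voronoi tiles clipped to the tissue outline.

**Orientation statistics.** Nucleus→Golgi axes (a proxy for mesenchymal
cell polarity) are projected onto the frontal plane, binned into 30°
rosettes with radius √count (sector *area* ∝ frequency), and tested with
Watson's U²: one-sample against circular uniformity,

&nbsp;&nbsp;&nbsp;&nbsp;U² = Σᵢ (uᵢ − ū − (2i−1)/(2n) + ½)² + 1/(12n),

and the rank-based two-sample U² for homogeneity, with asymptotic
(p = 2 Σₘ (−1)^(m−1) e^(−2m²π²U²)) or resampling p-values.

**Shelf morphometry.** From an annotated outline: *protrusion* = the
perpendicular distance from the distal edge to the shelf-boundary
landmark line; *thickness* = the outline chord perpendicular to the
protrusion axis at one quarter of the protrusion from the distal edge;
Welch *t* comparisons per stage/genotype.

**Synthetic tissue.** Dart-throwing (saturated random sequential
adsorption) with a spatially varying exclusion radius reproduces soft-core
nuclear packing at a prescribed local spacing; Bernoulli labelling with a
spatial probability field; von Mises orientation samples; Gaussian-blob
channel rendering with background noise — everything with per-cell ground
truth, so every analysis stage can be validated end to end.

## Worked example

```bash
python examples/02_segment_and_score.py
```

```
ground-truth nuclei:     179
segmented nuclei:        179 (0.0% count error)
mean nucleus area:       45.6 μm²
true label-positive:     84
scored label-positive:   84 (0.0% error)
```

A 150×150 μm synthetic field (179 nuclei at ~10 μm spacing, 40% labelled)
is rendered to two channels and pushed through the full recipe; both the
nucleus count and the label-positive count match ground truth — on such
panels the count error stays within the 4% (nuclei) and 6%
(label-positive) validation bounds of the imaging protocol. The other
examples cover tissue synthesis, pooled packing/proliferation maps
(`examples/03` resolves an imposed 8→14 μm packing gradient and a
0.2/0.5 proliferation step from three pooled sections), orientation
rosettes with Watson tests, and shelf morphometry.

A thin CLI wraps the same functions:

```bash
mesomap synth --out demo --seed 1
mesomap segment --nuclear demo/nuclear.tif --label demo/label.tif --out demo/nuclei.csv
mesomap run --config config.yaml
```

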