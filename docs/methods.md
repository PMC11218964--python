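# Methods

## The measurement

`chromring` quantifies how fluorescence signal is distributed between the
periphery and the centre of a cell nucleus. The input is a two-channel
microscopy image — a genomic-DNA stain (channel *B*) and an epigenetic marker
such as an acetylated-histone stain (channel *A*) — either a single 2D plane
or a 3D z-stack with known voxel depth. The output is a set of ten
dimensionless ratios that compare integrated signal in three nested
concentric regions of the nucleus.

The procedure, per nucleus:

1. **Segmentation.** The DNA channel is thresholded (iterative IsoData by
   default), binarized, interior holes are filled, and one 8-connected
   component is kept (the seeded one, else the largest). The outer boundary
   is traced as a closed polygon by marching squares at level 0.5. In a
   z-stack this runs on every slice, and the per-slice boundary is applied to
   *all* channels, so both stains are always measured over identical
   geometry.
2. **Concentric splitting.** Each boundary polygon is shrunk toward its own
   area centroid (shoelace moments): `v_new = c + s · (v − c)`. Because this
   is a similarity transform, the shrunken polygon's area is exactly `s²`
   times the full area. With reduction fractions `r = 0.3333` and `0.6666`
   and `s = sqrt(1 − r)` ("area" mode, the default), the two inner regions
   hold 66.66% and 33.33% of the full area, so the three bands —
   peripheral (full − intermediate), intermediate (intermediate − center),
   and central (center) — are iso-area in 2D and iso-volume in 3D.
3. **Normalization.** A user-drawn rectangle in a nucleus-free area gives the
   background level. Per channel, `NF = (Σ per-slice background means /
   n_slices) × voxel_depth` in 3D (the depth factor is dropped in 2D), and
   every region's integrated density `IntDen = Σ intensities (× voxel_depth
   in 3D)` is corrected as `normalized = IntDen − NF × count`, where `count`
   is the region's pixel/voxel count.
4. **Ratios.** Band values telescope out of the nested regions and the ten
   ratios are formed: A/B, A1/B, A2/B, A3/B, A1/A, A2/A, A3/A, B1/B, B2/B,
   B3/B (1 = peripheral, 2 = intermediate, 3 = central). They are reported
   both as raw fractions and ×100.

## Model assumptions

- The nucleus is a single, simply-connected, roughly star-shaped object;
  concentric shrinking about the centroid nests by construction for
  star-shaped boundaries, and nesting is additionally enforced by
  intersecting each raster mask with its parent.
- "Concentric" means *similar to the boundary*, not equidistant from it:
  the construction scales the boundary polygon rather than peeling
  fixed-width shells (no distance transform). For elongated nuclei the
  peripheral band is correspondingly wider along the short axis.
- Background is an additive, spatially constant offset per channel,
  estimated from one rectangle and assumed valid across the frame (and, in
  3D, across slices via the per-slice means).
- In 3D, shrinking is per-slice about each slice's own centroid, matching
  per-slice edge detection; slices are independent geometrically and only
  the integrals are pooled.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `reductions` | `(0.3333, 0.6666)` | fraction of full area | area removed by each inner region; two reductions give the classic full/intermediate/center trisection |
| `mode` | `area` | — | `area`: `s = sqrt(1−r)`, regions iso-area; `linear`: `s = 1−r`, coordinates shrink by `r` (a 0.6666 coordinate shrink leaves only 11% of the area) |
| threshold `method` | `default_isodata` | — | Ridler–Calvard fixed point `t ← (mean(<t)+mean(≥t))/2` on raw values; `otsu`, `mean`, `manual` available |
| `pixel_width/height` | 0.07 | µm/px | lateral calibration (high-resolution nuclear imaging scale) |
| `voxel_depth` | 0.2 | µm/slice | z-spacing; enters `NF` and `IntDen` in 3D and cancels from every ratio |
| `per_slice_threshold` | off | — | default is one threshold from the maximum-intensity projection applied to all slices, which avoids z-flicker of the boundary; per-slice re-thresholding is available |
| `FilterCriteria` | all `None` | µm², intensity | optional per-slice windows on nucleus area and mean intensity; defaults accept everything |

Both shrink semantics are carried into the results metadata (`shrink_mode`
column) rather than silently chosen, because either reading is defensible;
`area` is the default since it is the only one that makes the three bands
equal-area, which is the point of an iso-regional analysis.

Normalized intensities may be negative when a region is dimmer than the
background estimate; they are flagged (`negative_bands`), never clipped,
because clipping would bias ratios silently.

Whether ratios should use normalized or raw integrated densities is left
switchable (`normalize=False`, CLI `--no-normalize`); normalization is the
default and is exact for additive offsets (see invariances below).

## The synthetic phantom generator

`synthgen` renders centred disk/ellipse nuclei (2D) or spheroid stacks (3D)
with per-channel radial intensity profiles `f(r/R)` (uniform, linear decay,
linear rise, Gaussian), an additive constant background over the whole
frame, and optional Gaussian noise clipped at zero. Spheroid slices taper as
`R·sqrt(1 − (z/c)²)` with `c = (n_slices+1)/2`, so end slices stay nonzero
and per-slice boundaries vary in size as in a real confocal stack. Defaults
mirror the emulated acquisition: 1024×1024 frame, 0.07 µm pixels, nucleus
radius 300 px, 0.2 µm voxel depth.

Because the concentric construction is a similarity transform, any radial
profile has an analytic expectation: band fractions are
`∫ 2πr f(r) dr` over the annuli `[R·s₁, R]`, `[R·s₂, R·s₁]`, `[0, R·s₂]`
divided by the disk total (closed form for uniform, adaptive quadrature
otherwise). `analyze(generate(spec)) ≈ expected_ratios(spec)` is the
package's primary end-to-end check; on a radius-300 phantom agreement is
within 0.01 absolute per ratio.

What the phantoms do **not** emulate: chromocenters and texture, non-convex
or lobed nuclei, uneven illumination, Poisson (signal-dependent) noise, and
axial PSF blur between slices. Passing tests therefore certify the
geometric/algebraic machinery — iso-area splitting, normalization, ratio
algebra, 2D/3D bookkeeping — not robustness to every feature of real
micrographs. One consequence is exercised deliberately: a profile that
decays to zero at the nuclear edge (linear decay) defeats automatic
thresholding *on that channel*, so oracle tests of that profile segment on
the phantom's uniform channel instead — the same synchronous-edge-selection
mechanism used when real DNA staining outlines the nucleus better than the
marker does.

## Numerical choices

- **Rasterization.** A pixel belongs to a polygon iff its centre
  `(x+0.5, y+0.5)` is inside or on the boundary (shapely point-in-polygon,
  vectorized over the bounding box). The rule is boundary-inclusive, which
  settles ties for vertices landing exactly on a shrunken edge.
- **Contours.** Marching squares at level 0.5 on the zero-padded binary
  mask, largest contour kept, collinear vertices dropped. Corner cells are
  bevelled by half a pixel (a 10×10 square yields area 99.5); for components
  ≥ 500 px the polygon area is within 2% of the pixel count, and the
  re-rasterized polygon reproduces the mask to < 1% of its pixels.
- **IsoData on raw values.** Iterating on the pixel values rather than a
  binned histogram makes the threshold translate *exactly* with an additive
  intensity offset, so masks — and hence every downstream ratio — are
  invariant to constant background shifts; iteration stops at a relative
  step below 1e-12 (≤ 500 iterations).
- **Degenerate inputs.** Constant planes reject automatic thresholds;
  empty foregrounds, multi-component masks, zero-area polygons, and regions
  rasterizing below 10 px raise with context. In stacks, slices that fail
  are omitted and the longest contiguous run of valid slices is kept.
- **Exact invariances** (unit-tested): band conservation
  `b1/b + b2/b + b3/b = 1` to 1e-9; voxel-depth cancellation from all ten
  ratios to 1e-12; background-offset cancellation to 1e-6; pre-rasterization
  shrink-area ratio exact to 1e-12.

## Statistics

Groups of per-nucleus ratio tables are summarized as mean ± sample SD
(n−1). Two-group comparisons use two-sided Welch's *t* by default (the
mean ± SD reporting convention suggests a parametric view), with
Mann–Whitney U as the distribution-free alternative; p-values are binned at
0.05 / 0.01 / 0.001 / 0.0001. No multiple-testing correction is applied by
default; a Holm option exists. These are reporting conventions, not claims
about any particular study's unstated test.

## Problem sizes used in the checked examples

The reference phantom for the split-fraction figures is the radius-300 px
uniform disk on a 1024×1024 frame; the radial-profile oracle and the
stochastic-stability check (10 replicates, noise SD = 5% of signal) use the
same geometry. Unit tests use radii 30–200 px on smaller frames, where the
rasterization error of the split fractions is already below 0.5 percentage
points and shrinks roughly linearly with radius.

## Known limitations

- One nucleus per analysis; touching nuclei are not split (choose one with a
  seed point).
- ImageJ `.roi` binaries and proprietary microscope formats are not read;
  ROIs use a documented JSON schema, images are TIFF.
- Linear-mode shrinking reproduces a coordinate-shrink reading of the
  construction literally and is *not* iso-area; it exists for comparison and
  is labelled in the output.
- The analytic ground truth covers the three-region (two-reduction) split;
  more reductions are analyzed numerically only.
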