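# Methods

## Scope and model

`rodmap` quantifies the 2D organisation of enamel rod profiles in a
transverse section of a rodent (mouse) mandibular incisor. The section is
modelled as a curved band between two polylines — the dentoenamel junction
(DEJ) on the inner side and the enamel surface on the outer side — with a
third polyline marking the boundary between the inner enamel layer
(oval rod profiles in alternating-tilt rows) and the outer enamel layer
(diamond-shaped profiles). Four profile categories are carried throughout:
`inner_mesial`, `inner_lateral` (oval inner-enamel profiles tilted toward
the mesial or lateral CEJ), `outer`, and `cej` (disorganised profiles near
the band termini). All tilt angles are axial quantities on [0°, 180°),
measured counterclockwise from the 3 o'clock direction with the y axis up;
the x axis runs lateral → mesial. The band is divided into four equal
regions of normalized x (region 1 = lateral, region 4 = mesial), where
normalized (virtual) coordinates are min/max-rescaled positions over the
enamel-layer bounding box.

## Measurement chain

**Thresholding and labelling.** Synthetic layers are clean (0 background),
so the default threshold keeps any non-zero intensity; thresholds and
polarity for real etched-section images are user-supplied. Connected
components use 8-connectivity (two pixels touching at a corner belong to
one profile), matching the common particle-analysis convention.

**Feret morphometrics.** Caliper lengths are computed on the convex hull
of the *pixel corners* (each pixel contributes its four corner points), so
a single-pixel particle has a long Feret of √2 and a short Feret of 1
rather than degenerate zeros. The long Feret is the hull diameter (maximum
over hull-vertex pairs); the short Feret is the minimum caliper width
(smallest over hull edges of the farthest vertex distance). The **Feret
angle**, however, is estimated from the maximal pair of *pixel centres*:
the corner cloud is the Minkowski sum of the centre set with a half-pixel
square, an anisotropic dilation that systematically drags the
maximal-distance direction toward the pixel diagonals (biases of 5–10° for
profiles ~12 px long). The centre hull has no diagonal preference, and
exactly tied maximal pairs are resolved by the axial circular mean of
their directions, falling back to the smallest angle when the tie is
perpendicular-degenerate (e.g. the two diagonals of a square, which
therefore reports 45°). With pointed-oval profiles ~23 px long this keeps
the per-profile angle error near ±1.5° and, critically, unbiased, so
pooled circular means recover the generating field to a few tenths of a
degree.

**Circular statistics.** Axial Feret angles are treated as plain
directions (not axial-doubled): with mean cosine C and sine S, the mean
direction is atan2(S, C), the resultant length R = √(C²+S²), and the
circular SD is √(−2 ln R) (radians, converted to degrees). The plain
(undoubled) convention is the one under which the circular mean of
{30°, 60°, 80°} is 57°, the field's standard check for this kind of tilt
data. The decussation angle of two mean directions is their smallest
absolute difference in [0°, 180°]; the alternating inter-row angle is
180° minus it, so the supplement identity holds exactly by construction.

**Row assembly.** Rows are recovered per tilt category by greedy
shortest-first linking of centroid pairs, gated at 2.5× the category's
median nearest-neighbour distance, under three structural constraints:
every profile carries at most two links (chains, not webs), accepted links
never close a cycle, and a link added at an occupied chain endpoint must
continue the chain — the angle between the incoming chain direction
(averaged over up to three links, so one laterally displaced member cannot
fold the test) and the new link must be ≥ 120°. Connected components of
the accepted links are the rows. A repair pass then re-joins
over-segmented chains whose endpoints lie within the gate when the
smoothed end directions are consistent with the bridging link (fragments
of < 3 members, too short to carry a direction, re-join on distance
alone). Chains shorter than 3 are flagged as orphan rows, never silently
dropped. Rows are numbered by along-band midpoint position
(lateral → mesial): rows are diagonal chains each spanning most of the
inner layer, so every midpoint sits near half depth and depth ordering
would be degenerate, while the mesial/lateral alternation used for
decussation pairing is a sequence along the band. Row summaries follow the
chain order; for near-vertical rows a pure x-sort would zigzag (successive
centroid x-deltas are smaller than the placement jitter) and inflate the
row length.

**Decussation by rows.** Adjacent pairs in along-band order must alternate
tilt; same-tilt neighbours (which occur near the band ends where only one
tilt is present) are skipped with a logged warning. Two variants are
reported: pair angles from whole-row circular means binned by the pair's
region, and a region-restricted variant that recomputes row means from
members inside each region — covering both ways such angles are computed
from grand means or row-by-row measurements.

**Thickness.** The outer-surface polyline is smoothed and its curvature
maximum located (mid-x for flat bands, where curvature is below numerical
noise); the measurement itself anchors on the *original* polyline point
(smoothing shrinks curved arcs inward by several pixels) and casts the
local surface normal to its intersections with the DEJ and the layer
boundary. Depth fractions use d(DEJ)/(d(DEJ)+d(surface)), exact for both
flat and curved bands.

## Synthetic map generator

The generator is the package's ground-truth instrument: it renders a band
(default: DEJ arc radius 540 μm, arclength 700 μm, total thickness 121 μm
of which 100 μm inner + 21 μm outer, at 16 px/μm) containing exactly
`total_profiles` (default 7233) profiles apportioned 70/27/3% to
inner/outer/CEJ by largest remainder, the inner profiles organised into
`n_rows` (default 124) rows split equally between mesial and lateral tilt.

**Angle fields.** Each category has four region-anchored circular means
and SDs. Defaults: inner-mesial 58.4° → 147.0° (SD 12.5–14.1°),
inner-lateral 29.9° → 75.6° (SD 52.8–13.5°), interior regions linearly
interpolated between the printed end regions (matching the reported ~30°
and ~15° per-region steps); outer 24° → 122° (SD 28°), chosen so the
density-weighted grand mean is ≈ 69.5° with the reported ~4× lateral-to-
mesial increase; CEJ constant 101.0° (SD 43.9°). By default the anchors
apply as region means (`field_interpolation="step"`), which makes them
directly recoverable as per-region circular means; a `"linear"` mode
interpolates between region centres instead. Row *paths* always follow
the linearly interpolated field so a chain never bends ~30° in one link at
a region edge.

**Angular noise.** Sampled angles live on the axial half-turn. The default
family is a normal truncated to (0°, 180°) whose location parameter is
calibrated (quadrature + bisection, cached per anchor) so the *population
circular mean* of the sampled angles equals the configured anchor exactly.
A wrapped normal folded mod 180° is available (`angle_noise="wrapped"`)
but folds its far tail onto the opposite end of the axial range, biasing
recovered circular means by up to ~3° and inflating circular SDs by up to
~27% at the default anchors — measurable artefacts, not generator noise,
which is why it is not the default. With either family, a configured SD
approaching the axial half-range cannot be realised on a bounded support:
the inner-lateral region-1 cell (mean 29.9°, SD 52.8°) realises a circular
SD near 40°. SD-recovery checks therefore apply to cells with configured
SD ≤ 30°.

**Geometry and curvature.** In arc mode the band bends on a circular DEJ
with the surface on the convex side; the DEJ tangent rotates by ±37° over
the default band, which is what makes the section-frame angle gradient
(58° → 147°) largely a curvature effect: the same field expressed relative
to the local DEJ spans only ~95°–110° (mesial tilt) and ~67° → 39°
(lateral tilt), reproducing the characteristic flattening of DEJ-relative
angle profiles. Flat mode is the R → ∞ limit and is used for the
small/constant-field test maps (the published section-frame anchors on a
short *flat* band would drift rows ~150 μm sideways, more than the band
holds).

**Rows, spacing and packing.** Each row starts near the DEJ and walks
toward the layer boundary along the local mean field direction with steps
drawn from the category's region-anchored spacing field (default
inner-mesial 2.86 → 2.02 μm, gradual mesial compression; inner-lateral
3.02/2.35/2.35/4.50 μm, compression then a ~1.9× mesial expansion; outer
2.6 → 2.0 → 2.4 μm, tighter than the inner layer with its minimum in the
central labial region; CEJ 2.5 μm). The published record gives these
spacing trends but no absolute values, so the absolute level is calibrated
from packing: the defaults are the scale at which 5063 inner profiles fit
124 row paths. Profile counts are apportioned to rows in proportion to
path capacity (largest remainder, capacity-capped); rows place their quota
at the configured spacing from the DEJ end and simply stop short of the
boundary when under capacity, so realised spacing equals the configured
field (~2% on the defaults). Outer profiles fill staggered columns at the
local spacing; CEJ profiles fill two jittered zones at the band termini,
split 5:1 mesial:lateral.

**Shapes and overlap.** Inner profiles are pointed ovals (sharp-tipped
ellipses, default 1.45 × 0.65 μm — sized from the packing constraint, not
a printed dimension) whose tips give the rasterised profile a well-defined
maximal Feret pair; outer profiles are rhombi (1.3 × 0.7 μm diagonals);
CEJ profiles are randomly perturbed ovals. Where mesial and lateral row
paths cross, conflicting profiles are resolved deterministically
(earlier-placed wins): the later profile is nudged perpendicular/along its
axis — capped so neither the within-row gap nor the chain-continuation
angle can cross the assembler's gates — then both may move, then the
profile shrinks (×0.85/0.72/0.6, a rod sectioned near its end) until every
polygon pair keeps ≥ 0.3 μm (≈ 5 px) clearance; generation fails loudly if
a map cannot be packed. One seed reproduces a map bit-exactly.

## What the generator does and does not emulate

It reproduces the *quantitative* architecture: counts, composition, row
organisation and alternation, region-dependent angle and spacing fields,
band geometry and thickness. It does not simulate SEM imaging physics,
etching texture, interrod enamel (real rod profiles abut through interrod
material rather than keeping clearance), montage seams, or segmentation
ambiguity at layer boundaries. Passing recovery tests therefore validates
the measurement chain on clean, well-separated profiles; on real etched
sections the thresholding and the manual color-coding remain the accuracy
bottlenecks.

## Numerical choices and defaults

| parameter | default | meaning |
|---|---|---|
| `pixels_per_um` | 16 | raster scale; inner profiles ≈ 23 px long, where Feret-angle noise is ~±1.5° |
| `total_profiles` | 7233 | profiles per cross-section |
| `category_fractions` | 0.70/0.27/0.03 | inner/outer/CEJ composition |
| `n_rows` | 124 | inner rows, split 62/62 by tilt |
| `thickness_um` | 121 = 100 + 21 | band, inner and outer thickness |
| `curvature` | 540 μm (or `"flat"`) | DEJ arc radius |
| `clearance_um` | 0.3 | minimum polygon gap (≥ 2 px at 8 px/μm and above) |
| row gating factor | 2.5 | × median NN distance, link gate |
| min continuation | 120° | chain-folding rejection angle |
| `min_rods` | 3 | below this a chain is an orphan row |
| DEJ tangent window | 50 μm | total-least-squares fit window |
| DWLS bandwidth | 0.25 | Gaussian weight scale, fraction of data range |

DWLS smoothing uses a local *linear* fit (exact for planes at any
bandwidth) and is visualisation support only; no numeric conclusion
depends on it.

## Problem sizes

The default map is a 700 μm band at 16 px/μm (≈ 12 MP per layer) analysed
in ~15 s. Recovery of the pooled grand means uses five 400 μm flat maps
with constant angle fields (≈ 3 400 profiles each, pooling > 5 000
profiles per tilt); regional anchors are checked on five default maps
(> 2 000 mesial profiles per end region). The test suite builds one small
200 μm map (700 profiles) for most end-to-end checks.

## Known limitations

- Feret angles of profiles shorter than ~10 px are noisy (±4–5°) and near-
  vertical profiles retain a residual bias up to ~2°; pooled means remain
  accurate to well under a degree at the default profile size.
- The assembler assumes rows are locally straight chains; genuine row
  branching/merging (a 3D phenomenon) is outside the 2D model.
- Circular SDs configured above ~30° are not exactly realisable on the
  axial half-range (see Angular noise above).
- `assign_region` uses half-open quarter bins with the right edge closed
  at 1.0; region counts on real maps depend on the annotated band extent
  through the bounding box.
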