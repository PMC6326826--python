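# rodmap

Quantitative 2D morphometry of enamel rod profiles in rodent incisor
cross-sections.

Mouse and rat incisor enamel is built from thousands of enamel rods, each
the product of a single ameloblast. In a transverse section the rods appear
as small oval, diamond-shaped or irregular profiles: oval profiles in the
thick **inner enamel layer** are organised into rows that alternate between
a **mesial** and a **lateral** tilt (decussation), diamond-shaped profiles
fill the thin **outer enamel layer**, and disorganised profiles sit near
the two cementoenamel junctions (CEJ). Counting these profiles and
measuring their tilt angles, row structure and packing is how the cellular
dynamics of amelogenesis are read out of a static section.

`rodmap` implements that measurement chain for color-coded rod-profile
maps (one raster layer per rod category), plus a synthetic map generator
with full ground truth for validating every stage:

- **particle extraction** — thresholding, 8-connected component labelling,
  and per-profile area, centroid, long/short Feret diameters and Feret
  angle by rotating calipers on the pixel-corner convex hull. Angles are
  measured counterclockwise from 3 o'clock, on [0°, 180°).
- **row assembly** — automatic chaining of inner-enamel profiles into rows
  (distance-gated greedy linking with degree, cycle and chain-continuation
  constraints), replacing manual row outlining.
- **map geometry** — normalized (virtual) coordinates from the enamel-layer
  bounding box, the four equal lateral-to-mesial regions, enamel thickness
  at the point of maximum convexity, depth fractions, and local
  DEJ-relative angle frames.
- **circular statistics** — mean direction, resultant length and circular
  SD (`sqrt(-2 ln R)`); decussation angles between alternating rows and
  their supplements (the alternating inter-row angles); nearest-neighbour
  and within-row spacing summaries; distance-weighted least-squares (DWLS)
  surface smoothing for angle-field visualisation.
- **synthetic data** — a curved (or flat) enamel band ~121 μm thick with
  ~7233 non-overlapping profiles in ~124 alternating-tilt rows,
  region-anchored angle and spacing fields, and a ground-truth table tied
  to every rendered shape.

The central statistic is the plain circular mean of axial Feret angles
θ₁…θₙ treated as directions: with C = Σcos θᵢ, S = Σsin θᵢ,
mean = atan2(S, C), R = √(C²+S²)/n, circular SD = √(−2 ln R). The
decussation angle between two mean directions is their smallest absolute
angular difference; the alternating inter-row angle is its supplement.

## Worked example

```python
from rodmap import GeneratorConfig, simulate, run_pipeline, circular_mean

cfg = GeneratorConfig(seed=1)          # default curved band, 7233 profiles
emap, truth, _ = simulate(cfg)         # four category layers + ground truth
res = run_pipeline(emap, config=cfg)   # measure -> rows -> statistics
s = res.summary
print(s["total"], s["counts"], s["percent"], s["n_rows"])
```

prints (exactly, for seed 1):

```
total rod profiles : 7233
inner / outer / CEJ: 5063 / 1953 / 217  (70% / 27% / 3%)
rows (mesial/lateral): 124 (62/62)
thickness total/inner/outer: 121.0 / 100.0 / 21.0 um
inner_mesial: n=2443 circular mean 106.5 deg +- 34.1
inner_lateral: n=2620 circular mean 51.9 deg +- 29.0
mean decussation by region: {1: 25.0, 2: 43.8, 3: 58.4, 4: 72.9}
```

All 7233 generated profiles are recovered as exactly 7233 particles, the
124 generated rows are re-assembled exactly, the 121 μm band thickness is
measured to sub-pixel accuracy, tilt grand means sit near 104°/49°
(mesial/lateral), and the decussation angle between alternating rows
rises sharply toward the mesial side — the structural signature of this
enamel. `res.profiles`, `res.rows`, `res.regional`, `res.spacing` and
`res.decussation_pairs` hold the full tables; `rodmap.write_outputs`
writes them as CSV together with a reproducibility manifest.

A CLI wraps the same functions:

```sh
rodmap simulate --config cfg.yaml --seed 1 --out mapdir
rodmap measure  --layer mapdir/layer_outer.png --category outer --scale 16 --out outer.csv
rodmap analyze  --map-dir mapdir --out analysis
rodmap run      --seed 1 --out outdir
rodmap recover  --seed 1 --out recovery.csv
```

## Documentation

`docs/methods.md` describes the generative model, the measurement
conventions (Feret angle estimation, axial circular statistics), the row
assembler, parameter defaults with units, and known limitations.
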