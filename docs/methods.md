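# Methods

## Coordinate and orientation conventions

All geometry lives in tissue coordinates: x = image column (increasing
rightward), y = image row, 0-based, pixel-centre origin. The distal
direction of the tissue is +x, following the standard acquisition
convention of orienting wings with the distal side to the right; every
polarity statistic (ABP sign, Q1 sector, density-map vertex) is defined
about that axis. Inputs acquired with the opposite orientation can be
mirrored at load time (`score --flip-axis`).

## Cell geometry

Cells are measured on the label mask as pixel sets: the centroid is the
unweighted mean of pixel coordinates, the area is the pixel count, and the
axial extents are the minimal/maximal pixel x-coordinates of the cell.
Border-touching cells are flagged and excluded from scoring by default
(configurable): their extents are truncated by the field of view, which
would bias the ABP normalization asymmetrically. `min_area` (default
20 px) drops segmentation slivers.

Centrioles are matched to cells by point-in-pixel-set lookup. Detections
that land on a background pixel — junction-stained membrane skeletons are
1–2 px wide — are snapped to the nearest labelled pixel within 2 px;
anything unresolved is reported as unassigned, never silently dropped.
Point-in-cell matching (rather than nearest-centroid) is an assumption of
this implementation.

## ABP score

Per centriole, with `dx = x_centriole − x_centroid`:
`score = dx / (axial_max − x_centroid)` for `dx ≥ 0`, else
`dx / (x_centroid − axial_min)`, clamped to [−1, 1] (raster edge effects
can put a snapped detection ≤ 1 px beyond the pixel extent range). Cells
with zero extent on the relevant side are rejected as degenerate. The
per-image score is the arithmetic mean over centrioles; both members of a
cell's centriole pair enter individually (each centriole is computed
individually; a per-cell-mean mode exists for sensitivity analysis and,
in the worked example, shifts image scores by < 0.01). Axial extents are
the whole cell's pixel x-range, not the chord through the centroid; for
near-convex wing cells the two differ by at most a pixel, which the test
suite checks against a brute-force chord-scanning oracle.

## Q method

The offset angle is `atan2(dy, dx)` in (−π, π], measured from +x. Sectors
are half-open, closed on the counterclockwise-lower end: Q1 = [−π/4, π/4),
Q2 = [π/4, 3π/4), Q3 = [−3π/4, −π/4), Q4 absorbs the remainder including
π. The closure convention is a measure-zero choice made deterministic;
the Q3 interval is the mirror of Q2, the only reading that partitions the
circle. The sector axis is the global tissue axis translated to each
centroid — no per-cell axis estimation, since wings are globally oriented
during acquisition. Zero-offset centrioles have no defined angle; they
are excluded and reported in `n_excluded` rather than force-assigned.

## Density maps

The reference cell is a regular hexagon, circumradius 1, one vertex on
the +x axis (wing hairs form at the distal vertex, so polarized density
accumulates there). "Same size" is implemented as equal area: offsets are
scaled by `sqrt(A_hex / area_px)`, which preserves direction exactly —
so quartile assignment is invariant under the normalization — and scales
lengths by 1/s when the cell area scales by s². Points outside the
hexagon (real cells are not regular hexagons) are clamped radially to the
boundary, preserving counts. Normalized positions are binned on a
101 × 101 raster over the bounding box, optionally Gaussian-smoothed
(default σ = 2 raster px), zeroed outside the hexagon footprint, and
normalized to sum to 1. Histogram-plus-smoothing was chosen over a kernel
density estimate; both rendering parameters are exposed. Maps are
compared descriptively (centre-of-mass displacement and total-variation
distance); no statistical testing is done on the maps themselves.

## Group comparison

Two-sample, two-sided t-test on per-image summaries (per-image ABP or a
per-image quartile fraction). The image is the sampling unit: centrioles
within one image share tissue context and are not independent. Welch's
unequal-variance variant is the default, with the pooled Student variant
behind a flag, since the variance structure of real groups is unknown.
A per-centriole comparison can be assembled from the per-centriole CSVs
but is deliberately not the default.

## Synthetic epithelium

The generator emulates a pupal-wing field with exact ground truth:

- **Packing.** Seeds on a hexagonal lattice (centre spacing √3·R for
  circumradius R, default 14 px — comparable to wing cells at typical
  confocal sampling), perturbed by Gaussian jitter (s.d. 0.15·R). Cells
  are the Voronoi partition of the seeds, rasterized by nearest-seed
  labelling (identical to the polygon partition) with a 1-px membrane
  carved between neighbours. The membrane pixel is taken from alternating
  sides of each boundary pair (checkerboard parity) so pixel centroids
  are not systematically displaced from the polygon centroids — carving
  one fixed side biases the measured ABP of an unpolarized field by
  ≈ +0.03.
- **Centrioles.** Exactly two per cell. The first sits at angle
  θ ~ von Mises(μ, κ) about μ = 0 (distal) or π (`reversed_polarity`), at
  radius `radial_fraction × d(θ)` where d(θ) is the centroid-to-boundary
  distance along θ — referencing the actual boundary keeps centrioles
  inside irregular cells. The second is displaced from the first by an
  isotropic Gaussian (σ = `pair_sigma_px`, default 2 px), mimicking the
  near-coincident centriole pairs of wing cells, and radially truncated
  to stay ≥ 1.6 px inside the cell (off the membrane). Cells are convex,
  so truncation is exact.
- **Defaults** are the wild-type-like condition: κ = 6, radial fraction
  0.6, which yields image ABP ≈ 0.5 and Q1 fraction ≈ 0.9. κ = 0 is the
  unpolarized (loss-of-function-like) condition; real knockdown cells may
  be partially polarized, so κ of the LOF model is a free parameter
  rather than a biological claim.
- **Mosaic fields** place a central vertical stripe of LOF-model cells
  (group "IR") between WT-model flanks, the layout of a stripe-driver
  RNAi wing with internal controls. One RNG stream per run, seeded from
  the config; outputs are bit-reproducible and every artifact carries the
  config echo.

What the generator does *not* emulate: fluorescence images and detection
noise, true cell-shape mechanics (it uses Voronoi geometry, not a vertex
model), hair/actin geometry, apical-surface curvature, or spatial
correlation of polarity between neighbours. Passing tests therefore
validate the measurement pipeline, not the biology of any particular
dataset: on real data the segmentation and detection quality dominate.

## Problem sizes and numerical choices

Test and acceptance runs use 300-cell fields (20 × 15 lattice), five
seeds where averaging across replicates is called for — enough for the
binomial/SE bounds asserted (≈ 2500 interior centrioles pooled over five
fields) while keeping the full suite around ten seconds. The type-I-error
calibration of the group comparison (1000 replicate pairs, 5 images per
group, 100 cells per image) samples per-image ABP scores from the same
placement model on exact regular hexagons without rasterization; at that
replicate count the rasterization step would add cost but no information
about the t-test being calibrated. Degenerate inputs fail loudly:
all-zero masks, non-integer rasters, empty detection lists, degenerate
cells, zero-offset angles, sub-minimum lattices and out-of-range
simulation parameters all raise with specific messages.

## Known limitations

- Strictly 2-D: z-stacks must be reduced to the apical plane upstream.
- Point-in-cell assignment cannot recover detections mis-localized into a
  neighbouring cell by more than the 2-px snap radius.
- The ABP normalization uses whole-cell axial extents; for strongly
  non-convex cells the score is defined but less interpretable.
- Density-map comparison is descriptive; no significance test is offered
  on the maps.
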