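# Methods

This note documents the models, conventions and numerical choices behind
sarcoquant, in the spirit of a methods appendix: what each computation
assumes, which knobs matter, and what the synthetic validations do and do
not show about real data.

## Mitochondrial segmentation

### Background removal

A two-cluster k-means on scalar pixel intensity separates background from
candidate signal. Initialization is fixed at the 25th and 75th intensity
percentiles followed by Lloyd iterations to convergence, so the mask is
fully deterministic; no random restarts. The lower-mean cluster is always
background — the convention is intensity-based, never size-based, so an
inverted-contrast image would classify its bright majority as foreground.
A constant image is rejected ("no intensity contrast"). If the two
percentiles coincide on a non-constant image, initialization falls back to
the intensity extremes.

### Feature space

Each retained pixel becomes a row (x, y, s) where x is the column index, y
the row index (pixels, 0-based), and s the intensity min-max rescaled to
[0, `intensity_weight`]. Nothing in the source workflow fixes how
intensity is made commensurate with coordinates; the weight defaults to 10
pixel-units and is exposed everywhere. Weight 0 recovers a purely spatial
clustering, which the tests exploit. A constant retained intensity
rescales to 0 by definition. Coordinates stay in pixels; physical
calibration enters only when areas are measured.

### DBSCAN semantics

Euclidean DBSCAN in the 3D feature space with eps = `search_radius` and
minPts = `min_cluster_size`. Conventions are pinned because
implementations differ:

* a point is core if at least minPts points **including itself** lie
  within eps;
* clusters are the connected components of core points (two cores
  connect if within eps);
* a border point (non-core with at least one core neighbour) joins the
  cluster of its **lowest-index core neighbour in row-major pixel
  order** — a deterministic tie-break for borders reachable from several
  clusters;
* noise maps to background (label 0). Instance ids are consecutive from
  1, ordered by each cluster's first core pixel in row-major order.

Neighbourhoods come from a KD-tree (scikit-learn `NearestNeighbors`) and
components from `scipy.sparse.csgraph`; a brute-force O(n²) oracle with
the same semantics but a dense distance matrix and BFS verifies label-level
equality on a thousand random problems in the test suite.

### Monte-Carlo tuning

`n_iterations` independent draws: minPts uniform on its integer range,
eps log-uniform on its range (a scale parameter; log-uniform spreads draws
evenly across magnitudes). Each draw is scored by the IOU of the binarized
segmentation against the annotation; the search stops early at the first
draw exceeding `target_iou` (default 0.95) and is fully seed-deterministic.
With the same seed, a longer search extends the same draw sequence, so the
best IOU is non-decreasing in `n_iterations`. No adaptive refinement is
attempted — random search is the simplest faithful reading of the
procedure, and on the representative synthetic field it exceeds the 0.95
objective within a handful of draws.

The tuned parameters are intended to be frozen and applied to every image
of an experiment; `segment_stack` does exactly that.

### Plane policy

Analysis can run on an explicit plane index, on the max-intensity
z-projection (default), or per-plane with one label map per plane. Whether
the original workflow clustered single planes or projections is not
documented; both are provided and neither claimed as canonical. No 3D
volumetric clustering across z is attempted.

## Morphometry and the chi-square comparison

Area = pixel count × pixel_size_um² ("cluster resolution" = pixel area).
Log₁₀ binning at −0.5 and 0 (≈0.316 µm² and 1 µm², the thresholds
interpreted in µm², the pipeline's only calibrated unit): boundaries are
inclusive on the left class, so log₁₀A = −0.5 is small and log₁₀A = 0 is
medium. Zero areas cannot occur (every instance has ≥ 1 pixel).

Per-replicate percentages are computed from each replicate's own total,
then averaged arithmetically. The group comparison is a Pearson χ² on a
2×3 table, df = 2, in one of two modes:

* `percent_as_count` (default) — rows are the two groups' mean
  percentages; this mirrors the common practice of testing the averaged
  percentage distributions directly. Percentages are stabilised to 1e-6
  before the test.
* `pooled_counts` — rows are raw instance counts summed over replicates;
  the statistically orthodox construction, with the usual χ² sampling
  theory behind it. The null simulation in the acceptance suite uses this
  mode and holds its 5% nominal type-I rate.

A table with a zero expected cell is rejected as degenerate rather than
silently producing NaN.

## Fluorescence quantifications

* **8-bit conversion** — linear min-max rescale to [0, 255], rounding
  half-up; a constant image maps to 0.
* **Gaussian blur** — isotropic, reflective borders, default sigma 2 px.
* **Remove outliers** — a pixel is replaced by the median of its circular
  neighbourhood (default radius 2 px) iff it deviates from that median by
  more than a threshold (default 50), bright mode by default; dark and
  two-sided modes exist.
* **IsoData threshold** — Ridler–Calvard iterative intermeans on the raw
  (not histogram-binned) values: T ← ½(mean ≤ T + mean > T) from the
  global mean until the induced partition is stable; mask = pixels > T.
  The threshold is equivariant to constant offsets. Exhaustive
  enumeration of intermeans fixed points over all splits of the sorted
  unique values serves as the oracle in tests.
* **Membrane-potential ratio** — both channels run the identical chain
  (projection, 8-bit, blur, outlier removal, optional rectangular ROI
  crop, IsoData); only the final areas differ. Ratios above 100% are
  returned but flagged. A signal-free (constant) active channel yields
  area 0.
* **Particle analysis** — 8-connected components (the ImageJ default; the
  choice is otherwise arbitrary), areas in calibrated µm², half-open
  filter window [min, max) so the 2 µm² boundary belongs to the
  extramyocellular class and the two droplet modes partition components
  exactly. Size windows are interpreted in µm² by default because an
  "infinite" upper bound only makes biological sense calibrated; a pixel²
  reading can be had by passing pixel-unit bounds with pixel size 1.
* **TCCF** — integrated density minus ROI area × pooled-background mean;
  offset-invariant by construction. Overlapping cell and background ROIs
  warn but compute. Other single-channel intensity readouts (DHE, OPP,
  PAS) are the same computation on a different channel.
* **Muscle integrity** — IsoData threshold computed from the cuticle-ROI
  pixels only; raw fraction = suprathreshold pixels / ROI pixels. A
  zero-contrast ROI cannot be thresholded and scores 1.0 if its constant
  value is positive, else 0.0. Normalisation to a control mean is optional
  (control ≙ 1).

## Synthetic data: what it emulates, what it does not

Generators produce 3-plane stacks (same structures, independent noise per
plane) so projections act on a real z-axis. Intensities are mean levels
(foreground 180, background 20) plus additive Gaussian noise (sd 5)
clipped at zero — a high-SNR confocal regime. There is no point-spread
function, no Poisson photon statistics, no photobleaching, and no
sarcomere texture; passing tests therefore demonstrate the correctness of
the computations, not robustness to low-SNR or structured-background
imaging.

* **Mitochondria fields** — instance areas are 10^N(µ, σ) µm² with
  defaults µ = −0.25, σ = 0.35, spanning the three size classes at
  0.1 µm/px; the true size law of muscle mitochondria is not documented,
  so the lognormal is a modelling convenience, not a claim. Instances are
  ellipses (aspect ratio uniform in [1, 2], random orientation),
  rasterized by taking exactly the target number of pixels in
  elliptical-distance order, so ground-truth areas are exact. Placement
  is rejection sampling with a 3-px clearance and a cap of 1,000 attempts
  per instance; on overflow the generator warns and reports the placed
  count — ground truth never disagrees with the image.
* **Two-channel pairs** — the active channel contains a seed-deterministic
  random subset of instances chosen greedily, including an instance only
  when that moves the summed area closer to the designed fraction of the
  total; the realized active area is within one instance of the target
  and unbiased. The default validation field (`tmre_field_spec`) uses
  larger structures (median ≈ 5.6 µm², ≈ 560 px) than the morphometry
  default because membrane-potential ratios are measured on
  low-magnification fillet images whose signal territories are many
  pixels across. This matters: when structure radius approaches the blur
  sigma, the thresholded-area ratio is dominated by boundary halo and
  biased upward at low active fractions — a limitation of the macro chain
  itself, documented here because the synthetic tests deliberately avoid
  that regime.
* **Droplet fields** — disjoint disks with areas uniform in a window
  (default [0.5, 5] µm²), realized exactly in pixels, so size filters and
  densities are checkable without tolerance.
* **Fillet fields** — the attached region is a smoothed Gaussian random
  field thresholded at the (1 − fraction) quantile: spatially coherent
  patches whose realized area fraction matches the request to within a
  pixel.

## Determinism and provenance

Every random choice flows from an explicit integer seed through
`numpy.random.default_rng`; k-means initialization is percentile-fixed;
DBSCAN tie-breaks are row-major. Assay runs echo their full configuration,
software version and input SHA-256 checksums into `provenance.json`;
result files are byte-identical across reruns of the same configuration
(timestamps live only in the provenance record). JSON floats use Python's
shortest round-trip representation; CSV files are UTF-8 with "." decimals
and units in the header row; coordinates are 0-based (row, column).

## Problem sizes used in validation

The validation suite runs on synthetic fields of 512×512 px (tuning,
droplet and two-channel recovery; ~30–40 instances) and 256×256 px for
unit-level checks; the DBSCAN oracle comparison uses 1,000 random feature
sets of up to 300 points; the chi-square null calibration uses 1,000
simulated group pairs of 150 instances each. These sizes match the scale
of single confocal fields while keeping the whole suite fast.

## Known limitations

* Segmentation is 2D per plane or projection; touching mitochondria
  separated only in z are not resolved.
* The k-means background model assumes a bimodal intensity histogram; a
  strong intensity gradient would need flat-field correction first (not
  provided).
* The membrane-potential ratio inherits the macro chain's halo bias for
  structures comparable in size to the blur kernel (see above).
* `percent_as_count` chi-square treats averaged percentages as counts;
  its p-values are not calibrated in the usual sampling sense (the pooled
  mode is, and both are reported by the pipeline).
* TIFF resolution tags are honoured only as a fallback for calibration
  and only for centimetre-unit tags; explicit `pixel_size_um` is always
  preferred.
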