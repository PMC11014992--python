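# sarcoquant

Quantitative confocal image analysis for muscle biology. The package
re-implements, as a tested and reusable Python library, the automated
measurements used to characterise muscle wasting in fluorescence
microscopy: mitochondrial morphometry, membrane-potential ratios, lipid
droplet densities, background-corrected fluorescence, and muscle
integrity.

## Who this is for

Labs quantifying muscle confocal images (e.g. *Drosophila* larval muscle
fillets or mouse muscle cryosections) who want scriptable, reproducible
versions of the usual FIJI-macro measurements plus a validated
mitochondrial instance segmentation — and synthetic ground-truth images to
verify the whole chain.

## What it computes

**Mitochondrial segmentation.** Pixels of a confocal plane (or
max-intensity z-projection) are split into background and candidate signal
by a two-cluster k-means on intensity. Candidates become a feature matrix
of (x, y, scaled intensity) rows and are grouped into instances by DBSCAN,
which needs no prior knowledge of mitochondrial count or size — only two
parameters, the minimum cluster size (minPts) and the search radius (eps).
These are tuned by Monte-Carlo random search against an annotated
reference image, scoring each draw by intersection over union

    IOU(A, B) = |A ∩ B| / |A ∪ B|,

with the goal IOU > 0.95; the winning parameters are then applied to every
image of the experiment. Instance area is pixel count × (pixel size)² µm².

**Morphometry.** Areas are log₁₀-transformed and binned: small
(log₁₀ A ≤ −0.5), medium (−0.5 < log₁₀ A ≤ 0), large (log₁₀ A > 0).
Per-replicate class percentages are averaged per group and two groups are
compared with a Pearson χ² on the 2×3 table (df = 2).

**Membrane potential.** The thresholded TMRE area divided by the
thresholded MitoTracker Green area (×100) estimates the fraction of
mitochondria holding a membrane potential. Both channels pass through the
identical chain: max projection → 8-bit → Gaussian blur → remove outliers
→ ROI crop → IsoData auto-threshold → area.

**Lipid droplets.** 8-connected particle analysis on a thresholded image
with a calibrated size window (e.g. [0, 10) µm² for intramyocellular,
[2, ∞) for extramyocellular deposits), normalised to droplets per mm².

**TCCF.** Total corrected cell fluorescence:
`TCCF = integrated ROI intensity − ROI area × mean background intensity`,
plus per-ROI mean-intensity ratios (e.g. FOXO/DAPI, mCherry/GFP).

**Muscle integrity.** Thresholded fluorescent area within a cuticle ROI
divided by the ROI area (% muscle attachment), optionally normalised to a
control mean.

**Synthetic data.** Every measurement has a generator producing
calibrated TIFF-compatible stacks with exact ground truth: lognormal-area
elliptical mitochondria, two-channel total/active pairs with a designed
active fraction, droplet fields of known density, and fillet images with a
designed attached fraction.

## Worked example

```python
import sarcoquant as sq

# a representative 512x512 field at 0.1 um/px: ~30 instances,
# foreground 180 / background 20 / noise sd 5
spec = sq.MitoImageSpec(rng_seed=5)
stack, truth = sq.generate_mito_image(spec)

plane = stack.max_projection()
background = sq.classify_background(plane)
result = sq.tune_parameters(plane, background, truth.binary_mask,
                            sq.TuningConfig(rng_seed=6))
print(f"best IOU    : {result.best_iou:.4f}")
print(f"best params : minPts={result.best_params.min_cluster_size}, "
      f"eps={result.best_params.search_radius:.3f}")

label_map = sq.segment_stack(stack, result.best_params)
records = sq.classify_sizes(sq.measure_areas(label_map))
dist = sq.summarize_distribution([records], group_label="example")
print(f"instances   : {label_map.n_instances} segmented vs {truth.n_instances} true")
print("size classes: small {:.1f}% | medium {:.1f}% | large {:.1f}%"
      .format(*dist.mean_percentages))
```

Output:

```
best IOU    : 0.9973
best params : minPts=8, eps=3.541
instances   : 30 segmented vs 30 true
size classes: small 30.0% | medium 53.3% | large 16.7%
```

The tuned search exceeded the 0.95 IOU objective (0.9973), recovered all
30 planted instances, and the size-class split reflects the generator's
lognormal area law. scikit-learn users can reach the same chain through
the estimator classes `sq.MitochondriaSegmenter` (fit / fit_predict,
`label_map_`) and `sq.DbscanTuner` (fit, `best_params_`, `best_iou_`,
`best_estimator_`).

A command-line interface mirrors the library:

```bash
sarcoquant simulate --kind mito --seed 5 --out sim/
sarcoquant segment --image sim/image.tif --annotation sim/labels.tif \
    --pixel-size-um 0.1 --seed 6 --out seg/
sarcoquant tmre --total total.tif --active active.tif --pixel-size-um 0.1 --out tmre/
```

Every run writes its results as CSV/JSON next to a `provenance.json`
(config echo, software version, input checksums); reruns with the same
configuration are byte-identical.

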