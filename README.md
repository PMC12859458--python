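# orgquant

Organoid quantification from whole-well bright-field images.

Organoid co-culture assays (e.g. cytotoxicity experiments at a fixed
effector-to-target ratio) need the number of *cells* in a well, not the
number of organoids: two wells with the same organoid count can hold very
different cell numbers because organoid sizes span orders of magnitude.
`orgquant` estimates per-organoid and total cell numbers directly from a
single grayscale bright-field image of a whole well, with no dye, no
dissociation and no fluorescence channel.

The toolkit has two halves:

1. **Tiled instance segmentation with cross-tile duplicate suppression
   ("mosaicking").**  Whole-well images are large (2,000–5,000 px per
   side) while segmentation backends consume fixed 512×512 tiles.  A
   sliding window with a 256 px stride (half a tile) cuts overlapping
   tiles so every organoid appears at least once in the middle of a tile
   rather than clipped at an edge.  Because of the overlap one organoid
   can be detected in several tiles, so a modified non-maximum
   suppression merges the per-tile detections: instances from
   overlapping tiles whose mask intersection exceeds 30% of either
   instance's area are the same organoid, and only the largest-area
   instance of each duplicate group survives.  Segmentation itself is
   pluggable — a backend is any callable `tile -> [(mask, confidence)]`;
   a classical threshold/watershed reference detector is included, and
   externally produced masks (label-image TIFF or VGG Image Annotator
   polygon JSON) can be ingested instead.

2. **Area-to-cell-number regression.**  The number of nuclei N in an
   organoid is modelled as

   log N = β₀ + β_A·log A + β_S·S + β_M·M + ε

   where A is the organoid's image area in pixels, S is tissue origin
   (healthy = 0, tumor = 1) and M is morphology (cystic = 0, budded = 1),
   fitted by ordinary least squares on training rows with reference
   nuclei counts.  An extended variant adds the perimeter P and the
   ratio A/P as predictors.  The well total is the sum of the unrounded
   per-organoid estimates N̂ = exp(·).

A seeded synthetic-well generator with pixel-perfect ground truth (ring-like
organoids on a noisy background, counts drawn from the same log-linear law)
makes every stage testable end-to-end, and evaluation utilities provide
mask-IoU matching, mean average precision (mAP), log₁₀ relative-error
statistics and per-well percent deviation.

## Worked example

```python
from dataclasses import replace
from orgquant import (SynthConfig, generate_well, generate_training_table,
                      fit, estimate_well, mosaic, make_reference_backend,
                      SegmentationConfig, mean_average_precision, well_deviation)

# 1. training data: four tissue/morphology conditions, ~3200 organoids
base = SynthConfig(n_organoids=100, seed=17)
records = []
for s in ("healthy", "tumor"):
    for m in ("cystic", "budded"):
        records += generate_training_table(replace(base, sample_type=s, morphology=m), 8)
model = fit(records)
print("fitted on", model.fit_n, "organoids")
for name, value in model.coefficients.items():
    print(f"  {name:13s} {value:+.4f}  (se {model.stderr[name]:.4f})")

# 2. a new well: detect, deduplicate, count
well = generate_well(SynthConfig(width=1024, height=1024, n_organoids=12, seed=7))
dets = mosaic(well.image, make_reference_backend(SegmentationConfig(confidence_threshold=0.5)))
print("detected", len(dets), "organoids;",
      "mAP vs truth =", round(mean_average_precision(dets, well.truth), 3))

est = estimate_well(dets, model, "healthy", "cystic")
real_total = sum(r.real_nuclei for r in well.counts)
print(f"estimated total {est.total:.0f} cells, real total {real_total}; "
      f"deviation {well_deviation(real_total, est.total):.1f}%")
```

prints

```
fitted on 3200 organoids
  intercept     +0.4645  (se 0.0586)
  log_area      +1.0049  (se 0.0073)
  sample_type   -0.2000  (se 0.0071)
  morphology    -0.3036  (se 0.0072)
detected 12 organoids; mAP vs truth = 1.0
estimated total 73350 cells, real total 64987; deviation 12.9%
```

The fitted coefficients recover the generator's law (β₀ = 0.5, β_A = 1.0,
β_S = −0.2, β_M = −0.3) within sampling error; the reference detector finds
every synthetic organoid exactly once after duplicate suppression
(mAP = 1.0 against ground truth); and the estimated well total lands within
the scatter implied by the generator's multiplicative count noise
(σ_ε = 0.2 in natural-log space).

## Command line

The same pipeline is available as subcommands of the `orgquant` console
script: `simulate`, `tile`, `segment`, `dedup`, `fit`, `count`,
`evaluate` and `run` (end-to-end).  Every command writes a
`run_config.json` provenance record next to its outputs.  For example:

```sh
orgquant simulate --width 1024 --height 1024 --n-organoids 12 --seed 7 --out-dir well/
orgquant run --image well/image.png --model model.json \
    --mode cystic --sample-type healthy --threshold 0.5 --out-dir out/
```

which writes a label TIFF, a per-organoid CSV (id, centroid, area,
perimeter, confidence, estimated cells), a colored overlay PNG with ids
at the centroids, and the well total as JSON.

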