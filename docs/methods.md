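# Methods

## Problem and model

Perineural invasion (PNI) is scored per nerve: a nerve structure is positive
when tumor cells contact or surround its perineurium.  The pipeline therefore
separates *where the nerves are* from *where tumor signal is* and joins the
two only at the end:

```
RGB tile ──► nerve segmentation ──► pyramid smoothing ─► threshold ─► open/close ─► nerve components
RGB tile ──► PNI segmentation  ──► max(const, Otsu) threshold ─► components ─► size filter ─► retained
                                                        nerve components × retained ─► per-nerve PNI call
```

A nerve is called positive iff some retained PNI component has a pixel within
Chebyshev distance `adjacency_px` of a nerve pixel.  `adjacency_px = 0`
demands overlap; the default 5 px (~1.2 µm at 0.23 µm/px) tolerates the
1–2 px boundary erosion that blurring and thresholding introduce on each
side.  Chebyshev distance was chosen over Euclidean because it is exactly
realizable by square-structuring-element dilation, making the rule auditable
pixel-by-pixel.

## Segmentation stage

The network keeps parallel resolution branches (1, 1/2, 1/4, …, base width
`C`, width `C·2^i` at branch `i`), built from three block types: A
(conv3×3 + batch norm + ReLU), B (1×1/3×3/1×1 bottleneck with residual), C
(two 3×3 convs with residual).  Downsampling is stride-2 convolution;
upsampling is bilinear; the final stage concatenates all branches at full
resolution into a 1×1 sigmoid head, which makes the [0, 1] output range
structural rather than a postcondition to check.  The exact per-stage block
counts are configurable (`block_layout`, default stem 2×A + 4×B, then 2×C per
branch); the published description fixes the family but not the counts, so
the default was chosen to echo the cited high-resolution-network design while
remaining trainable on a single CPU.

Two independent models of identical architecture are used for the two tasks
(nerve, PNI); nothing in the task definition suggests weight sharing.

The engine is a compact numpy reverse-mode autodiff (im2col convolutions;
the convolution backward pass is expressed as a dilated transposed
convolution so both directions run as matrix products).  Gradients of every
op are verified against central finite differences in the test suite.
Tensors are float64: at desk scale the cost is negligible and it keeps the
gradient checks tight.

Training uses Adam (lr 0.001), MSE on the binary mask, inputs scaled to
[0, 1], batches sampled with replacement (this realizes the "augment by a
factor of 2048" strategy as resampled epochs instead of materialized copies).
Reference converged losses for the full-scale models (0.0082 nerve / 0.0077
PNI) are carried as metadata; they are properties of the original clinical
training corpus, which is not distributed, and are not reproduced here.

**Desk-scale profile.** `DESK_SCALE_CONFIG` (64×64 tiles, C=8, 2 branches,
layout 2A/2B/2C, ~14k parameters) overfits four synthetic nerve tiles to
MSE < 0.008 in ~40 Adam steps (≈10 s on one CPU).  Problem sizes throughout
the tests and the acceptance script (64×64 training tiles, 1280×1280 scenes,
50-scene batches) were chosen as the smallest sizes at which every pipeline
behaviour of interest — nest/noise separation around the published cutoff,
pyramid smoothing depth 2, tiled inference — is still expressed.

**Augmentation.** Brightness ±0.30, saturation and contrast in [0.7, 1.3],
horizontal/vertical flips, random crop (a `crop_scale_range` fraction of the
output size) rescaled to 256×256.  Geometric transforms are applied
identically to image and mask (mask nearest-neighbour, so it stays binary);
photometric transforms touch only the image.  Every range contains the
identity, so augmentation can be disabled by configuration alone.

**Tiled inference** covers the image with a clamped patch grid
(stride = tile − overlap, last origin clamped to the edge) and averages
predictions in overlap zones.  Images smaller than a tile are reflect-padded
and cropped back.

## Rule flow: numerical choices

* **Gaussian pyramid** — `levels` (default 2) reduce steps with the separable
  5-tap binomial kernel [1,4,6,4,1]/16 and symmetric edge handling, then
  bilinear expansion back through the recorded shape stack (so odd
  dimensions round-trip exactly).  All resampling in the package uses one
  half-pixel-center bilinear convention, implemented as dense per-axis
  interpolation matrices whose transpose is the autodiff adjoint.
* **Otsu threshold** — fixed 256-bin histogram of [0, 1] (not of the data
  range: probability maps have an absolute scale).  Candidate thresholds are
  bin upper edges; maximal between-class variance ω₀ω₁(μ₀−μ₁)², ties to the
  smallest edge; a single occupied bin sets a `degenerate` flag and the
  caller (binarization) falls back to the constant threshold.  The constant
  floor (default 0.5) guards against Otsu splitting background noise when no
  real signal is present.  Binarization keeps values strictly greater than
  the effective threshold.
* **Smoothing construction** — the published flow names a smoothing step that
  removes the "right angle" staircase artifacts of pixel-wise segmentation
  but does not specify it; it is implemented as disk opening-then-closing
  (radius 3).  A disk footprint genuinely rounds right angles (a square
  footprint would preserve them), at the cost of clipping the corners of
  perfectly rectangular regions — irrelevant for anatomical shapes.
* **Size filter** — removal rule `area ≤ cutoff` with the nearest-rank
  quantile calibration (sorted sample, 1-based rank ⌈(1−α)n⌉, minus a 1e-9
  epsilon so float representation of (1−α)n cannot bump an exactly integral
  rank).  The pairing guarantees that the calibrated cutoff removes at least
  a fraction (1−α) of its own calibration sample, and the cutoff is always an
  observed component area, as the published values (21,632 and 36,864 px²)
  evidently are.  "Significance level" is read as the retained upper-tail
  fraction (α = 0.10 ⇒ 90th percentile), the only reading consistent with
  "filter out 90%".
* **Cell equivalents** — cells are modelled as circles:
  `cells = area·mpp²/(π(d/2)²)`; at 0.23 µm/px and d = 13.5 µm this maps
  21,632 px² to 7.99 cells (detection limit ~8 cells, round half-up) and
  40,000 px² to 14.8 cells.
* **Components** — scipy's connected-component labeling, relabelled into
  row-major first-encounter order so component identity is deterministic and
  oracle-checkable; connectivity 8 by default (diagonally touching tumor
  cells belong to one nest).
* **Order of operations** — thresholding and size filtering run on the whole
  map *before* any nerve is inspected, and Otsu is computed per input map;
  both points are underdetermined in the published description and are fixed
  here in the stated order.

## Display conventions

Published confusion-matrix reports mix two percentage conventions: the
nerve-identification and ROI-level tables follow round-half-up (91.67 from
121/132) while the whole-slide tables follow truncation (98.20 from 384/391,
91.66 from 11/12).  No single rule reproduces all printed rows, so
`metrics()` takes a `convention` argument ("truncate" default, "half_up"
available) and the tests assert each table under the convention it actually
uses.  Diagnostic-time percentages round half-up to one decimal (floor of
10x + 0.5), which reproduces every per-slide entry and both totals (15.0%,
23.7%); the total uses summed times, not the mean of per-slide percentages.

Nerve-level scoring matches detections to truth nerves greedily by pixel
overlap (≥ 10% of the truth region, the `min_overlap_frac` default); a
matched pair contributes TP/FP/FN/TN by its class pair, an unmatched truth
PNI nerve is FN, an unmatched PNI-positive detection is FP, and an unmatched
truth-normal nerve counts TN (it was never flagged).  Any overlap-dominant
rule gives identical results on the well-separated synthetic scenes; the
exact matching rule is not specified by the source material.

## Synthetic scenes: what they emulate, and what they do not

One seeded generator stream drives everything in a documented order (nerves →
nests → speckles → noise → texture), so scenes are bit-reproducible and nerve
placement is independent of how much noise is requested.  Placement is
rejection sampling with a bounded retry budget (default 1000 per structure,
20 scene-level restarts); exhaustion raises rather than silently overlapping.

* **Nerves**: rotated ellipses (semi-axes 40–70 px) with a darker 6 px
  perineurium ring, separated so that no nest or speckle of one nerve can
  fall within the adjacency distance of another.
* **PNI nests**: 12–18 disk "cells" of diameter 13.5 µm / 0.23 µm/px ≈ 58.7 px
  in a Vogel-spiral cluster at 0.85 cell-diameter spacing (the within-nest
  packing density is a free parameter, `nest_packing_frac`), anchored on the
  perineurium pointing away from the nearest neighbouring nerve.  At these
  defaults a nest's pixel union is ~26–41k px², always above the 21,632 px²
  cutoff — the planted positives are meant to be detectable, the study
  condition for the recovery experiment.
* **Noise blobs**: exact-pixel-area elliptical blobs with areas drawn
  log-normal(µ=9, σ=0.8) px² (~90% below the cutoff, a tail above 40,000 px²),
  kept ≥ 25 px from every nerve.  Because blobs are planted with exactly
  their drawn areas, observed component statistics equal the draws.
* **Peri-nerve speckles**: small (500–8,000 px²) blobs placed 2–4 px outside
  the perineurium of normal nerves — outside the 1-px-dilated nerve mask,
  inside the adjacency distance.  They model the spurious near-nerve
  responses of a pixel-wise segmenter: with the size filter on they are
  removed; with the filter off they flip normal nerves to false positives,
  which is exactly the behaviour the cutoff exists to prevent.  They target
  normal nerves because on a PNI nerve the planted nest masks them (and can
  geometrically wall off the whole perineurium).
* **Simulated maps**: truth masks blurred (σ = 1 px) plus clipped Gaussian
  noise (sd 0.05); the PNI map deliberately carries the noise blobs as
  foreground so the size filter has real work.

Not emulated: stain variation and decorrelated chromatin texture, fibroblast
and inflammatory-cell mimics, nerves split across tile borders, lymphovascular
structures, and segmentation failure modes other than additive noise and
blur.  Passing the recovery tests therefore demonstrates the correctness and
calibration of the *rule flow*, not clinical-grade accuracy of the
segmentation stage; the published clinical accuracies (89.01% ROI-level,
97.5% WSI-level) depend on a non-distributed cohort and are covered only
through their confusion-matrix arithmetic.

## Known limitations

* The numpy network is desk-scale by design; full-scale 256×256/C=32 training
  is possible but slow without a GPU framework.
* The generator's nests always touch their nerve; the matcher is not
  exercised on ambiguous multi-nerve nests.
* Otsu on a map with almost no foreground can exceed the constant floor and
  suppress faint true signal — mitigated, not eliminated, by the max(const,
  Otsu) rule.
* `PlacementError` on over-crowded canvases is deliberate; callers asking for
  many large blobs must provide canvas room (the 50-blob distribution example
  uses a 2048² canvas for this reason).
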