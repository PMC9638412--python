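# pnikit

Two-stage detection of **perineural invasion (PNI)** — tumor cells invading
in, around, and through nerves — in H&E-stained histology images of oral
cavity squamous cell carcinoma (and other solid tumors where PNI is an
adverse prognostic feature).  PNI is an indication for adjuvant therapy, yet
its diagnosis suffers substantial intra- and inter-observer variability; this
toolkit implements the algorithmic half of a hybrid human/algorithm workflow
for pathologists and image-analysis researchers.

## The method

The pipeline mirrors a pathologist's two-step reading:

1. **Semantic segmentation** — two multi-resolution encoder–decoder networks
   (high-resolution-network style: parallel branches at scales 1, 1/2, 1/4,
   ... with base channels *C*, stride-2 downsampling, bilinear upsampling, and
   a final full-resolution fusion through a sigmoid head) map a 256×256×3 RGB
   patch to a 256×256×1 probability map — one model for nerve fibers, one for
   PNI signal.  Trained with Adam (lr 10⁻³) on an MSE mask loss with
   brightness/saturation/contrast/flip/crop augmentation.
2. **Domain-knowledge rule flow** — the nerve map is smoothed with a Gaussian
   pyramid (5-tap binomial reduce, bilinear expand), thresholded, and cleaned
   by a disk opening-then-closing; the PNI map is binarized at
   max(0.5, Otsu threshold), labeled into connected components, and passed
   through a **size filter** that removes components with
   area ≤ 21,632 px² — the nearest-rank 90th percentile of the spurious
   ("irregular") component size distribution, equivalent to ~8 tumor cells at
   0.23 µm/px with 13.5 µm cells:

   cells = area · mpp² / (π (d/2)²)

   Each nerve structure is then called PNI-positive iff a retained PNI
   component lies within a Chebyshev adjacency distance (default 5 px) of it.

Because no clinical images are distributed, the package ships a **synthetic
scene generator** (elliptical nerves with perineurium rings, tumor-cell nests
hugging the perineurium, log-normally sized noise blobs, near-nerve speckles)
that produces ground-truthed scenes on which every stage of the pipeline is
exercised and scored.

## Worked example

```bash
python examples/02_rule_flow.py
```

prints, for one synthetic scene (seed 7):

```
Otsu threshold on the PNI map: 0.4922 (effective threshold is max(0.5, Otsu))
PNI components: 20 found, 18 removed by the 21,632 px^2 size filter, 2 retained
  nerve 1: predicted normal (supported by components [])
  nerve 2: predicted PNI    (supported by components [5])
  nerve 3: predicted PNI    (supported by components [10])
  nerve 4: predicted normal (supported by components [])
confusion matrix vs planted truth: TP=2 FP=0 FN=0 TN=2
accuracy on this scene: 100.0%
```

Of the 20 connected components in the binarized PNI map, the size filter
removes the 18 spurious ones; the two retained tumor nests are each adjacent
to exactly one nerve, so those nerves are flagged PNI and the other two stay
normal — matching the planted ground truth.  The other examples cover scene
generation (`01`), cutoff calibration and the pixel↔cell conversion (`03`),
the published confusion-matrix and timing arithmetic (`04`), and desk-scale
training of the reduced network (`05`).

A thin CLI mirrors the library: `pnikit simulate|tile|train|infer|decide|
calibrate|evaluate|sweep|timing` (see `pnikit --help`).

## Layout

```
src/pnikit/
  synthetic.py        ground-truthed H&E-like scene generation
  io.py               TIFF/PNG masks & 16-bit probability maps, JSON
                      annotations, patch grids, timing CSVs
  segmentation/       numpy multi-resolution network, augmentation,
                      training, tiled inference
  postprocess.py      the rule flow: pyramid smoothing, Otsu+constant
                      binarization, components, size filter, per-nerve calls
  calibration.py      nearest-rank cutoff calibration, pixel <-> cell counts
  evaluation.py       confusion matrices, nerve matching, cutoff sweeps,
                      diagnostic-time analysis
  cli.py              thin typer CLI
```
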