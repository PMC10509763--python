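# Methods

`rectuseg` implements a fully automatic pipeline for measuring the
separation between the two rectus abdominis (RA) muscle bodies in
transverse B-mode ultrasound, the measurement used to assess diastasis
recti abdominis (DRA).  This note documents the model and procedure, the
parameters that matter, the synthetic phantom used for testing, and the
design choices made where the design was genuinely open.

## Pipeline

1. **Preprocessing.** Exported frames carry a black annotation periphery
   around the bright scan region.  The frame is binarized at the Otsu
   threshold (exhaustive between-class-variance maximization over the 256
   levels, ties toward the lower level), foreground components are labelled
   with 8-connectivity, and the frame is cropped to the minimum enclosing
   rectangle of the largest component.  The crop is resized to the model
   grid (512×512 by default; smaller in tests) with bilinear interpolation;
   masks use nearest-neighbour so they stay binary.  The per-axis pixel
   size is rescaled as `new = old · old_extent / target`, which conserves
   the physical extent of the frame, so a pixel gap measured on the model
   grid converts exactly to mm.
2. **Segmentation.** An encoder–decoder network maps the single-channel
   frame (scaled to [0, 1]) to a per-pixel foreground probability through a
   1×1-convolution head with a sigmoid.  Three variants are provided:
   `plain` (double-conv blocks, skip concatenation), `nested` (dense
   intermediate skip nodes re-aggregating all same-resolution predecessors),
   and `residual` (each block replaced by a projected-shortcut residual
   block).  All blocks use batch normalization.
3. **Post-processing.** The probability map is binarized at 0.5 (strictly
   greater; a tie is background) and only the two largest connected
   components (8-connectivity; area ties broken toward the smaller bounding
   column) are kept — the RAs appear as at most two regions, so anything
   beyond two components is segmentation error.
4. **Measurement.** With two regions, the pixel gap `d` is the number of
   background columns strictly between the minimum bounding rectangles of
   the left and right muscle (clamped at 0 when the rectangles touch or
   overlap laterally); with one region `d = 0` by definition.  The physical
   distance is `D = Px·d` with `Px` the lateral (column-axis) effective
   pixel size after crop+resize.  DRA is called at `D ≥ 25 mm`; both the
   threshold and its strictness are configurable.

## Training protocol

Datasets are split at the **patient** level (ratio 7:1:2
train/val/test), since repeated views of one abdomen are strongly
correlated; allocation uses largest-remainder rounding on a seeded
permutation, so subset patient counts deviate from exact proportions by at
most one.  Augmentation is horizontal flipping (probability 0.5, applied to
image and mask) and a contrast gain drawn uniformly from [0.7, 1.3],
applied around the mid-gray pivot 128 to the image only.  The loss is the
mean two-term binary cross-entropy; a foreground-only cross-entropy
`−Σ y log x` admits the degenerate all-foreground minimizer, so background
errors are penalized as well.  Optimization is Adam with learning rate
1e-3 and first-moment decay 0.9 (batch size 8).  After every epoch the
validation Dice is computed in inference mode (no parameter updates); the
best-scoring parameters are retained and training stops early after 15
epochs without improvement.  All randomness (initialization, shuffling,
augmentation) flows from a single integer seed, and the stack runs on
plain NumPy arrays, so CPU runs are bit-reproducible.

The networks are implemented directly in NumPy (NHWC float32) with
explicit forward/backward passes recorded on a small tape; gradients are
verified against central finite differences in the test suite.  This keeps
the package dependency-light and deterministic, at the cost of training
speed — which is acceptable because the architectures are fully
convolutional and correctness, not throughput, is what the package
guarantees.

## Evaluation metrics

Per image: Dice `2|A∩B|/(|A|+|B|)` and IoU `|A∩B|/|A∪B|` in percent
(single-foreground-class form; a two-class foreground/background mean is
available behind a flag), and the Hausdorff distance
`max(h(A,B), h(B,A))` over the **full** foreground point sets, in mm, using
exact Euclidean distance transforms with the per-axis pixel sizes (verified
against the brute-force max–min definition).  Two empty masks are defined
to agree perfectly (Dice/IoU 100, flagged), and the Hausdorff distance is
undefined (error) when either mask is empty.

Distance agreement: the average physical distance error
`APDE = mean_i p_i·|d_i − d̂_i|` (mm) between reference and automatic pixel
gaps, the sample Pearson correlation, and Bland–Altman statistics
(mean difference and 95% limits of agreement `mean ± 1.96·sd`, sample sd).
Repeated experiments aggregate per-repeat test-set means as mean ± sd
(n−1).

## The phantom generator

Clinical RA ultrasound with expert annotations is not publicly available,
so the pipeline is exercised end-to-end on seeded synthetic phantoms that
emulate the salient content of a transverse abdominal frame:

* **Geometry.** Two lens-shaped hypoechoic muscle bodies (default 18 mm
  wide, 9 mm thick on a 256-px, 0.3 mm/px grid) separated laterally by a
  configurable gap.  Every column of a muscle's lateral span contains at
  least one mask pixel and all column runs share the body's center row, so
  each body is connected, its lateral extent is exact, and the recorded
  `true_gap_px` equals exactly the count of empty columns between the two
  components.  A requested gap of 0 generates the two bodies in adjacent
  columns, i.e. one merged region.  Positive sub-pixel gaps round to at
  least one pixel so the two-region topology is preserved.
* **Texture.** Speckle is the magnitude of a low-pass-filtered (σ = 1.2 px)
  complex Gaussian field — Rayleigh-like, the simplest ultrasound-looking
  model — normalized to unit mean and scaled by per-class means
  (fascia outline 205, background tissue 115, muscle interior 70, floor 25),
  plus a few bright/dark distractor blobs in the tissue.  The class-mean
  ordering fascia > tissue > muscle therefore holds for every seed.
* **Raw-frame mode** embeds the frame in a black canvas with small bright
  text-like pixel clusters scattered in the periphery (≥ 2 px away from the
  scan region), recording the true crop rectangle, which makes periphery
  stripping exactly checkable.
* **Cohorts.** `generate_dataset` draws one latent gap per patient
  (22% below the 25-mm DRA threshold, the rest above, emulating a
  postpartum screening population) and 4–11 views per patient whose gaps
  jitter by 10% (relative, Gaussian) around the latent value, so views of
  one patient are correlated — which is exactly why splitting is done at
  the patient level.

What the phantoms do **not** model: attenuation, shadowing, beamforming
geometry (sector scans), posture-state variation, inter-subject anatomy
beyond gap/size jitter, and annotator disagreement.  Passing the end-to-end
tests therefore shows that the pipeline's machinery is correct and
trainable, not that the reported clinical accuracy transfers to real
ultrasound.

## Numerical choices and edge cases

* Otsu ties broken toward the lower level; constant images are an error.
* Periphery stripping declares "no periphery" (returns the full frame)
  when more than 10% of the thresholded foreground falls outside the
  largest component's rectangle — on an already-cropped speckle frame Otsu
  splits scan content rather than finding a rim, and this guard makes the
  operation idempotent.
* Binarization is strict (`p > 0.5`); component area ties break toward the
  smaller bounding column; no hole-filling or morphological smoothing is
  applied after component selection.
* The gap convention counts background columns strictly between inclusive
  bounding rectangles; the alternative edge-to-edge reading differs by one
  pixel, and one convention had to be fixed — this one makes `d` the width
  of the empty corridor and is what the phantom records.
* BCE probabilities are clamped to `[1e-7, 1 − 1e-7]`; the training
  gradient is taken with respect to the logits (`(p − y)/N`), which is the
  numerically stable form of the same derivative.
* Batch-norm running statistics (momentum 0.1) are used for validation and
  inference; max-pool gradients are split evenly among tied maxima.
* Checkpoints store the parameter and buffer arrays positionally together
  with a JSON config header.

## Problem sizes used in the shipped benchmarks

The scaled end-to-end benchmark trains the residual variant at depth 3
with 8 base channels on 200 phantoms (128×128 px at 0.4 mm/px, muscle
width 14 mm, latent gaps ~2–22 mm) for up to 10 epochs with batch 8 and
lr 1e-3, and evaluates on 40 held-out-patient phantoms.  These sizes give
a single-CPU run a few minutes long while leaving the task non-trivial
(the network must localize both bodies and their medial edges to within a
pixel or two for the gap metrics to pass).  Unit tests use 32–96 px
phantoms and depth-2/3 networks with 2–8 channels.

## Known limitations

* Sector (curvilinear) scan geometry is out of scope; frames are assumed
  rectangular with laterally aligned columns.
* No per-patient aggregation over locations/postures: the measurement is
  per image.
* The NumPy training stack is single-threaded BLAS-bound; it is meant for
  desk-scale experiments, not full-resolution clinical training.
* Burned-in text inside the scan region (rare) would survive periphery
  stripping and is not handled.
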