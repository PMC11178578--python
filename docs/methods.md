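# Methods

This note records the modelling and numerical choices behind `sellarnet`,
what the synthetic scenes do and do not emulate, and the known limitations.

## Problem setting

During the sellar phase of endoscopic pituitary surgery the sphenoid-bone
surface shows two large, visually distinct depressions — the sella and the
clival recess — and four small bony imprints of structures that must not be
damaged: the left/right carotid and left/right optic protuberances. The
task is joint semantic segmentation of the two regions (3 classes with
background) and point-landmark regression of the four protuberances from a
single RGB endoscopic frame. Annotated clinical data is scarce and
incomplete: region labels are generally present, but each landmark is
annotated on only a subset of frames, which drives most of the design below
(loss masking, presence head, weighted sampling, per-structure metrics).

## Network

An HRNet-style backbone maintains four parallel resolutions. Stage depths
follow the published high-resolution-network convention — stage 1: four
bottleneck units; stages 2–4: 1/4/3 exchange modules of four basic residual
blocks per branch — but every depth is configurable, and the `tiny` preset
(width 8, one module of one block per stage, 96×96 inputs, ~260 k
parameters) exists so that the full two-phase pipeline trains on a single
CPU core in minutes. Construction asserts the channel/resolution contract:
fused channels = 15 × base width at 1/4 input resolution.

Choices the architecture description leaves open, and how they were fixed:

* **Fusion operators.** Downsampling by repeated stride-2 3×3 conv + BN
  (ReLU between steps, none after the last); upsampling by 1×1 conv + BN +
  bilinear interpolation; contributions summed, then ReLU.
* **Landmark head output.** Coordinates are regressed as 8 sigmoid-bounded
  values normalized by image width/height. Bounded outputs keep the Wing
  loss well-behaved and make the head resolution-independent; the
  alternative (absolute pixel regression) is strictly a rescaling.
* **Pooling.** "Average pooling with output size 1" is implemented as
  adaptive (global) average pooling, so any input resolution divisible by
  32 is accepted.
* **Presence head.** A 4-logit linear head on the pooled features predicts
  whether each landmark is annotated/visible. It exists to give the focal
  term a classification target (see below) and is optional; without it the
  focal term is zero.

## Losses

`Loss = w1·Dice + w2·BDL + w3·Wing + w4·FL`, defaults (0.9, 0.1, 0.8, 0.2).

* **Soft Dice** per foreground class, averaged over classes flagged
  annotated; smoothing constant 1e-5.
* **Boundary loss** integrates predicted class probability against the
  signed Euclidean distance map of the target region (negative inside,
  positive outside, distances in pixels, computed by
  `scipy.ndimage.distance_transform_edt`). It is the only term allowed to
  be negative; empty or unannotated target classes are skipped.
* **Wing loss** on coordinate errors scaled by 100 (percent-of-image
  units), ω = 10, ε = 2 — the defaults of the loss's original formulation;
  logarithmic inside ω, linear beyond, continuous at the joint. Coordinates
  of unannotated landmarks are masked from both value and gradient; with no
  annotated landmark the term is exactly 0 with zero gradient.
* **Focal loss** (γ = 2, α = 0.25) is attached to the presence logits with
  the annotated flags as targets. The compound objective's description
  pairs FL with landmark detection but a pure coordinate head offers no
  natural classification target; the presence-head reading keeps the term's
  role (robustness to the heavy annotation imbalance) while staying
  architecturally minimal. This is an implementation choice, flagged as
  such.
* Ablation variants are selectable by configuration: pixelwise
  cross-entropy or generalized Dice (class weights 1/volume², guarded
  against empty classes) for segmentation, MSE for coordinates, boundary
  term off.

The reported `LossBreakdown.total` is the float64 weighted sum of the term
values; optimization backpropagates the float32 graph.

## Training

SGD with momentum 0.9, weight decay 0, linear learning-rate decay from 0.01
at epoch 0 to 0.0001 at the final epoch (the minimum is reached exactly at
the last epoch). Phase 1 freezes the landmark and presence heads and
optimizes only `w1·Dice + w2·BDL`; excluding the landmark terms from the
objective (rather than merely freezing the head) keeps the logged loss
components interpretable and is equivalent under freezing. Phase 2
unfreezes and uses the full objective. The backbone trains in both phases.

Gradients are clipped to a global L2 norm of 5 before each update. The Wing
term's percent-scale errors produce coordinate gradients two orders of
magnitude larger than the segmentation terms at the phase-2 transition;
without clipping the landmark head's sigmoid saturates early in phase 2 and
recovery is slow. Clipping is a stability measure and does not alter any
converged result in the benchmark runs.

Batch size defaults to 8; image intensities are scaled to [0,1] then
normalized with mean 0.5, std 0.25. Non-finite losses abort with a
diagnostic. All randomness (weight init, sampling, augmentation) descends
from the config seed; per-epoch loss logs are bit-reproducible on the same
machine.

## Sampling and augmentation

Frames are drawn with replacement, epoch length = dataset size, with
probability proportional to 1 / #{frames with the same annotated-structure
count}. The count includes all six structures (two region classes + four
landmarks) by default; a landmarks-only mode is available since the
convention is not uniquely determined by the sampler's description.

Augmentation applies, per draw with probability 0.5 (a per-sample Bernoulli
reading of "half the training data"; an exactly-half mode was considered
and rejected as it couples samples), one affine composed as shift (≤10 % of
each dimension) → zoom (±30 %) → rotation (≤30°) about the image centre,
identically to image (bilinear), mask (nearest-neighbour) and landmark
coordinates (exact matrix map); vacated regions are filled black to match
the endoscope's dark surround. Landmarks mapped outside the frame are
flagged unannotated. Photometric jitter (brightness/contrast/saturation
±30 %, hue ±10 %, applied in HSV) touches the image only.

## Fold construction

Frames of one patient never straddle folds. Patients are assigned greedily
in decreasing order of total annotation count to the currently lightest
fold (ties among equal-count patients broken by a seeded shuffle). The
greedy heuristic's total imbalance is within the largest single-patient
count of the exhaustive optimum, which the tests verify on enumerable
instances. Fold statistics use population standard deviation by default
(sample std via a flag); the aggregation convention is stated rather than
derivable.

## Synthetic scenes

The generator's contract is statistical structure, not photorealism: a dark
frame with a bright circular field of view, one large central elliptical
region whose diameter is roughly a third of the frame (matching the
published 200–300 px sella on 720-px frames), an elongated inferior second
region, and four subtle bumps placed symmetrically — carotid analogs
lateral at mid-height, optic analogs superior-lateral. Patients carry
persistent styles (tissue colour, region geometry biases, lateral layout
scale); frames add landmark jitter, sensor noise, specular highlights.
Ground truth is always stored; annotation dropout only hides entries in the
visible manifest columns, so models can be scored even on frames whose
labels were withheld. The `hard` preset's per-landmark dropout of 0.35
mirrors a cohort where at most 65 % of frames carry each landmark; the
default cohort shape is 635 frames over 64 patients.

Not emulated: instruments, blood, smoke, motion blur, temporal coherence,
real anatomical texture, and scale/illumination pathologies. Passing the
desk-scale benchmark therefore demonstrates that the pipeline — data
handling, losses, optimization, metrics — is correct and can fit a scene
distribution with inter-patient variability; it says nothing about accuracy
on real surgical video.

## Desk-scale benchmark sizes

The standing benchmark trains the tiny preset on the easy synthetic preset:
250 frames from 10 synthetic patients (200 train / 50 validation,
patient-disjoint), 20 + 20 epochs, batch 8. These sizes were chosen as the
smallest round configuration at which the trained model separates cleanly
from its untrained initialization (sella IoU ≥ 50 %, MPCK20 ≥ 70 % with a
wide margin in practice: ~80–86 % IoU, 100 % MPCK20, ~2.5 px mDistance
across seeds 0–2).

## Degenerate inputs and tie-breaks

* IoU with empty union, precision with nothing predicted, PCK/mDistance
  with no annotated instance: reported as NaN and excluded from means, so
  averages are never silently biased by undefined cells.
* PCK's "20 % of the image" resolves to image *height* (0.2 × 720 = 144
  matches the published radius exactly); width and diagonal references are
  configurable.
* Boundary loss of an all-true or all-false region: signed distance map
  defined as identically zero (the term vanishes rather than diverges).
* `distance_to_mm` clamps a negative lower endpoint at 0 with a warning.
* Mask labels outside {0, 1, 2} are rejected at load time, as are
  annotated landmarks outside the frame.

## Engine export

`export_engine` validates its arguments and then raises a documented
capability error: engine conversion requires an NVIDIA TensorRT runtime and
GPU, and a silent stub would misrepresent an unusable artifact as a
deliverable. Native inference is the supported CPU path.

## Known limitations

* The autodiff core is minimal by design (the ops this model needs, float32
  only, no graph optimization); it trains the tiny preset in minutes but is
  not suitable for the reference width 48 at full 1280×736 resolution —
  that configuration constructs and runs forward passes, but realistic
  training at that scale needs a GPU framework.
* Landmark regression via global pooling + fully connected layers predicts
  one coordinate set per image; it cannot express multi-modal uncertainty
  (heatmap heads would, and are out of scope).
* The sampler assumes annotation counts are a good proxy for frame
  informativeness; on real data this is an approximation.
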