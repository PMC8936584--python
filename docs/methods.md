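# Methods

## The model

The network couples region localization and segmentation in a single
differentiable graph. A frame `I` (grayscale, square working resolution,
intensities in [0, 1]) passes through four stages.

**Coarse proposal.** A compact fully convolutional net with FCN-8-style skip
fusion (five stride-2 stages, channels 16/32/64/96/128; 1×1 score layers at
1/8, 1/16 and 1/32 fused coarse-to-fine and upsampled back to the input
grid) produces a rough multi-label mask `z`. This mask exists only to drive
localization, so capacity is deliberately small; it is trained with
unweighted per-pixel cross-entropy.

**Localization.** The localization net `L` regresses, per region, the four
free parameters of a shear-free affine transform (scales `s_x, s_y`,
translations `t_x, t_y`; the shear entries are structural zeros). Its input
is the coarse mask one-hot encoded over the N+1 classes — making the net
stable under label permutation in magnitude — concatenated with two fixed
coordinate channels in [−1, 1]. The coordinate channels are a design choice:
after global pooling they make bounding-box moments (centroid, extent)
linearly readable, which is exactly what a box-parameter regressor needs.
`L` is eight 3×3 conv/batch-norm/ReLU layers (16·2, 32·2, 64·2, 128·2
channels, stride 2 on every other layer), global average pooling, and a
linear head. The head has near-zero weights and an identity bias, so the
untrained module predicts (approximately) identity transforms and early
training cannot collapse the crops; predicted scales are clamped to
[0.05, 1.5] so the inverse transform always exists.

**Differentiable cropping.** All coordinates use the align-corners
convention: (−1, −1) is the centre of the top-left pixel, so the identity
transform is an exact identity resampling (several tests rely on this).
The grid generator maps the canonical target grid through each transform;
the bilinear sampler evaluates the truncated-kernel sum
`sum_{n,m} x[n,m] · max(0, 1−|x_s−m|) · max(0, 1−|y_s−n|)`, which zero-pads
outside the frame and is differentiable in both the image and the grid —
this is what lets localization train from the segmentation loss.

**Per-crop segmentation.** Three pathways process each crop concurrently
and are shared across regions (parameter count independent of N):

* *Spatial* — three 3×3 stride-2 conv/BN/ReLU blocks with 64/64/128
  channels: rich low-level detail at 1/8 resolution.
* *Handcrafted* — three local-binary-convolution blocks. Each block holds
  `m` fixed sparse anchor filters with nonzero entries in {−1, +1} (a
  fraction `sparsity` of entries nonzero, default 0.5, drawn once from a
  configurable seed), a ReLU, and a learnable 1×1 recombination; stride 2
  sits in the anchor convolution so the resolution plan mirrors the spatial
  pathway. Anchors never update — gradients flow *through* them to earlier
  layers — giving `m·c_out` learnable parameters versus `k²·c_in·c_out` for
  a standard convolution (k²-fold fewer at `m = c_in`). We default
  `m = max(2·c_in, 16)`: the floor keeps the first block expressive on
  1-channel crops. The ReLU realizes the classic binarization step of local
  binary patterns as a differentiable surrogate.
* *Context* — five depthwise-separable stride-2 blocks (16/32/64/96/96
  channels at the desk scale) reach 1/32 resolution fast; a global-average
  pooled descriptor is broadcast-multiplied onto the 1/32 map (maximum
  receptive field) and the result is upsampled to 1/8. The 1/16 and 1/32
  stage outputs are projected to class logits for auxiliary supervision.

Fusion concatenates the three 1/8-resolution maps, batch-normalizes to
balance scales, and applies channel attention
`v_out = v_concat · w_concat + v_concat`, with `w_concat` from a
squeeze bottleneck (1×1 → ReLU → 1×1 → sigmoid, hidden width C/4). A shared
(N+1)-class 1×1 head plus ×8 bilinear upsampling yields per-crop logits; at
inference the per-crop argmax labels are pasted back to frame coordinates
through the inverse transforms.

**Inverse remapping.** By default a crop pastes *every* nonbackground label
it predicts: a region's margin-expanded crop legitimately contains
neighbouring structures (the ventricle crop covers both thin walls at
higher effective resolution than their own crops). A frame pixel claimed
through several crops goes to the crop whose sampling point lies nearest
its centre; exact ties go to the lower region id — deterministic and
order-independent. An own-label-only mode exists for diagnostics. Label
maps are remapped with nearest-neighbour sampling (labels are categorical);
bilinear interpolation is reserved for intensities and features.

## Losses and training protocol

Per-ROI loss: `L_seg = L_p + a1·L_aux1 + a2·L_aux2`, every term a mean (not
summed — so the weights are resolution-independent) per-pixel softmax
cross-entropy, with a1 = a2 = 1; auxiliary logits are upsampled to target
resolution rather than the targets downsampled, which would destroy the
thin wall labels. The network loss is the arithmetic mean of the N per-ROI
losses. Localization pre-training uses smooth-L1 (0.5 r² below |r| = 1,
|r| − 0.5 above) on the free parameters.

Training is two-staged, Adam at lr 1e−3 with plateau reduction (factor 0.5,
patience 5) throughout, full-scale defaults batch 16 and 100 fine-tune
epochs:

1a. the coarse net trains on its own split;
1b. the localizer trains against ground-truth transforms derived from the
    label masks, with the coarse net frozen (its masks are precomputed once
    when augmentation is off).
2.  everything except the coarse net and the anchors fine-tunes jointly.
    The per-ROI target is the ground-truth mask cropped through the
    *current* predicted transform, so prediction and target always share a
    window and the loss is well posed wherever the localizer currently
    points. The localizer trains at 0.02× the base learning rate in this
    stage: it starts near its optimum while the trunk starts from scratch,
    and at the full rate the noisy transform gradients produced by an
    untrained trunk walk it away from the stage-1 solution before any
    useful signal arrives. (A fixed ground-truth-window target was tried
    and destabilizes training for the same reason — the misalignment
    gradient dominates early.)

Ground-truth transforms come from margin-expanded tight bounding boxes
(default margin 0.1 of the box extent per side, so wall pixels at the box
edge are not clipped), in pixel-centre normalized coordinates.

Augmentation (when enabled) applies one random draw per transform — rotation
±15°, shifts ±0.25 of the frame, scale from {0.75, 1, 1.25}, horizontal and
vertical flips — identically to image (bilinear) and mask (nearest),
on the fly each epoch.

## The numerical substrate

No GPU framework is assumed: the networks run on `tanet.nn`, a small
reverse-mode autodiff engine over numpy arrays written for this package.
Heavy operations (convolutions as k² batched GEMMs, batch norm, bilinear
upsampling as a pair of interpolation-matrix products, the grid sampler)
are fused nodes with hand-written backward passes, each verified against
central finite differences in the test suite (the sampler is only piecewise
smooth, so gradient checks run at non-degenerate points away from integer
pixel crossings). Float32 is used for training; running batch-norm
statistics accumulate in float64 but normalization happens in the input
dtype. All randomness flows through seeded `numpy.random.Generator`s, so
runs are bit-reproducible on one machine.

## The phantom generator

Real parasternal long-axis and inferior-vena-cava data with per-region
expert masks are not publicly available, so the generator emulates the
*geometry* of B-mode echo far enough to exercise every component: a dark
cone-shaped sector (apex up, half-angle 38°, radius 0.92 of the frame) on a
black background; in PLAX mode three anechoic bright-rimmed elliptical
chambers (LV, RV, LA) and two thin bright ribbons (SW, PW) hugging the
upper and lower LV border, built as bands of an LV-concentric ellipse;
in IVC mode one elongated bright-walled tube. Wall ribbons stay below 8% of
the frame height — the thin-wall separation difficulty is the hard part of
the real task and is preserved deliberately. Multiplicative unit-mean gamma
speckle (shape 4) keeps contrast geometry-driven, followed by a mild
Gaussian blur (σ 0.7 px). Frames of one synthetic subject share geometry up
to small jitter (position ±0.006, log-scale ±0.025, angle ±1.5°; subjects
differ by ±0.02 / ±0.08 / ±4°), so datasets split subject-wise.

What the phantoms do *not* model: polar-coordinate point-spread functions,
attenuation and shadowing, probe motion, valve anatomy, or anatomical shape
statistics. Passing tests therefore demonstrate that the architecture,
gradients, losses and training protocol work as specified — not clinical
segmentation accuracy.

## Desk-scale study conditions

All training-based checks run at sizes chosen for a single CPU and fixed
before the checks were frozen:

* working resolution 128 px, crop resolution 64 px (full-scale
  configuration: 512/512);
* localization recovery: 50 phantoms (10 subjects × 5 frames), coarse net
  200 steps at batch 8, localizer 80 epochs; held-out mean entry-wise
  transform error ≈ 0.014 (acceptance bar 0.1);
* end-to-end: 30 phantoms (10 subjects × 3 frames), subject-wise 20/60/20
  split, 30 fine-tune epochs at batch 2 (with 18 fine-training frames the
  Adam step count, not the sample count, limits the from-scratch trunk;
  smaller batches buy steps at constant epoch cost), augmentation off for
  determinism and tiny-set stability; held-out mean IoU ≈ 0.86 over the
  five regions.

## Known limitations

* The shared head must tell chambers apart from zoomed crops in which
  global position cues are weakened; with very few training frames the
  right ventricle and atrium are the typical confusions.
* Thin-wall IoU (~0.75–0.8 at desk scale) trails the chambers — boundary
  discretization in crop-to-frame remapping costs proportionally more on
  thin structures.
* The engine is CPU-bound; full-scale 512 px training is functional but
  slow, and batch-norm behaviour at batch 1 relies on running statistics.
* The degenerate optimum of window-consistent targets (zooming into empty
  background) is held off by the pretrained localizer and its reduced
  fine-tuning rate, not by an explicit penalty; starting stage 2 from an
  untrained localizer is unsupported.
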