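# Methods

## Model

Two structurally identical 3D U-Nets are trained as a student/teacher pair.
Each encoder/decoder block is two stages of (3×3×3 convolution → InstanceNorm
→ LeakyReLU). With `use_residual` the block adds a shortcut from its input
(post-activation addition; a 1×1×1 projection when the channel count
changes). With `use_cbam` the block output passes a serial attention gate:
channel attention first (global max- and average-pooled descriptors through a
shared bottleneck MLP of reduction ratio `cam_reduction`, summed, sigmoid),
then spatial attention (channelwise max and mean maps, concatenated, one
convolution of size `sam_kernel`, sigmoid). Downsampling is 2× max pooling;
upsampling is nearest-neighbour repetition followed by a convolution — as
free of checkerboard artifacts as interpolation-based upsampling and markedly
cheaper to differentiate on the numpy backend. A 1×1×1 head produces raw
scores per class; all predictions are softmax probabilities.

The student is optimised by SGD (momentum 0.9, weight decay 1e-4). The
teacher is updated only by the exponential moving average
`z′_t = ε z′_{t−1} + (1−ε) z_t`, ε = 0.99, initialised as a copy of the
student at step 0. Inference uses the teacher by default (EMA-smoothed
weights are the better predictor); `--use-student` switches.

## Losses and schedules

Supervised loss: unweighted mean of voxelwise cross-entropy and soft Dice
loss over foreground classes (smoothing 1e-5). Consistency loss: mean over
classes, then over *reliable* voxels, of the squared difference between the
student's softmax map and the teacher's Monte-Carlo mean probability; the
denominator is the reliable-voxel count, and an empty reliability mask yields
exactly 0. Reliability is the strict indicator `u < I`: a voxel whose teacher
entropy ties the threshold counts as uncertain.

The consistency weight follows `λ(t) = λ_max exp(−5(1 − min(t,T)/T)²)` with
λ_max = 0.1 and ramp length T; the uncertainty threshold ramps from
(3/4)·ln c to ln c on the same shape. Entropy is measured in nats; for two
classes its ceiling is ln 2 ≈ 0.6931.

The joint objective sums the supervised term over labeled cases and the
weighted consistency term over unlabeled cases. One batch holds one labeled
and one unlabeled case; labeled cases are presented as the clean rendering
with probability 5/8 (the configured 5:3 clean:degraded ratio). Student
inputs receive independent Gaussian noise ξ ~ N(0, 0.1) clipped at ±0.2
(volumes are z-score normalised first, so these are in units of intensity
standard deviation); each of the teacher's N = 8 Monte-Carlo passes draws its
own input noise ξ′ and dropout realisation. The consistency target is the
teacher's MC mean probability — the same quantity the uncertainty is
estimated from — rather than an additional stochastic teacher pass; this
saves one forward pass per step and gives a lower-variance target. An epoch
is one pass over the unlabeled pool whenever one exists, so the
supervised-only ablation (λ = 0) sees exactly the same number of optimiser
steps as consistency training.

Dropout sits after every block group: rate 0.5 at the bottleneck, 0.1
elsewhere, active in both networks during training and in the teacher during
Monte-Carlo estimation; deterministic evaluation disables it.

## Numpy backend

No deep-learning framework is used: `uamt3d.autograd` is a small
reverse-mode autodiff engine (im2col convolutions, pooling/upsampling,
attention reductions). Every backward pass is verified against central
finite differences in the test suite. Parameters are float32; convolution
weights use Kaiming initialisation for LeakyReLU.

## Phantoms

Each synthetic case places a half-ellipsoid soft-tissue target (intensity
0.6, the mask) against a planar high-intensity slab (1.0) on a dark
background, plus mild intensity texture (σ = 0.02) so segmentation is not
pure thresholding. Target radii and position are drawn per case from wide
ranges (axes roughly 20–75% of the available extent, centre jitter ±10%
laterally), reflecting how much CTVs vary across patients; masks stay clear
of the volume border and occupy 1–20% of the voxels. The degraded rendering
multiplies the clean volume by a smooth shading field (1 ± 0.30, from an
upsampled 4×4×3 uniform grid), adds Gaussian noise (σ = 0.30, half the
target/background contrast — degradations severe enough that the degraded
domain is genuinely harder than the clean one), and zeroes the outer
`floor(truncation_fraction · width)` lateral columns (default 5%) to mimic a
limited field of view. Each case derives its RNG stream from (seed,
case_index), so any case regenerates independently and datasets are
byte-identical functions of their spec (NIfTI gzip members are written with
zeroed timestamps).

What the phantoms do *not* emulate: scatter and beam-hardening physics,
Hounsfield calibration, anatomical texture, inter-observer contour
variability. Passing the phantom benchmark demonstrates that the training
machinery works and that consistency training extracts signal from unlabeled
degraded data; it says nothing quantitative about clinical CBCT performance.

## Scaled study conditions

The pure-numpy backend on one CPU is orders of magnitude slower than a GPU
stack, so the canned experiments (`uamt3d.experiments`) run at desk scale:
20 cases of 32×32×12 voxels (10% labeled, 20% test), a 3-level U-Net with 4
base channels and `sam_kernel` 3, 15 epochs, replicated over three fixed
seeds (11/12/13). The learning rate is 0.01 rather than the clinical-scale
default of 0.001 because these runs make ~200 optimiser steps rather than
tens of thousands; both benchmark arms share every hyperparameter, so the
comparison isolates the consistency term. The fully supervised sanity run
uses 8 cases, 100% labeled, 60 epochs. The benchmark reports the median
across seeds of the mean test-set Dice of the teacher network.

## Metrics

A surface voxel is a mask voxel with at least one face-adjacent
(6-connectivity) background neighbour; the array boundary counts as
background. 95HD and ASD pool the directed nearest-surface distances of both
directions before taking the 95th percentile (numpy linear interpolation) or
the mean — the symmetric construction that is standard in segmentation
benchmarking, even where one-directional shorthand appears in print.
Distances use physical spacing by default with a voxel-unit option. Edge
conventions: both masks empty → overlap 1, distances 0; exactly one empty →
overlap 0, distances undefined (reported as missing). Argmax ties at
inference go to background, the conservative choice for a target volume.

## Known limitations

* The backend is single-threaded numpy; clinical-resolution volumes
  (400×400×48) are configurable but impractically slow to train on.
* Nearest-neighbour + conv upsampling and the 5:3 modality ratio are fixed
  design choices, not tuned.
* The uncertainty threshold schedule and λ ramp follow the established
  mean-teacher conventions; neither is calibrated per dataset.
* The SSL benefit measured on phantoms is trend-level (a few Dice points at
  the margin); the benchmark is a direction-of-effect check, not an effect
  size estimate.
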