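# Methods

## Problem setting

Echocardiography records 2D tomographic video slices (views) of the
3D heart; standard views (apical four-chamber A4c, apical two-chamber
A2c, parasternal long-axis PLAX, apical five-chamber A5c) show
different walls and valves, and clinical diagnoses routinely
triangulate across several of them. `echofuse` implements a multiview
video-classification pipeline for binary disease detection from three
views of the same echo study, together with the single-view and
late-fusion comparators needed to quantify what joint processing of
the views adds.

## Models

**Single-view backbone.** The per-view trunk is X3D-Medium, a
channel-separated 3D-convolutional video network: a 24-channel stem
(1x3x3 spatial convolution followed by a 5x1x1 depthwise temporal
convolution), then four residual bottleneck stages of depths 3/5/11/7
with output widths 24/48/96/192, inner widths 2.25x (54/108/216/432),
squeeze-excitation (ratio 1/16) on every other block and swish inner
activations. Spatial resolution halves at the stem and at each stage
(32x total); the temporal axis is never downsampled. The classifier
head projects 192 -> 432 -> (pool) -> 2048 -> classes; with the
400-class reference head the model has 3,768,690 trainable parameters
(3.8M at one decimal). A `tiny` preset — five plain conv-BN-ReLU
blocks on 16x32x32 clips — exercises the identical contracts at CPU
speed.

**Mid-fusion multiview architecture.** Each view's clip passes through
its own trunk (no weight sharing across view slots; views carry
designated anatomical meaning, and slot-specific parameters are the
reading consistent with the 230M reference total). The per-view
embeddings (B, C, T, H, W) are stacked along a view axis V and fused:

1. flatten to (B, C, V, THW); 2D conv (3x3) + BN + ReLU across
   (view, spatiotemporal) -> C6 channels;
2. reshape to (B, C6*T, V, H, W); 3D conv (3x3x3) + BN + ReLU across
   (view, height, width), expanding channels by the expansion factor
   (128 at full scale) — time rides along in the channel axis at this
   stage, exactly as the fusion is specified;
3. reshape to (B, C''*V, T, H, W), global average pool over (T, H, W),
   one fully connected layer, sigmoid (binary) or softmax (multiclass).

The two fusion widths are free knobs; the defaults (C6 = 4, expansion
128, 3x3(x3) kernels) were fixed once so that the full-scale model
(three 64x224x224x3 inputs through X3D-M trunks) totals 232.5M
parameters (230M at ten-million precision) — the documented reference total for the full-scale model.
The tiny preset uses C6 = 8, expansion 8.

**Late-fusion comparator.** The arithmetic mean of the three
single-view sigmoid scores.

**Numerical substrate.** All layers (2D/3D grouped convolutions, batch
norm, ReLU/swish, squeeze-excitation, linear, pooling) are implemented
in numpy with explicit forward/backward passes, verified against
central finite differences in the test suite. Explicit backward passes
are what make grad-CAM and guided backpropagation straightforward: any
module boundary exposes its activation and gradient. Convolutions
accumulate one BLAS matmul per kernel offset, which is efficient at
the clip sizes trained here. Batch statistics use the biased variance;
running statistics use momentum 0.1; eval mode freezes them.

## Preprocessing

The ultrasound cone is the only time-varying region of an echo frame.
The cone mask is the set of pixels whose temporal variance of the
grayscale mean exceeds a threshold; by default Otsu's threshold is
applied to log1p(variance). The log compression matters: the raw
variance image is trimodal (static background ~0, speckle ~sigma^2,
moving walls much higher) and Otsu on the raw image can split
speckle-vs-wall instead of background-vs-cone. Erosion then dilation
with disk elements (radius 3 at 224-pixel scale, scaled proportionally)
removes thin moving structures such as ECG traces; the largest
connected component is kept (one cone per video). The video is zeroed
outside the mask, cropped to the smallest enclosing square (centered on
the tight bounding box, zero-padded if it overhangs), resized
bilinearly to 224x224 (masks nearest-neighbor), and cut to the first
64 frames, zero-padding shorter videos. A `random` start mode supports
inference-robustness probes. Frame rates are carried as metadata but
never resampled. Pixels enter the model as intensity/255 in [0, 1].
Coordinates are 0-based with half-open ranges throughout.

## Training protocol

Data are split 70/15/15 into train/development/test **by patient**
(largest-remainder integer rounding over shuffled patients); a
leakage check runs on every experiment. Studies missing any required
(view, doppler) combination are excluded before comparison so single-
and multiview models see identical studies; among duplicate candidate
videos the first by path sort order is used. Optimization is SGD
(momentum 0.9, weight decay 1e-4) on binary cross entropy (sigmoid
head) or cross entropy (softmax head), with reduce-on-plateau decay of
the learning rate monitoring development loss: a relative 5% threshold
by default, decay after more than `patience` consecutive
non-improving epochs, counter reset on decay. Hyperparameter sweeps
draw the learning rate log-uniformly from [1e-6, 5e-2], patience from
{3, 5, 7, 10} and factor from {0.3, 0.5, 0.7}, with per-trial fixed
seeds. Augmentation (training data only) draws one random resized crop
in [0.95, 1.0], one intensity jitter in [0.8, 1.2] and one rotation in
[-5, 5] degrees per clip, applied identically to all frames.
Every epoch is checkpointed; task models keep the highest-development-
AUC epoch (ties to the earliest), view/doppler classifiers the
lowest-development-loss epoch. The view/doppler recipe (lr 0.01,
factor 0.5, patience 50, absolute threshold 0.01, 1,000 epochs) is
provided as a preset.

## Evaluation

AUC is the Mann-Whitney concordance probability with ties counted 1/2.
Operating thresholds come from one of four rules — maximal geometric
mean of sensitivity and specificity, maximal F1 on the development
set, or the threshold fixing sensitivity (specificity) at 0.800 on the
test set — scanning midpoints between adjacent sorted unique scores
(plus +-infinity sentinels for the maximizing rules; the fixed rules
use finite candidates only, and error when 0.800 is unattainable,
reporting the attainable maximum). Exact fixing is generally
impossible on finite data, so "fixed at 0.800" means the threshold
attaining the smallest sensitivity >= 0.800 (ties toward the larger
threshold). Confidence intervals are 5th/95th percentiles of 1,000
joint (score, label) bootstrap resamples; single-class resamples are
redrawn, and a metric undefined in more than half the resamples is an
error rather than a number. Paired AUC differences use DeLong's
placement-value variance estimate with a two-sided normal p-value
(p = 1 when the variance estimate is zero with equal AUCs); families
of comparisons are Bonferroni-adjusted (p*m capped at 1) with the
significance threshold kept at 0.05 — family size 4 in the standard
report (multiview vs three single views and vs their average).
Stratified reports reuse the single global threshold and skip
single-class strata with a warning. PPV/F1 with no predicted
positives are reported as missing, never as zero.

## Explainability

Grad-CAM weights the final convolutional block's activation channels
by the spatiotemporal mean of the target-logit gradient, rectifies the
weighted sum, upsamples trilinearly (linear in T, H and W) to the clip
and max-normalizes per frame (raw values are kept alongside). Guided
backpropagation passes only positive gradients through
positively-activated ReLUs; guided grad-CAM is the elementwise
product. For the multiview model one map per view trunk is produced by
backpropagating through the fusion blocks; the per-view trunk's final
block is the default target layer. Cases are selected at score > 0.95
(confident positives). Localization resolution is set by the final
feature map: the default tiny trunk pools to 2x2 and cannot localize,
so explainability probes use a variant with only 2x spatial
downsampling (16x16 final maps, keeping receptive fields tight around
the evidence); this is an architecture choice, not a change to the
saliency algorithm.

## Synthetic data generator

Each study draws one latent z_v ~ N(0,1) per view, independently. The
binary label is deterministic given the latents: under the `sum` rule,
label = 1 iff (z_1+z_2+z_3)/sqrt(3) exceeds the (1-prevalence) normal
quantile; under `any`, iff any z_v exceeds the per-view cutoff making
the OR hit the prevalence. Videos show a bright sector cone (apex near
top-center, half-angle 32 deg, radius 0.75x frame, tilted +-8 deg by
view so a view classifier has signal) over black background; in-cone
speckle is redrawn per frame (sd 25 on base intensity 70); a bright
wall band at 0.55x cone radius oscillates radially with period 16
frames and amplitude `wall_base_amplitude + wall_amp_per_latent * z_v`
(defaults 0.05 and 0.035 of the frame size) — the amplitude is the
only label-relevant image feature. The band carries attenuated speckle
so every in-cone pixel is strictly time-varying while everything
outside the cone is static except a thin wiggly ECG-like trace with a
moving bright sweep; static text-like annotation blocks sit in the top
corners; optional doppler videos get a colored patch on the band. A
configurable fraction of patients (default 0.2) contributes two
studies to exercise patient-level splitting. Everything is
deterministic given (seed, study index).

Because the label is a noiseless function of all three latents, the
all-view Bayes AUC is exactly 1.0 while a single view's ceiling is the
AUC of one latent against the thresholded sum — 0.78029 at prevalence
0.25 by numerical integration, reproduced by the package's seeded
Monte-Carlo oracle (1e6 draws). This guarantees a measurable fusion
gap for the desk-scale analogue of the multiview-vs-single-view
comparison. What the generator does **not** emulate: acoustic physics
(point-spread function, shadowing, attenuation), anatomy, correlated
speckle, probe motion, or label noise — so passing tests demonstrate
that the pipeline recovers planted cross-view structure, not clinical
performance.

## Desk-scale experiment sizes

The fusion-advantage experiment uses 2,000 studies (64-pixel source
videos preprocessed to 16x32x32 clips), tiny trunks, batch 16, 6
epochs per single-view model and 8 for the multiview model, lr 0.01
with patience-3/factor-0.5 plateau decay; augmentation is identity
here (the planted signal does not need it and the protocol's
augmentation path is tested separately). The localization experiment
uses 250 studies and 20 epochs of the 16x16-map trunk with
lowest-dev-loss checkpoint selection. Calibration simulations: DeLong
type-I error over 500 null replications at n=100; bootstrap coverage
of the nominal-90% AUC interval over 200 replications at n=500 against
a binormal process with known true AUC.

## Known limitations

- numpy training is single-threaded BLAS-bound; full-scale inputs are
  supported for construction and parameter accounting, not training.
- AVI/MP4 decoding requires an imageio codec backend; NPZ and DICOM
  are the reliable interchange formats.
- The DeLong test is mildly anticonservative at very small n (its
  asymptotic normal reference); the calibration simulation quantifies
  this at the sizes used here.
- Guided backprop for the multiview model flows through the fusion
  blocks; per-view maps are therefore joint-model saliency read out at
  one view, the same single-view approximation caveat that applies to
  any mid-fusion architecture.
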