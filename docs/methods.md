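# Methods

## Problem and model

`vesselage` classifies transmission-EM images of brain capillary
cross-sections as coming from an *aged* or *young* brain. The classifier is
a transfer-learning fusion model

    score = sigma( head( [ f_backbone(x),  m ] ) )

where `f_backbone` is a convolutional feature extractor applied to the
224x224x3 preprocessed image `x` (pixels in [-1, 1]), `m` is a 5-long
one-hot metadata vector `[sex_F, sex_M, region_CC, region_HC, region_PFC]`,
`[.,.]` is concatenation, and the head is a small fully connected network
(default: one hidden layer of 256 ReLU units, dropout 0.2) ending in a
sigmoid. The output is the **age-likelihood score**: the probability that
the image shows an aged-brain capillary, with *aged* as the positive class
throughout.

Training minimises binary cross-entropy plus an L2 penalty
`lambda * ||W_head||^2` on the head's weight matrices (default
`lambda = 1e-4`). Backbone layers below a configurable cut point are frozen;
only the final stage and the head are updated, the usual fine-tuning
compromise for small datasets.

### The neural-network engine

The network layer is implemented on a small in-package numpy engine
(`vesselage.nn`): dense and depthwise convolution, inference-mode batch
normalisation, ReLU/ReLU6, max/average/global-average pooling, linear,
dropout, Adam, and a numerically stable cross-entropy on logits. Every
backward pass is validated against central finite differences in the test
suite. Batch normalisation always runs with its stored running statistics
(the standard behaviour when fine-tuning downstream of frozen layers);
at random initialisation these are mean 0 / variance 1.

Five backbones are provided:

| name        | feature dim | default trainable tail        |
|-------------|------------:|-------------------------------|
| resnet50    | 2048        | last bottleneck of stage 4    |
| mobilenetv2 | 1280        | last inverted residual + 1x1  |
| vgg16       | 512         | conv block 5                  |
| vgg19       | 512         | conv block 5                  |
| tiny_test   | 32          | conv blocks 2 and 3           |

The four named architectures follow their published layer layouts (for the
VGGs the feature vector is the global average pool of the last conv block,
512-wide, rather than the 4096-wide fully connected features, keeping the
parameter count dominated by the frozen convolutional stack). When
ImageNet checkpoints are unavailable the builders fall back to He-normal
random initialisation with a warning; a weights file in the engine's `.npz`
layer format is loaded when supplied. `tiny_test` is a deliberately small
three-block network (2x average-pool stem, 8/16/32 channels, final conv
layer at 1/8 of the input side — 28x28 for a 224 input, fine enough to
resolve few-pixel structural differences) that trains in tens of seconds on
one CPU core and carries every training-dependent test and the synthetic
parameter-recovery experiments. Its default cut freezes only the stem and
first conv block: the backbone is randomly initialised, so there is no
pretrained representation worth protecting, and freezing a random middle
block was observed to cap convergence for unlucky initialisations. For the
four named backbones the default cut points always leave the majority of
parameters frozen.

Default optimisation: Adam, batch size 16, 11 epochs. The learning rate is
1e-4 when a pretrained backbone is used (the transfer-learning convention)
and 2e-3 for the randomly initialised `tiny_test` backbone, which has no
pretrained representation to protect and converges too slowly at 1e-4 in
the 11-epoch budget (the rate was chosen on training-loss convergence
across initialisation seeds).

## Preprocessing chain

Fixed order: histogram equalisation -> intensity floor -> resize -> RGB
replication -> affine rescale to [-1, 1].

* **Equalisation** is global, computed on the luminance (channel mean) and
  replicated back across channels; EM "RGB" content is effectively
  single-channel and per-channel equalisation could invent false colour.
  The CDF mapping preserves pixel rank order.
* **Intensity floor**: the Otsu threshold `t` is computed on the luminance
  and pixels below `0.5 * t` are set to 0 (a soft background floor, not a
  binarisation — hard thresholding would destroy the texture the classifier
  relies on). The Otsu maximiser is taken at the *midpoint* of its plateau:
  for strongly bimodal histograms every threshold in the inter-mode gap is
  equally optimal, and implementations that return the plateau's low edge
  would place `t` directly above the background mode, defeating a
  threshold-relative floor.
* **Resize** to 224x224: exact area averaging when the scale factor is an
  integer, antialiased bilinear otherwise; non-square inputs are
  centre-cropped to square with a warning.
* **Rescale**: the representable range of the input dtype maps affinely to
  [-1, 1] (uint8 0 -> -1, 255 -> +1).

## Splitting, leakage and cross-validation

The labelled data is split 90:10 stratified by age. Each class is shuffled
and the first `ceil(0.9 * n_class)` records train. The ceiling rule is
what reproduces the published arithmetic for a 359-image cohort with 161
aged / 198 young: 145 + 179 = 324 training and 16 + 19 = 35 test images
(round-half-up would give 323/36).

Images of the same vessel re-acquired at different magnification or
position are marked by a shared `vessel_group` in the manifest; after the
split, any test image whose vessel also appears in training is dropped.
Splitting is by image, not by mouse (most images come from distinct
animals); grouping by mouse can be emulated by placing the mouse id in
`vessel_group`.

Model selection uses shuffled, age-stratified 10-fold cross-validation:
per fold, the fit portion is augmented 8x, the model retrained, and the
*un-augmented* validation portion scored. The selected configuration is
the arg-max of mean validation AUPRC (ties: higher mean sensitivity, then
listing order). Fold means are reported with 95% confidence intervals
`mean +/- t(0.975, k-1) * sd / sqrt(k)`.

## Augmentation

Each training fold is expanded exactly 8-fold with the symmetry group of
the square (D4): identity, rotations by 90/180/270 degrees, horizontal
flip, and the flip composed with each rotation. On square images these are
exact pixel permutations, so augmentation is lossless and label-preserving.
The named transforms (flip, three rotations) generate a group of order 8;
the three flip-rotation compositions are its only completion, which is how
the fixed factor of 8 is realised. Augmentation happens after
preprocessing (on 224x224 arrays, where the transforms are cheap index
permutations) and is applied only to fit portions, never to validation or
test data; per-item provenance (source id, transform name) makes this
auditable. At the study scale, 324 training images x 8 = 2,592 per epoch,
i.e. 28,512 presentations over the 11-epoch budget, and at least 1,000
augmented samples per class.

## Metrics

Sensitivity TP/(TP+FN), specificity TN/(TN+FP), precision TP/(TP+FP), in
percent, aged = positive. A zero denominator yields an *absent* metric,
never 0. The ranking metric is the area under the precision-recall curve
computed with the step-wise (interpolation-free) estimator; linear PR
interpolation is optimistically biased. The decision threshold before
stratification is 0.5. Calibration is summarised by an equal-width
reliability curve (per-bin mean predicted score vs observed aged
fraction; empty bins are reported with count 0 and absent frequency).

## Traffic-light stratification

Two thresholds `0 < t_low <= t_high < 1` partition scores into
**Green** (`score < t_low`, confident young), **Amber**
(`t_low <= score < t_high`, abstain) and **Red** (`score >= t_high`,
confident aged). The half-open convention resolves the double-booked
boundaries of interval notation: 0.25 with thresholds (0.25, 0.75) is
Amber and 0.75 is Red. `(0.5, 0.5)` reproduces plain thresholding.

Thresholds are optimised on predictions the model has not fit: a 5-fold
cross-validation re-trains the selected recipe and pools the out-of-fold
validation predictions. The published procedure asks to "balance"
sensitivity and specificity on the confident groups while limiting
abstention; this is operationalised as

    maximise   min(sensitivity, specificity) over Green+Red
    subject to Amber fraction <= amber_cap      (default 0.35)

by exhaustive search on a 0.05 lattice. Ties prefer a smaller Amber
fraction, then a wider band symmetric about 0.5. `amber_cap = 0`
degenerates to a single decision threshold. Post-stratification metrics
count Red as a positive call and Green as a negative call; Amber items are
abstentions and are reported as the Amber fraction. Subgroup difference
scores (per sex or brain region) are the mean Red score minus the mean
Green score, in percent; a subgroup missing either confident group has an
absent difference.

## Grad-CAM

For a chosen convolutional layer with activations `A_c`, channel weights
are the spatial means of `d(logit)/dA_c` and the raw map is
`relu(sum_c w_c A_c)`. Because the classifier has a single sigmoid output,
the aged logit is the network output and the young logit is its negation.
Maps are bilinearly upsampled to the 224x224 input frame and
max-normalised to [0, 1]; an all-zero map is passed through unchanged.
The visualisation target defaults to the predicted class. Layers are
addressed by stable hierarchical names (e.g. `stage2_block4.conv3` and
`stage4_block3.conv3` on the ResNet50, giving the early-vs-final layer
pair; `conv1`/`conv3` on `tiny_test`). Overlays alpha-blend a warm-to-cool
colormap with per-pixel opacity proportional to the normalised map, so
irrelevant regions show the untouched grayscale image. Physical scale bars
require a pixel size, which the computational pipeline does not carry, so
overlays omit them.

## Synthetic cohort

The generator renders what the classifier is meant to see in real data: a
bright lumen ellipse, a darker vessel-wall annulus (endothelium plus
basement membrane, carrying its own finer-grained texture), perivascular
blobs abutting the wall (astrocyte-endfoot analogue), dark elliptical
organelle-like bodies scattered through the parenchyma (nuclei,
mitochondria, myelin profiles), multiplicative speckle over the parenchyma,
and additive sensor noise, at 512x512 (the preprocessing chain is
resolution-agnostic; full 4096x4096 frames would only slow the tests).
Determinism: every image is a pure function of (seed, image index).

The organelle distractors are load-bearing for the localisation contract,
not decoration. Global histogram equalisation couples local structure to
global intensity: a thicker dark wall shifts the per-image CDF, which moves
the equalised parenchyma level, so without distractors the *background
brightness* becomes a class cue and a classifier can score well while never
looking at the vessel. The organelles' dark area varies strongly between
images independently of class, which drowns that histogram cue (measured:
background-mean AUC drops from ~0.88 to ~0.7) and keeps the reliable
discriminative signal where the design puts it — in the wall annulus.

The class effect is deliberately localised to the wall: aged wall thickness
is `N(mean_young + effect_size * sd, sd)` (defaults: mean 30 px, sd 6 px,
effect size 3) and the aged perivascular blob rate is twice the young rate
(Poisson means 6 vs 3). Localising the effect makes Grad-CAM claims
falsifiable against stored ground-truth geometry (`ring_mask` reconstructs
the dilated wall annulus in the 224x224 frame). Metadata (sex, region,
synthetic mouse id) is balanced and assigned independently of class, so the
fusion head cannot shortcut through it; a `region_confound` knob exists for
fairness experiments. A configurable fraction of images (default 5%) are
re-acquisitions of an existing vessel at 1.2x magnification sharing its
`vessel_group`, which exercises the leakage guard. An optional unlabelled
cohort renders vessels at the midpoint thickness (the middle-age analogue),
from female mice in CC and PFC only.

What the generator does *not* emulate: tight-junction ultrastructure,
pericytes and mural cell morphology, staining and acquisition variation
across microscopes, section folds and knife marks, or any real-data
texture statistics. Passing the recovery experiments therefore shows that
the pipeline's machinery (preprocessing, augmentation, training, threshold
optimisation, explanation) recovers a known localised effect of realistic
magnitude — it does not certify performance on real EM data.

## Experiment sizes and reproducibility

The parameter-recovery experiment uses 150 images per class, effect size
3, the `tiny_test` backbone, and the full pipeline (90:10 split, leakage
drop, 8x augmentation, 11 epochs, 5-fold threshold optimisation with Amber
cap 0.35), repeated over three seeds with a 2-of-3 majority read-out of
post-stratification sensitivity/specificity >= 90%; the null-effect
control (effect size 0) checks that held-out AUPRC stays inside the 95%
band of a 500-draw label-permutation null. These sizes keep a complete
run in the low minutes on one CPU core while leaving the effect estimate
well clear of both thresholds.

A single user-facing seed fans out to split/fold/augmentation/initialisation
sub-seeds through named SeedSequence derivations, so any two runs with the
same resolved configuration and seed produce identical artifacts; every CLI
command writes its resolved configuration and package version next to its
outputs.

## Known limitations

* No pretrained weights ship with the package; on real data the named
  backbones start from random initialisation unless a weights file is
  provided, and published real-data benchmark numbers (which depend on
  ImageNet features, unpublished hyperparameters and the original data)
  are out of reach by design.
* The numpy engine is single-threaded BLAS-bound; it is sized for the
  bundled experiments, not for training large backbones.
* Batch normalisation never updates running statistics, so unfreezing
  layers below a batch-norm and training long would not match
  framework-default behaviour.
* Automatic near-duplicate detection is out of scope; the leakage guard
  trusts the manifest's `vessel_group` annotations.
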