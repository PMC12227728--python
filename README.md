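# vesselage

Age classification of blood-brain-barrier electron-microscopy images, with
traffic-light uncertainty stratification and Grad-CAM explainability.

## The problem

The blood-brain barrier (BBB) — endothelium, tight junctions, pericytes,
astrocyte endfeet and basement membrane around brain capillaries — changes
structurally with age, and transmission EM is the only modality that
resolves those sub-250 nm components. Manual analysis of EM capillary
images is slow and prone to selection bias. `vesselage` is a pipeline for
labs that want a data-driven readout instead: given a manifest of capillary
cross-section images with per-image metadata (mouse, sex, brain region,
duplicate-vessel group), it trains a classifier whose output is an
**age-likelihood score** — the probability p(aged | image, metadata) — and
then turns those scores into auditable, abstention-aware calls.

## The model

    score = sigma( head( [ f(x), m ] ) )

* `x`: the image after a fixed preprocessing chain (histogram equalisation
  on luminance, Otsu-derived soft background floor, resize to 224x224,
  replication to 3 channels, rescale to [-1, 1]);
* `f`: a convolutional backbone with its early layers frozen
  (ResNet50 / MobileNetV2 / VGG16 / VGG19, plus a `tiny_test` network that
  trains in seconds on CPU); only the final block and the head are trained;
* `m`: one-hot metadata `[sex_F, sex_M, region_CC, region_HC, region_PFC]`,
  fused by plain concatenation so its influence stays traceable;
* training: binary cross-entropy + L2 on the head, Adam, batch 16,
  11 epochs, with every training fold expanded exactly 8-fold by the
  dihedral group of the square (identity, three rotations, horizontal flip,
  and flip-rotation compositions — all lossless pixel permutations).

Model selection is by mean area under the precision-recall curve over a
shuffled, age-stratified 10-fold cross-validation. Scores are finally
stratified by two thresholds into **Green** (confident young), **Amber**
(abstain) and **Red** (confident aged); the thresholds are optimised on
pooled out-of-fold predictions of a 5-fold cross-validation to maximise
min(sensitivity, specificity) on the confident groups under a cap on the
Amber fraction. Grad-CAM maps at any convolutional layer show which parts
of an image drove its score. Details and rationale: `docs/methods.md`.

A seeded synthetic-data module renders capillary-like images (bright lumen,
dark vessel-wall annulus, perivascular endfoot-like blobs, speckled
parenchyma) with a tunable, wall-localised class effect and ground-truth
geometry, so the whole pipeline is testable without any real data.

## Worked example

Generate a synthetic cohort (150 images per class, wall-thickness effect of
3 SD), train, optimise thresholds, and evaluate the held-out test split:

```
vesselage synth --n-per-class 150 --effect-size 3 --seed 1 --out data/
vesselage train --manifest data/manifest.csv --out run/ \
    --backbones tiny_test --cv-folds 5 --seed 1
vesselage stratify --checkpoint run/model.npz \
    --train-manifest run/train_manifest.csv --out run/ --seed 1
vesselage evaluate --checkpoint run/model.npz \
    --thresholds run/thresholds.json \
    --manifest run/test_manifest.csv --out run/eval
```

The `train` step reports the 90:10 split (here 270 training images and 30
test images, of which 3 are dropped for sharing a vessel with training
data) and the cross-validated comparison, then `evaluate` prints the
post-stratification summary:

```
split: train n=270, test n=30 (3 dropped as leaky)
tiny_test: AUPRC 97.8 (sens 89.6, spec 90.4)
selected backbone: tiny_test
...
{
  "sensitivity": 100.0,
  "specificity": 85.71428571428571,
  "precision": 91.66666666666667,
  "auc_pr": null,
  "n_evaluated": 18,
  "amber_fraction": 0.3333333333333333
}
```

Read: of the 27 held-out test images, the model abstained (Amber) on 33%;
among the remaining 18 confident predictions it recalled every aged vessel
(sensitivity 100%) and cleared 86% of young vessels (specificity), with
92% of Red calls truly aged (precision). `run/eval/` also contains the
pre-stratification metrics (threshold 0.5 and AUPRC), per-sex and
per-region score-difference tables, a reliability diagram, and the
stratified per-image CSV. `vesselage explain` adds Grad-CAM overlay panels
(on ResNet50, the early/final layer pair `stage2_block4.conv3` and
`stage4_block3.conv3`). On an unlabelled manifest, `evaluate` instead
writes the per-region percentage of confident-aged / confident-young /
uncertain images.

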