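# dlrs — deep-learning radiomics score for tumor-microenvironment prediction from CT

`dlrs` implements a CT-imaging classifier of the binary tumor-microenvironment
(TME) state of gastric tumors: a fusion network that combines a
multi-resolution convolutional backbone with squeeze-and-excitation (SE)
channel attention and a bank of 361 hand-crafted radiomics features, trained
with a focal-loss objective. Its output — the deep-learning radiomics score
(DLRS) — is the probability that a tumor is TME-high. The package is aimed at
quantitative-imaging researchers who want a fully inspectable, desk-scale
reimplementation of this class of model; since clinical CT cohorts of this
kind are private, everything is exercised and verified on synthetic phantoms
with planted, class-dependent texture.

## The model

**Preprocessing.** Volumes are resampled to 0.75 × 0.75 × 2.5 mm by trilinear
interpolation and window-normalized to [−150, 150] HU,
v′ = clip((v − lo)/(hi − lo), 0, 1). The network input is built from the
axial slice with the largest tumor cross-section: three 64 × 64 channels —
the normalized CT slice, the slice with background zeroed outside the tumor,
and the binary mask.

**Radiomics bank.** 361 features on the same slice: 9 shape-2D features
(physical units) plus, for each of four gray-level discretizations
(8, 16, 32, 64 bins), 18 first-order, 24 GLCM, 16 GLRLM, 16 GLSZM and 14
GLDM features (9 + 4 × 88 = 361). Pair/run statistics use distance 1 over the
four 2D directions with feature-level averaging; zones and dependences are
8-connected. Features are z-scored with training-cohort statistics.

**Network.** An HR-Net-style backbone keeps a high-resolution stream while
adding lower-resolution, double-width streams that exchange information each
stage; every branch ends in an SE gate (global average pool → C → C/r → C →
sigmoid → channel rescale). The 361 standardized radiomics features pass
through a fully connected embedding; image and radiomics embeddings are fused
in a fully connected layer ending in a sigmoid:

    DLRS = σ(W₂ · ReLU(W₁ · [GAP(image streams) ∥ ReLU(E · x_rad)]))

**Training.** Focal loss FL(p_t) = −α(1 − p_t)^γ log(p_t) with α = 1, γ = 2,
where p_t is the probability assigned to the true class; Adam, batch size 16,
learning rate 1e-3 halved every 10 epochs; augmentation by left/right and
anterior/posterior reflection (p = 0.5 each) and rotation uniform in
(−30°, +30°). The network is implemented on a small numpy reverse-mode
autodiff engine (float64, finite-difference-checked gradients).

**Evaluation.** Mann–Whitney AUC with stratified-bootstrap 95% CI, operating
threshold by Youden's J = sensitivity + specificity − 1 on the training
cohort (positive when score ≥ threshold), confusion-matrix metrics,
calibration curves, and decision-curve analysis
(net benefit = TP/n − FP/n · t/(1 − t)). Guided Grad-CAM renders saliency
heatmaps of the image branch.

## Worked example

```bash
dlrs run out/demo --n 200 --seed 3 --epochs 2
```

which prints (reproducibly for this seed):

```
validation AUC 1.000 (95% CI 1.000-1.000), cutoff 0.695, accuracy 1.000
```

Here 200 phantoms with class-dependent intratumoral texture were generated,
preprocessed, featurized, split 70/30, and a tiny-preset fusion model was
trained for 2 epochs; the planted texture contrast is strong enough that the
held-out cohort separates perfectly, and the Youden cutoff (0.695) is the
score threshold that maximizes sensitivity + specificity on the training
cohort. `out/demo/` contains the feature table, validation scores, the
checkpoint (weights + config + feature-dictionary version + z-score
statistics) and a provenance manifest. The same stages are available
individually (`dlrs simulate / preprocess / extract / predict / evaluate /
explain`) and as library functions.

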