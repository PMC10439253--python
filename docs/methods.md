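# Methods

## Problem and model

The package predicts a binary tumor-microenvironment (TME) class from a
contrast-enhanced CT volume and a manual tumor delineation. Two information
channels are combined: data-driven features learned by a convolutional
backbone from a 64 × 64 three-channel patch around the tumor, and 361
knowledge-based radiomics features describing the tumor's shape, intensity
distribution and texture. Both are embedded and fused in a fully connected
head whose sigmoid output — the deep-learning radiomics score (DLRS) — is the
probability of the TME-high class.

## Preprocessing

Volumes are resampled to 0.75 × 0.75 × 2.5 mm (trilinear for intensities,
nearest-neighbor for masks; masks must share the image grid exactly — no
registration is attempted) and intensities are window-normalized to
[−150, 150] HU, the soft-tissue window, via clip-and-rescale to [0, 1].
Analysis is 2D on the axial slice with the largest tumor cross-sectional
area (mm²; ties broken toward the lower index). The network patch is the
square bounding box of the in-slice mask, expanded by a 25% margin per side
and clipped at the image border, resized to 64 × 64 (bilinear for image
channels, nearest-neighbor for the mask so it stays binary). The masked-image
channel is always the product of the image channel and the mask channel; this
invariant is enforced by the `ModelInput` type and re-established after every
augmentation.

Whether the source model cropped around the tumor or rescaled whole slices is
not derivable from its description; the bounding-box-plus-margin crop was
chosen because it standardizes input size while preserving relative tumor
scale within the patch.

## Radiomics bank

The 361-feature inventory is reconstructed from its printed family counts
(9 shape / 72 first-order / 96 GLCM / 64 GLRLM / 64 GLSZM / 56 GLDM): 9
shape-2D features computed once, plus four equal-width discretizations of the
in-mask intensities (8, 16, 32, 64 gray levels), each contributing 18
first-order, 24 GLCM, 16 GLRLM, 16 GLSZM and 14 GLDM features
(9 + 4 × 88 = 361). This is the only arithmetic consistent with all printed
family counts at standard IBSI family sizes; the exact original composition
is not recoverable, so per-feature value parity with the original is not
claimed.

Conventions (fixed in a versioned feature dictionary, `1.0`):

- Pair/run matrices: distance 1, four directions (0°, 45°, 90°, 135°),
  symmetric co-occurrence counts, features computed per direction and then
  averaged, which makes the feature set invariant under 90° rotations.
- Zones (GLSZM) and dependences (GLDM) use 8-connectivity; GLDM dependence
  requires exact label equality (tolerance 0). Under 8-connectivity the two
  colors of a checkerboard each form a single diagonal-connected zone;
  singleton zones require all-distinct labels.
- GLDM matrices record raw dependent-neighbor counts d ∈ 0..8; emphasis
  formulas weight by dependence size s = d + 1 (the center pixel counts
  itself), keeping small-dependence emphases finite for isolated pixels.
- Gray-level normalizers (Idn/Idmn) use the discretization's bin count.
- First-order order statistics and moments are computed on the raw windowed
  intensities; entropy and uniformity on the discretized histogram, so they
  are the only first-order members that vary across the four settings. The
  18-feature block is nevertheless replicated per setting to preserve the
  printed 72-feature count.
- Shape features are in physical units. Perimeter and mesh surface come from
  marching-squares contours of a lightly smoothed (σ = 0.8 px) mask: raw
  marching squares on a binary grid inflates the perimeter of smooth shapes
  by ~6% (a digital disk's circularity would plateau near 0.94); smoothing
  restores disk circularity to ~0.99 at the cost of slightly rounding sharp
  corners (a 10 × 10 px square's perimeter reads ~37.3 rather than 40).
- Z-scoring uses training-cohort mean and population (denominator n) standard
  deviation; zero-variance features standardize to exactly 0 with a warning.

Every texture feature is verified against naive brute-force enumeration
(explicit pair/run/zone/neighborhood loops) at 1e-9 relative tolerance on
100+ random 8 × 8 label images.

## Network

The backbone is HR-Net-like at desk scale: a stem of two stride-2
convolutions (so the highest-resolution stream runs at ¼ input resolution),
then parallel streams where each added stream halves resolution and doubles
width. Each stage applies conv → ReLU → SE per stream and then a full
pairwise exchange (strided 3 × 3 convs downward, 1 × 1 conv plus
nearest-neighbor upsampling upward). The SE gate is global average pooling
followed by a two-layer perceptron (C → C/r → C, ReLU then sigmoid) that
rescales channels; `identity=True` converts it to a pass-through for the
no-SE ablation. Global-average-pooled stream embeddings are concatenated
with a ReLU embedding of the radiomics vector and passed through one hidden
fully connected layer to a sigmoid.

Presets: `tiny` (2 stages, base width 8, SE ratio 4, ~26k parameters —
asserted < 200k; single-case forward ~3 ms on one CPU core) for tests and
phantom studies; `paper_like` (4 stages, base width 18, 3 streams, SE ratio
16) for fuller runs. The original network's depth/width and SE placement are
unstated; one SE block per stream per stage was adopted.

The engine is a reverse-mode autodiff on numpy float64 written for this
package (conv via im2col, col2im backward). Analytic gradients are verified
against central differences on a random 1% of weights at 1e-4 relative
tolerance (with an absolute escape hatch of 1e-9 for gradients at the
finite-difference noise floor of ~1e-10 at this loss scale).

## Training

Focal loss FL(p_t) = −α(1−p_t)^γ log(p_t) with α = 1, γ = 2, where
p_t = DLRS for class-1 cases and 1 − DLRS otherwise; p_t is clamped at 1e-7
before the logarithm. Optimization is Adam (β = 0.9/0.999) at batch size 16
with the learning rate 1e-3 · 0.5^⌊epoch/10⌋. Augmentation (training cases
only): left/right and anterior/posterior reflections each with probability
0.5 and one rotation uniform in (−30°, +30°) (bilinear for image, nearest for
mask, zero fill). All stochastic steps — initialization, shuffling,
augmentation — consume seeded `numpy` generators, so a fixed config seed
reproduces histories exactly in single-threaded numpy.

Checkpoint selection: the epoch with the best validation AUC (the evaluation
metric; the original procedure is unstated). If the validation split is
single-class, AUC is undefined and the last epoch is kept with a warning.
Epoch count is configurable (tiny-preset default 30).

## Evaluation

AUC is the Mann–Whitney concordance probability with midrank tie credit; the
95% CI is a stratified percentile bootstrap (2000 replicates by default,
seeded) — the original CI method is unstated, and a distribution-free
bootstrap was chosen for reproducibility. The operating threshold maximizes
Youden's J over the distinct observed scores, predicting positive at
score ≥ threshold (matching the published orientation of the DLRS-high
group); ties resolve to the lowest threshold. Calibration uses 10 equal-width
bins with empty bins dropped. Decision curves report net benefit
TP/n − FP/n · t/(1−t) with treat-all and treat-none references; no claim is
made (or asserted) that the model curve dominates the references.

Guided Grad-CAM: channel weights are spatial means of the output-probability
gradient at a chosen activation (default: the last highest-resolution stage),
the rectified weighted sum is bilinearly upsampled to the input size and
max-normalized for rendering; the fine-grained overlay multiplies this by the
guided-backpropagation gradient magnitude of the CT channel (ReLUs pass only
positive gradients in the backward pass).

## Synthetic phantoms

Each phantom is a 64 × 64 × 40-voxel volume at 0.75 × 0.75 × 2.5 mm — a
soft-tissue background (40 ± 8 HU smoothed Gaussian noise) containing one
random interior ellipsoid (longest radius 6–14 mm, axis ratios 0.7–1.0). The
binary class is Bernoulli(0.5) and expresses itself only inside the tumor:
mean 70 HU plus 15 HU for class 1, plus a Gaussian random field (smoothed
white noise rescaled to a target sd, correlation length in physical mm so
resampling remains meaningful) with sd 12 HU / grain 3 mm for class 0 versus
sd 35 HU / grain 1.2 mm for class 1. These defaults were chosen once as a
plausible portal-venous soft-tissue contrast regime whose texture separation
(standardized mean difference > 0.8 on GLCM-contrast-family features) supports
planted-signal recovery in cohorts of a few hundred; all HU values are
clipped into (−200, 300). The signal is planted in texture (visible to both
the radiomics bank and the CNN) rather than in shape so both fusion branches
are exercised. The null configuration removes the mean shift and equalizes
texture, making classes exchangeable.

What phantoms do not emulate: anatomy and organ context, scanner and
reconstruction physics, inter-observer delineation variability,
multi-center heterogeneity, and realistic class overlap. Passing the
planted-signal studies therefore demonstrates that the pipeline recovers a
texture signal it is pointed at — not clinical-grade performance on real
cohorts, whose headline numbers require the original private data.

## Study design for planted-signal experiments

`phantom_experiment` uses a 60/15/25 train/validation/test split: z-scoring
is fitted on the training split, the checkpoint is chosen by validation AUC,
and the reported AUC and its bootstrap CI come from the untouched test split.
Reporting on the selection split would bias null-configuration AUCs upward
(the maximum of several noisy validation AUCs is above 0.5 in expectation),
which was observed and is why the third split exists. Study sizes — 400
phantoms, tiny preset, 12 epochs, a 5-seed grid, a 200-phantom null control
and a no-radiomics ablation — are the package's default desk-scale
configuration; the planted signal saturates well before 12 epochs.

## Known limitations

- The 361-feature composition reproduces counts, not the original values;
  cross-cohort transfer of the original model is out of scope.
- 2D analysis only (largest slice), as in the source procedure; no 3D
  texture, filtered images, or feature selection.
- The autodiff engine is single-threaded CPU float64: adequate for the tiny
  preset and phantom studies, not for full-scale clinical training.
- Marching-squares smoothing trades corner fidelity for disk fidelity in
  perimeter-based shape features (documented above).
- Bootstrap CIs are percentile-method; no AUC-comparison tests (e.g. DeLong)
  are provided.
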