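# Methods

`mfcrad` implements a multi-feature-combined (MFC) modelling pipeline for
predicting local tumor recurrence ("local failure") after surgery or
stereotactic body radiotherapy (SBRT) in early-stage non-small-cell lung
cancer, from pre-treatment CT. Three information sources are fused per
patient: handcrafted radiomic features of the gross tumor volume (GTV),
deep features from a frozen convolutional encoder applied to a fixed volume
of interest (VOI) around the tumor, and clinical covariates. This note
records the model, its assumptions, the defaults, and the numerical
conventions; everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`.

## Input model and geometry

CT volumes are Hounsfield-unit (HU) grids with a binary GTV mask on the same
grid. All analysis happens on a 1 mm isotropic grid: anisotropic inputs are
resampled (trilinear for intensities, nearest-neighbour with a >0.5
re-binarization for masks; the interpolation kernel is an assumption — the
pipeline is calibrated on data already near-isotropic). Arrays are indexed
`(z, y, x)`, 0-based; geometry is taken from the image headers and masks
must share the grid exactly — no registration is attempted. NIfTI-1 is read
and written through nibabel and NRRD through SimpleITK.

## Handcrafted radiomics (105 features)

Six families sized 13 (shape) + 18 (intensity) + 20 (histogram) + 22 (GLCM)
+ 16 (GLRLM) + 16 (GLSZM) = 105 features. Shape and intensity families are
computed on the original volume; histogram and texture families on a
fixed-bin-number (FBN) discretization with 32 bins:

    bin(x) = floor(32 * (x - min) / (max - min)) + 1,  x = max -> bin 32,

with a constant region of interest (ROI) mapping to bin 1. The family
*sizes* are the contract; the member lists are the IBSI-named sets given in
the module docstrings (the exact reference member lists are not public, so
documented IBSI formulations sized to the printed counts are used).

Texture conventions:

* GLCM: symmetric co-occurrences at voxel distance 1 along the 13 unique
  (non-opposite) directions of the 26-neighbourhood; features are computed
  per directional matrix and averaged (IBSI "averaging" aggregation).
* GLRLM: run lengths along the same 13 directions, feature-averaged.
* GLSZM: 26-connected zones, one directionless matrix.
* Degeneracy: zero-variance GLCM correlation is 0; any 0/0 ratio is 0;
  `0·log 0 = 0`; a single-voxel ROI yields zero texture features and a
  warning. These conventions keep all 105 values finite on any ROI with at
  least one voxel.

Shape surface area defaults to exposed voxel-face counting (exact, and
desk-verifiable: a 10 mm cube has 600 mm² of faces); a marching-cubes mesh
mode is available for smoother estimates but is not the tested default.
Axis lengths derive from principal components of the voxel point cloud
(length = 4·sqrt(eigenvalue), IBSI convention).

Correctness is established by independent brute-force enumerators (pair
loops, greedy run walks, flood fill) on random small ROIs — exact equality
on 200 random cases — plus invariances: run/zone-weighted sums equal the
voxel count, translation leaves all features unchanged, and 90° rotations
leave direction-averaged texture features unchanged because the 13-direction
set maps onto itself up to opposites.

## Deep features (512)

An 8×8×8 cm³ VOI centred on the mask centroid (padded at −1000 HU where it
leaves the volume; an error if the GTV exceeds 80 mm on any axis) is
windowed to [−1000, 1000] HU, mapped to [0, 1], and passed through a
U-Net-style encoder: five blocks of two 3×3×3 convolutions with ReLU,
channels 32–64–128–256–512, with 2× max pooling after the first four blocks
(80→40→20→10→5; a fifth pooling would not divide the 80 mm VOI, so the
bottleneck block is unpooled — the standard U-Net encoder layout). Global
average pooling over the final 5³ map yields the 512-vector.

The encoder is *frozen*: only the forward pass exists, implemented directly
in numpy as float32 GEMM convolutions (im2col for the single-channel first
layer, shifted channel-mixing products elsewhere). Weights load from a
named-tensor `.npz` archive validated layer by layer, or are He-initialized
from a seed so the pipeline runs end-to-end with no checkpoint. With random
weights the encoder is a fixed nonlinear random projection — a legitimate
feature extractor for testing the plumbing, but its features are weaker
than pre-trained ones; conclusions about *deep-feature quality* require a
real checkpoint. 3D augmentation (rotation, isotropic scaling, flips,
additive Gaussian noise) is provided for head training; the first element
of every augmented set is the unmodified block.

## Feature fusion and preprocessing

Blocks are concatenated handcrafted → deep → clinical (105 + 512 + 4 = 621
columns for surgery cohorts; 623 for SBRT, whose records add prescription
dose and fraction count). Within every cross-validation fold, in order:

1. **Multicollinearity reduction** on training rows: features are grouped
   into connected components of the |Pearson r| > 0.95 graph (components are
   the minimal closure of the pairwise statement); each component keeps the
   single feature with the smallest univariate two-group p-value against the
   outcome (two-sided Mann–Whitney U by default, Welch t optional; ties go
   to the earliest column). Constant features have no defined correlation
   and are kept as singletons. A cohort-wide mode exists for figure-style
   reporting only; fold-wise is the default because it is the honest one.
2. **Z-score normalization** fitted on training rows; zero-variance features
   map to 0 and are flagged. Test rows always use training statistics.
3. **Gaussian-noise oversampling** of training rows only: minority-class
   rows are first replicated to class parity (the cohorts have 7–9 events
   in ~84 subjects), then every row is replicated 4× with independent
   N(0, (0.05·sd_j)²) noise per feature. The multiplicity default matches
   the image-augmentation multiplicity so the tabular branch sees the same
   effective sample count as the deep branch; the noise scale is a free
   choice (no reference value exists) set small enough to preserve feature
   rank structure.

## Model variants and classifiers

* **PI** — clinical covariates only (gender, age, tumor volume, Charlson
  comorbidity index; + dose and fractions for SBRT).
* **R** — the 105 handcrafted features only.
* **DL** — the frozen encoder's 512-vector through one fully-connected
  sigmoid unit, trained with Adam (lr 1e-3, batch 8, 50 epochs by default)
  on binary cross-entropy. Encoder fine-tuning is unsupported and rejected
  explicitly.
* **MFC** — all blocks.

Backends: logistic regression (L2, lbfgs), RBF-kernel SVM (tolerance 1e-3,
Platt-calibrated probabilities — the score type for ROC is otherwise
unspecified), and a random forest (200 trees; depth either fixed or chosen
by a sweep over {2, 3, 5, 8, 12} that stops at the first depth where
validation AUC falls while training AUC rises). Confusion metrics use a 0.5
score threshold.

## Validation

* **LOOCV**: n folds, each sample held out once; held-out scores are pooled
  into a single ROC because a one-sample ROC is undefined.
* **MCRV**: repeated stratified 70/30 splits. The per-stratum training count
  is round-half-to-even(0.7 × stratum size), computed in exact rational
  arithmetic — the only rounding consistent with the reference counts
  (83/7 → 53+5, 84/9 → 52+6, the latter requiring 52.5 → 52). Per-fold
  metrics aggregate as mean ± SD; the mean ROC is vertically averaged on a
  101-point FPR grid with a ±1 SD band. Fold seeds derive from the master
  seed by a counter-based SeedSequence so any fold replays in isolation.
* AUC is the trapezoid under the empirical ROC, which equals the pairwise
  concordance probability with ties counted ½ (checked exactly against a
  brute-force pair counter).
* Models are compared by a two-sided Student's t-test on fold AUC vectors,
  paired on matched folds by default (identical split seeds across models),
  α = 0.05.

## Synthetic phantom cohorts

No clinical images are distributed, so the generator produces the study
conditions directly: a surgery-like cohort (83 subjects, 7 events, tumors
0.6–6 cc) and an SBRT-like cohort (84 subjects, 9 events, 0.9–4.7 cc, with
fractionation schemes of 3–5 fractions). Each phantom is a 128³ grid at
1 mm: lung-like background at −800 HU, an ellipsoidal tumor at +20 HU base
with mild random anisotropy (axis ratios 0.75–1.3), global Gaussian image
noise (SD 20 HU), and an in-tumor texture field of Gaussian-blurred white
noise (FWHM 3 mm, SD 30 HU at heterogeneity 1). Tumor volumes are
log-uniform over the configured range, matching the right skew of clinical
tumor-size distributions (means ≈ 2.3 cc). Demographics are sampled
uniformly within the reported ranges and carry no label association — the
clinical-only model should perform near chance, mirroring the weak
demographic signal in the application.

Event-positive tumors optionally receive a planted effect: a mean HU shift
and/or a heterogeneity multiplier. No quantitative image–outcome effect size
exists for the clinical cohorts, so the planted magnitudes are properties of
the test harness, not estimates; the acceptance study uses +60 HU and ×1.5,
which makes the image signal strong and the expected model ordering
(MFC ≥ R ≫ PI) unambiguous. What passing tests show: the pipeline detects a
planted image effect, keeps preprocessing fold-local, and reproduces the
qualitative variant ordering. What they do not show: clinical effect sizes,
or the performance of pre-trained deep features on real anatomy — phantoms
contain no vasculature, pleural attachment, or acquisition artefacts.

## Problem sizes and determinism

The acceptance study runs the full 83-subject surgery preset with 20
Monte-Carlo folds and a random-weight encoder; all randomness flows from a
single seed through `numpy.random.SeedSequence`, and identical seeds
reproduce cohorts, features, splits and fold metrics bit-for-bit. The
oracle suites use 200 random ROIs (texture), 500 random score sets (ROC)
and 100 random tables (reduction).

## Known limitations

* The encoder ships without pre-trained weights; the Genesis-style
  checkpoint must be converted to the documented `.npz` layout to reproduce
  transfer-learning behaviour.
* Feature-family member lists follow documented IBSI formulations; where a
  reference implementation chose different members within a family, absolute
  feature values may differ even though the counts and conventions match.
* Wavelet/filtered-image features, DICOM/RTSTRUCT ingestion, nested
  hyperparameter search and survival modelling are out of scope.
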