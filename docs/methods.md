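# Methods

## Problem and model

`omrad` implements a peritumoral-margin radiomics workflow for binary
risk prediction (the motivating use case is predicting microvascular
invasion, MVI, from the hepatobiliary-phase MRI appearance of the tissue
around a solitary hepatocellular carcinoma). The core idea is that the
*region* over which radiomic features are computed is itself a model
hyperparameter: a margin band parameterized by an inward erosion depth
`a` and an outward expansion distance `b` (both in mm),

    band(a, b) = dilate(M, b) \ erode(M, a)

for a lesion mask `M`, with Euclidean-ball structuring elements. The
pipeline sweeps `a, b` over the integers 0–10 mm (120 bands, plus the
unmodified lesion VOI = 121 regions), runs nine feature-selection chains
per region, and picks the *optimal margin region* (OMR) and chain by
ranking internal-test AUC. The chosen logistic signature is then
dichotomized at the training-cohort Youden cutoff, and the resulting
high/low risk groups are compared by Kaplan–Meier/log-rank survival
analysis and by chi-square/Fisher association tests against categorical
radiologic features.

## Geometry

All geometry is computed after resampling to 1.0 mm isotropic spacing
(trilinear for images, nearest-neighbour for masks), so a millimetre is
a voxel. The resampling target and interpolation order are package
choices; nothing downstream depends on the original grid. Morphology is
3D: erosion and dilation are thresholds of the exact Euclidean distance
transform, which makes bands rotation-invariant and lets one pair of
distance fields serve all 121 regions of a lesion. The `(0, 0)` band is
the empty set and is excluded from the sweep; the original VOI is a
distinct 121st region, not the `(0, 0)` pair. Under this convention the
OMR reported for the motivating application, "outer 0 mm / inner 5 mm",
is the inner 5 mm rim of the tumor.

Bands whose erosion consumes a small lesion come back empty; the patient
is dropped from that region's model only (never a hard failure), and
regions evaluable on fewer than half the training cohort are skipped
with a warning.

An organ label map (liver = 1, other labels = nontarget tissue) can be
supplied; each band reports voxel counts per nontarget label and a
`flagged` bit, reproducing the mechanism by which outward expansions
pick up gallbladder, vessels or air. Without an organ map the report is
marked not assessable.

## Features

Only the seven-feature signature of interest is first-class (the
registry is extensible; full catalogue parity is a non-goal):

| feature | filter | class |
|---|---|---|
| `logarithm_firstorder_Minimum` | signed log | first order |
| `logarithm_glcm_Imc1` | signed log | GLCM |
| `original_shape_Elongation` | — | shape |
| `wavelet_LHL_glcm_MCC` | stationary wavelet | GLCM |
| `wavelet_HLH_ngtdm_Busyness` | stationary wavelet | NGTDM |
| `log_sigma_3_0_mm_3D_glcm_ClusterShade` | LoG σ=3 mm | GLCM |
| `wavelet_HHH_glcm_JointEntropy` | stationary wavelet | GLCM |

Filters are applied to the whole volume before masking (texture near the
band border needs spatial context). Choices:

* **Logarithm**: `y = sign(x)·log(|x|+1)` rescaled by `max|x|/max|y|`,
  the common radiomics convention; all-zero input is a fixed point.
* **LoG**: separable Gaussian second-derivative kernels with σ in mm,
  truncated at 4σ, with a zero-sum correction on the derivative tap so
  constants and affine ramps map exactly to zero. A bright blob yields
  a negative centre response.
* **Wavelet**: single-level undecimated (stationary) 3D transform,
  Coiflet-1, periodic boundary, computed as separable circular
  correlation with the analysis filters. The first letter of a subband
  name is the filter on axis 0. For orthonormal filters the transform
  is inverted exactly by convolving each subband with the same filters
  and dividing by 8, which the test suite verifies to ~1e-16. The
  wavelet family behind the canonical feature names is not
  standardized; Coiflet-1 is this package's choice.

Texture features use fixed-bin-width discretization (default 25
intensity units) anchored at the in-region minimum, so all texture
features are invariant to intensity offsets. GLCMs are symmetric,
distance 1, computed per each of the 13 unique 3D directions, normalized
per direction, with features averaged over directions (not merged
matrices); directions with no in-region pair are skipped. NGTDM uses
26-connectivity with neighbours outside the region excluded from the
mean. Degenerate single-level regions return JointEntropy 0,
ClusterShade 0, IMC1 0, MCC 1, Busyness 0 — conventions chosen so flat
phantom regions flow through the pipeline instead of crashing it.
Shape elongation is `sqrt(λ2/λ1)` of the coordinate covariance of the
*original lesion mask* (never the band).

Inter-rater reproducibility filtering uses the two-way random-effects,
absolute-agreement, single-measure ICC (via `pingouin`), retaining
features with ICC strictly greater than the threshold (default 0.75).
The ICC variant is a package choice; the convention in the source
application is not stated.

## Selection chains and signature

Nine chains, each a shrinking left-to-right composition:
`corr+lasso`, `lr+lasso`, `corr+lasso+stepwise`, `lr+lasso+stepwise`,
`xgboost+lasso+stepwise`, `rf+lasso+stepwise`, `gbm+lasso+stepwise`,
`svm+lasso+stepwise`, `lasso+stepwise`.

* `corr`: of each pair with |Pearson r| > 0.90, drop the member with
  the smaller |point-biserial| correlation with the label (strongest
  correlations resolved first, deterministically).
* `lr`: univariate logistic Wald p < .05.
* `lasso`: L1 logistic over a data-driven penalty grid (8 points, three
  decades up from the all-zero boundary), stratified 5-fold CV on
  log-loss, 1-SE rule by default (`lambda.min` available as config).
* `stepwise`: bidirectional AIC on an unpenalized logistic model,
  starting from the incoming set, ≤ 30 moves.
* tree/SVM stages: importance pre-rankers keeping the top `min(20, p)`
  candidates for the subsequent lasso (linear-SVM |weight| for `svm`).

The thresholds (0.90, p < .05), the penalty rule, and the AIC criterion
are conventional defaults surfaced in configuration; the source
application names the stages but not their hyperparameters.

The signature is a maximum-likelihood logistic model on train-mean/SD
standardized features; its score is the linear predictor (ROC and the
Youden cutoff are invariant to the link, so the log-odds scale loses
nothing). Separable designs fall back to a small ridge penalty (1e-4)
with a logged notice.

Cross-validated training AUC re-runs *selection and fitting inside every
fold* (stratified folds); the classic selection-bias leak — selecting on
the full matrix before CV — is explicitly tested against. Internal and
external test cohorts are scored by the model refit on the full training
cohort; CV supplies only the training AUC estimate and tie-breaks.

## Region search and ranking

Every (region, chain) pair is evaluated with a seed derived
deterministically from the master seed and the pair identity, so the
ranking is independent of evaluation order. Ranking: internal-test AUC,
then training CV AUC, then narrower band (`inner+outer`; the original
VOI counts as the widest region), then (inner, outer) order. The
tie-break is invented — ties are essentially absent in continuous-AUC
practice but the ranking must be total and deterministic.

## Evaluation

AUC is the Mann–Whitney concordance probability (ties ½) with a DeLong
95% CI. The Youden cutoff maximizes J over midpoints between adjacent
distinct scores (ties → lower threshold, favouring sensitivity) on the
training cohort only, then is frozen. Kaplan–Meier estimation and the
two-group log-rank test come from `lifelines`; medians and quartiles
report `inf` when not reached. Contingency tests follow mainstream
statistical-software behaviour: Yates-corrected chi-square for 2×2
tables with all expected counts ≥ 5, uncorrected chi-square for larger
tables with all expected ≥ 5, and the Fisher exact test otherwise (2×2
via SciPy; r×c via exact enumeration over tables with fixed margins,
verified against R's `fisher.test`, with a chi-square fallback above an
enumeration cap). P values print to 3 decimals, with values above .999
shown as ">.999" — this convention is required to reproduce standard
published tables.

## Phantom cohorts

The generator emulates hepatobiliary-phase appearance at 1 mm isotropic:
a bright smooth liver background (mean 120, SD 10 after 2 mm Gaussian
correlation), a darker ellipsoidal lesion (mean 80, voxel noise SD 8,
semi-axes uniform 8–12 mm), and a planted margin band (default inner
5 mm / outer 0 mm) whose voxel-noise SD is `effect_size`-fold higher for
label-1 patients (default effect 2.0, base rim SD 12). Labels are
Bernoulli(0.4); survival is exponential with label hazard ratios (OS
median 60 months, HR 2.5; DFS median 36 months, HR 3.0) under uniform
censoring on 24–96 months, so prognostic separation flows through the
label exactly as MVI drives prognosis. A configurable fraction (default
0.25) of lesions gets an adjacent zero-intensity spherical cavity
recorded in an organ label map, exercising nontarget-tissue flagging.
Cohorts split 70/30 into training/internal test; an external fraction is
available. One master seed makes everything bit-reproducible.

Three nuisance components are essential to make the phantom a meaningful
testbed rather than a trivially separable toy:

* per-patient lognormal factors on the background, lesion-core and rim
  noise levels (SD 0.35/0.35/0.2), drawn independently per compartment —
  emulating scanner and biological variability. Without them, any band
  touching the rim separates the classes with AUC 1.0 and the region
  ranking degenerates into tie-breaking; with independent factors, a
  band that mixes in non-rim tissue absorbs label-independent variance
  and is genuinely penalized.
* a per-patient lognormal factor per 1 mm depth shell of the rim
  (SD 0.7). Because a noise *level* is estimable from any sub-sample, a
  spatially uniform rim effect would make every sub-band of the rim
  exactly as informative as the full band and the planted depth
  unidentifiable in principle; depth decorrelation means only the full
  planted band averages shell noise away.
* the resulting rim noise level is clipped to 3–45 intensity units:
  tissue and scanner noise are bounded in practice, and unbounded
  lognormal tails would occasionally produce voxel SDs several times
  the liver–lesion contrast (also inflating the discretized gray-level
  range far beyond what real images show).
* `effect_size = 1` makes the image model label-free by construction
  (the null cohorts used for calibration checks).

What the phantom does *not* emulate: MRI physics (bias fields, motion,
partial volume beyond voxelization), multi-sequence appearance,
non-ellipsoidal lesion shape, and inter-centre heterogeneity. Passing
recovery tests therefore demonstrates that the pipeline's inference
machinery works when its assumptions hold, not that the clinical result
transfers to real scanners.

## Problem sizes and numerical choices

The bundled test and acceptance runs use scaled problem sizes chosen as
a deliberate trade-off between statistical resolution and a laptop-class
single-core run: the full 9 × 121 grid demonstration uses a 60-patient
phantom with the chains' `fast` preset (3-fold lasso CV, 50-tree
ensembles) and 2-fold outer CV; the planted-band recovery study uses
n = 240 per seed over 10 seeds on a reduced band-pair sweep (inner
0–6 mm × outer 0–3 mm, which contains the planted band and
distance-3+ competitors on every side) with the two cheap chains and
3-fold outer CV (the ranking key is the internal-test AUC; outer CV
only tie-breaks). The acceptance script runs the same study on the
wider inner/outer 0–6 mm sweep at a single seed. The null-effect
control uses n = 300 with the full 10-fold CV. Seeds fan out from the master
seed via `numpy.random.SeedSequence` spawning, per stage and per
(region, chain) pair.

Other numerical conventions: lasso penalty grids are data-driven from
the all-zero boundary; empty selections short-circuit with a warning and
score as chance (AUC 0.5); eigenvalues for MCC are clipped to [0, 1]
before the square root; the `(0,0)` band and single-voxel regions follow
the degenerate conventions above.

## Known limitations

* The 121-region sweep is evaluated without multiple-testing
  correction, matching the procedure it implements; the external cohort
  (and the optimism property test) exists precisely because the
  internal-test maximum is optimistically biased.
* The exact r×c Fisher enumeration is exponential and guarded by a cap
  (N ≤ 500, ≤ 12 cells); beyond it the uncorrected chi-square is used
  with a warning.
* Reproduction of the motivating study's cohort-level AUCs is out of
  scope — its raw images are unavailable — so all quantitative claims
  are about phantom cohorts and printed summary tables.
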