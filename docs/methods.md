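# Methods

`tibrad` re-implements, as a tested pipeline on synthetic data, an analysis
that asks whether radiomic features of tibial bone on knee MRI can
distinguish knees without and with MRI-defined tibiofemoral osteoarthritis
(tfOA). The pipeline has six stages: phantom/cohort simulation, rule-based
labeling from MOAKS score records, tibia segmentation, VOI placement,
radiomic feature extraction, and penalized classification with
cross-validated evaluation. This note records the models, the parameters
that matter, and the design choices made where the design was genuinely
open.

## Synthetic phantoms and cohort

Real cohort MRI is not publicly deposited, so every stage runs on
tibia-like phantoms with known ground truth. A phantom is a vertical shaft
(default radius 13.5 mm) flaring into a plateau (default width 30 mm) whose
top bears two Gaussian spines of distinct heights (6 and 4 mm, 12 mm apart)
— the landmarks the VOI stage must find. Axis convention: arrays are
indexed `(x, y, z)` with `x` medial–lateral and `z` vertical; the default
grid is 80×80×96 voxels at 0.5 mm isotropic, i.e. 48 mm of height so that
the plateau, spines, and three stacked 10-mm VOI tiers all fit. Tests and
the acceptance run use 40×40×56 grids at 1.0 mm, which preserve every
geometric relation at a quarter of the voxel count; the problem sizes named
throughout (n = 200 cohorts, 10 phantoms / 5 atlases for segmentation,
3 CV repetitions with a 2×2 hyperparameter sub-grid) are the package's
desk-scale defaults for its own test suite, while the configuration
defaults keep the full printed protocol (k = 10, R = 100, the complete
α/λ grids).

Two class effects are planted, each in the direction the analysis is
expected to recover:

* **Texture homogeneity.** Bone texture is a stationary correlated Gaussian
  field: white noise smoothed with a Gaussian kernel of σ =
  `texture_corr_len_mm` per axis, rescaled to a fixed marginal SD (20 by
  default) and added to a base intensity of 100, plus i.i.d. noise (SD 2).
  OA knees use a longer correlation length (2.0 mm vs 0.5 mm), which lowers
  local intensity variance at equal marginal SD — "more homogeneous" OA
  texture. The effect sizes are free parameters (no quantitative value is
  published); the defaults are chosen once to give a clearly detectable
  effect at n = 200 and are exercised by monotonicity tests (local variance
  strictly decreases over three correlation lengths).
* **Plateau irregularity.** OA outlines are scalloped by a sinusoidal
  radial perturbation with 6 lobes and amplitude 0.25 that (a) cuts inward
  only (radius factor in [1−amp, 1]), so the footprint never outgrows the
  shaft and the compartment mid-column always sits over ≥30 mm of bone, and
  (b) twists with height (8-mm period), so sagittal silhouettes are wavy
  and slice-wise compactness — the shape feature of interest — genuinely
  drops. A static in-plane sinusoid would leave sagittal outlines nearly
  straight.

Each subject also receives a small seeded geometric jitter (±8% on radii,
spine heights and separation, plus an in-plane center offset). Without it
all phantoms are congruent and atlas registration is a trivial identity;
with it, multi-atlas segmentation is a real estimation problem.

Cohorts are stratified, not Bernoulli: exactly `round(n·prevalence)` knees
are tfOA-positive (default prevalence 76/665 ≈ 11.4%), and the three
medial sub-outcomes are stratified at 13.7%, 12.8% and 10.5%. Age ~
N(54.6, 3.7²) years and BMI ~ N(26.8, 4.6²) kg/m² are independent of the
labels by default (a `covariate_association` switch can shift positives),
so covariate-only models are near-chance on synthetic data — unlike the
real cohort, where age and BMI carry signal. That is the main caveat on
what passing tests show: they validate the machinery and the direction of
the planted effects, not the published effect sizes.

What the phantoms do **not** emulate: femur/patella/cartilage anatomy, MRI
sequence physics (bias fields, partial volume), bilateral knees, and any
covariate–outcome confounding.

## MOAKS labels

MOAKS grades are ordinal 0–3 per anatomical site. tfOA is positive when
both primary features are present (definite osteophyte = grade ≥2 at any
site; full-thickness cartilage loss = grade 3 at any site), or one primary
plus ≥2 of three secondaries: a BML/cyst (grade ≥1) not associated with
meniscal or ligamentous attachments; meniscal maceration/degeneration
(grade ≥1) or a horizontal tear; and cartilage loss counted as the
partial-thickness secondary. The partial-thickness secondary is read as
*any* cartilage loss (grade ≥1): full thickness subsumes partial when
counted as a secondary. This reading makes the rule monotone — raising any
grade can never flip a positive knee to negative — which a strict
grades-{1,2}-only reading violates (promoting the only partial-grade site
to grade 3 would delete a secondary). Sub-outcome labels are simple
grade ≥1 thresholds over the three medial tibial surface sites (cartilage,
BML) or the medial tibia osteophyte site. The sampler inverts these rules:
records generated for requested labels re-classify to them exactly, which
is tested exhaustively over all 16 label combinations.

## Tibia segmentation

The multi-atlas component registers each atlas image to the target with an
affine stage followed by a B-spline free-form stage, both optimizing Mattes
mutual information (32 bins, 10% regular sampling); atlas masks are warped
with nearest-neighbour interpolation and averaged into a per-voxel tibia
probability. SimpleITK is the registration backend behind a pluggable
contract; any affine-then-nonrigid MI-optimizing backend satisfies it. A
guard guarantees the returned transform is never worse than identity in
joint-histogram MI (with a 5% slack absorbing pure interpolation loss); if
optimization loses MI — as in degenerate self-registration — the identity
transform is returned and the case is flagged in the diagnostics.

The appearance component is a random forest (100 trees, balanced voxel
subsampling, seeded) over a 49-channel Gaussian scale-space stack: the raw
intensity plus, at each of three scales (0.5, 1.0, 2.0 mm), the smoothed
image, three first derivatives, six Hessian entries, gradient magnitude,
Laplacian, Gaussian curvature (taken as the Hessian determinant), and the
three Hessian eigenvalues sorted descending — 1 + 3×16 = 49. Derivative
kernels are sampled Gaussian derivatives renormalized to be exactly
zero-sum with unit polynomial gain, so constant images have identically
zero derivatives even at sub-voxel σ. The 1+3×16 decomposition and the
scale triplet are package choices; only the channel total is fixed.

Fusion is a weighted arithmetic mean of the two probability maps (default
w = 0.5) thresholded at t = 0.5, keeping the largest 6-connected component.
A QC flag (Dice against the thresholded atlas consensus below 0.8) stands
in for the visual inspection step of a clinical pipeline; manual correction
is out of scope. Dice = 2|A∩B|/(|A|+|B|) is the accuracy metric; two empty
masks are an error, not 0/0.

## VOI placement

The two tibial spines are the two highest surface points of the
column-height map at an in-plane separation of ≥8 voxels; candidate peaks
are regional maxima (flat peak tops are represented by their centroid), and
equal-height ties break toward the smaller medial–lateral index. A flat-top
mask has no two separated maxima and is an error. The vertical plane
through the inter-spine midpoint splits compartments; each compartment runs
from its spine column to the outer border, and for a right knee the medial
compartment is on the lower-x side (a laterality flag flips this for left
knees). The cartilage–bone interface is proxied by the topmost bone voxel
per column — the phantoms (like the segmentation) contain bone only. Per
compartment, the subchondral box starts at the interface height over the
compartment's middle column and extends 10 mm down; the mid and trabecular
boxes stack in the next two 10-mm tiers (heights converted to voxels by
round-half-away-from-zero). The horizontal extent is the central 80% of
the compartment span — the source protocol does not state the in-plane
extent, so it is a configurable assumption — and a compartment with less
than 30 mm of bone below its anchor raises an error naming the compartment.

## Radiomic features

Counts per knee are pinned by `FeatureConfig` and verified by tests:
17 shape (whole bone) + per VOI 3 orientation + 12 histogram + 271 texture.
The 271 decompose as GLCM 11 statistics × {mean, SD over the 13 unique 3-D
directions} = 22; GLRLM 16 × 2 = 32; GLSZM 16; NGTDM 5; LBP 3 radii × (10
rotation-invariant-uniform code fractions + code mean + code SD) = 36; and
Gabor 5 frequencies × 8 angles × {mean, SD, skewness, kurtosis of the
response magnitude} = 160. The itemization reproduces the printed family
totals; where the underlying protocol leaves parameters unstated (gray
levels, Gabor bank, LBP radii) the values here are configuration-pinned
assumptions, not published facts.

Conventions worth knowing:

* Quantization: G = 16 equal-width levels between the in-mask min and max;
  a constant VOI maps to level 1 everywhere (not an error).
* GLCM/GLRLM/GLSZM/NGTDM are computed in 3-D on the masked VOI; LBP and
  Gabor are slice-wise 2-D on sagittal slices. Gabor kernels have their
  mean removed and slices are edge-pad-extended before convolution, so a
  constant image has exactly zero response; frequencies above Nyquist
  (0.5 cycles/pixel) are rejected.
* NGTDM coarseness with a vanishing denominator is set to 10⁶ (documented
  constant, never infinity); busyness and strength fall back to 0.
* Histogram features: min, max, mean, median, SD, skewness, kurtosis,
  range, IQR, 16-bin entropy, energy (sum of squared bin probabilities),
  and the modal-bin centre ("peak"); zero-variance samples set skewness and
  kurtosis to 0.
* Shape: six slice-wise descriptors (compactness 4π·area/perimeter² with a
  Crofton perimeter, convexity, circular variance, radial mean/SD,
  eccentricity) aggregated as mean and SD over sagittal slices, plus
  volume, mesh surface area (marching cubes), sphericity, extent, and
  elongation — 17 values. Single-voxel slices are skipped.
* Orientation: three principal-axis angles of the mask's second-moment
  tensor (major-axis azimuth, major-axis polar angle, second-axis azimuth).

All matrix families are cross-checked against brute-force enumeration
oracles on random ≤8³ volumes; LBP against an independent per-pixel
bilinear-sampling implementation; Gabor against analytic alignment and
DC-free properties.

## Classification

Models are penalized logistic regressions minimizing the mean binomial
negative log-likelihood plus λ·[α·Σ|βⱼ| + (1−α)/2·Σβⱼ²] with an unpenalized
intercept: α = 1 is the lasso, α → 0 approaches ridge. The solver is a
deterministic monotone accelerated proximal-gradient method (MFISTA) with
a spectral-norm Lipschitz step; its objective trace never increases, a
huge λ collapses exactly to the intercept-only solution logit(p̂), λ → 0
matches an unpenalized fit, and the solution objective is verified against
a derivative-free optimizer. Hyperparameters come from the printed grids —
α from 0.1 to 1.0 in steps of 0.05 (19 values) and λ from 0.001 in steps
of 0.009 (17 values ending at 0.145; 0.15 is off-grid) — selected by
repeated stratified k-fold cross-validation (defaults k = 10, R = 100)
maximizing the mean out-of-fold ROC AUC. Out-of-fold scores are pooled per
repetition and the AUC averaged across repetitions (a pooled mode is also
implemented); this choice, like the selection criterion itself, is
unstated in the source protocol and recorded here as the default.
Standardization is fit on training folds only — a dedicated test corrupts
held-out rows and verifies the fold's scaler and coefficients are
unchanged. The only feature pre-filtering is zero-variance removal.

Design matrices: covariates = {age, BMI}; image = the 286 features of each
selected VOI (shape features join only when the selection is `All`);
combined = union. Class weights are uniform despite the 11.4% prevalence.

## Evaluation

ROC AUC is the Mann–Whitney statistic (ties 0.5); PR AUC is
non-interpolated average precision, whose chance level equals the
prevalence (constant scores give exactly prevalence). Confidence intervals
are stratified percentile bootstraps over subjects (default B = 2000,
95%) — the original CI construction is not specified, so bootstrap widths
are not expected to match published ones. Report tables have one row per
VOI selection and columns {covariates, image, combined} × {ROC AUC, PR
AUC}, each cell "estimate (low–high)", with explicit `NA` for missing
cells.

## Known limitations

* The published AUCs (e.g. combined-model ROC AUC 0.80) and the Dice of
  0.96 against manual segmentations were measured on non-deposited
  clinical MRI and are not reproducible here; the synthetic planted-effect
  experiments check directions and orderings, not those values.
* On synthetic cohorts the planted texture effect separates classes almost
  perfectly at n = 200, so sparse elastic-net fits may zero out any single
  feature in favour of a correlated proxy. Effect-direction checks
  therefore read coefficient signs from the ridge limit (α = 0) of the
  combined model, where every informative feature participates, and from a
  shape-family fit where compactness is not shadowed by texture, alongside
  the raw group differences.
* Slice-wise shape and texture descriptors assume near-isotropic in-plane
  spacing; anisotropic grids use the mean in-plane spacing.
* The MOAKS record model covers the sites and features the label rules
  consume; it is not a full MOAKS instrument (no meniscal subluxation or
  bone attrition, which the rules do not use).
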