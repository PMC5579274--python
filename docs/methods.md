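# Methods

`radrisk` implements a complete radiomics risk-assessment workflow for 3D
PET/CT tumour imaging: extraction of a 1615-feature battery per modality from
a tumour region of interest (ROI), univariate association screening,
imbalance-adjusted construction of multivariable outcome models, and
prognostic evaluation with censored time-to-event data.  This note documents
the models, the conventions adopted where several are defensible, what the
synthetic generators do and do not emulate, and the package's numerical
choices.

## Image model and preprocessing

A scan is a 3D scalar grid (`ImageVolume`) with anisotropic voxel spacing in
mm — SUV values for PET, Hounsfield units for CT — plus an aligned binary
`ROIMask` (possibly multi-component: primary tumour and involved nodes).
NIfTI is the reference on-disk format (via nibabel); volume and mask must
share shape and affine.

Texture analysis happens on a resampled, quantized ROI:

* **Isotropic resampling** to s ∈ {1,2,3,4,5} mm. Image values are
  interpolated with a cubic spline, the mask linearly and re-binarized at
  0.5 — a smooth intensity field but a crisp binary ROI. The output grid is
  anchored at the input origin and covers the ROI bounding box padded by one
  output voxel (texture neighbourhoods near the border), clipped to the input
  extent (no data exists outside it). An input already at the target spacing
  is returned unchanged. The interpolation orders are conventions (exposed as
  arguments); nothing in the method constrains them.
* **Quantization** of in-ROI intensities to n_gray ∈ {8,16,32,64} levels,
  computed from ROI voxels only, per scan:
  * *Uniform*: equal-width bins over [min, max];
    level = min(n_gray, ⌊n_gray·(x−min)/(max−min)⌋+1), so min→1 and
    max→n_gray. A constant ROI maps to level 1.
  * *Equal-probability* (histogram equalization): level = ⌊n_gray·P(X<x)⌋+1
    from the lower empirical CDF. With all-distinct values the level
    histogram is flat to within one count; tied values always share a level
    (some levels may then be empty). Both rules are invariant under strictly
    increasing affine transforms of the intensities (equal-probability under
    any strictly increasing transform).

The extraction grid is the full cross product: 5 voxel sizes x 2 quantizers
x 4 gray-level counts = 40 parameter combinations.

## Texture matrices

All four matrix families use merged 3D analysis: one matrix per scan
accumulating the 13 canonical directions of the 26-neighbourhood, not one
matrix per direction. The three neighbour classes (6 face, 12 edge, 8
corner) sit at distances 1, √2, √3 and are treated distance-aware:

* **GLCM** — each unordered in-ROI voxel pair at Chebyshev distance 1
  contributes once with weight 1/d (inverse Euclidean distance, equalizing
  per-unit-length sampling density), then the matrix is symmetrized and
  normalized to sum 1. A single-voxel ROI has no pairs; it is flagged
  degenerate and features fall back to single-level rules.
* **GLRLM** — maximal same-level runs along each direction; a k-voxel run of
  step length d is filed in column round_half_up(1 + (k−1)·d), so diagonal
  runs accumulate √2/√3 per step and a single voxel is always a length-1 run
  (13 of them, one per direction).
* **GLSZM** — zones are maximal 26-connected components of equal level;
  m[g,s] counts zones of level g and size s voxels. Mass conservation holds
  exactly: Σ s·m[g,s] = |ROI|.
* **NGTDM** — per in-ROI voxel, the inverse-distance-weighted mean of its
  in-ROI 26-neighbours; s[g] accumulates |g − mean|. Voxels with no in-ROI
  neighbour contribute nothing and are excluded from the occurrence
  probabilities.

The inverse-distance weighting and the geometric run-length increment are
this package's reading of "distance-aware" merged analysis; the unweighted
voxel-count convention is selectable everywhere (`weighted=False`).
Correctness is enforced by exhaustive brute-force oracles (plain voxel
loops) on random ROIs up to 4x4x4.

## Feature battery (1615 per modality)

10 intensity + 5 shape at native resolution, plus 40 texture features at
each of the 40 grid points (10 + 5 + 40x40 = 1615). Names are deterministic:
`intensity_*`, `shape_*`, `<feature>_<FAMILY>__vx<s>mm_<algo>_Ng<k>`, in
stable lexicographic column order.

**Intensity** (first-order): variance, skewness, kurtosis (Pearson m4/m2²,
non-excess), max, peak, mean, area under the cumulative intensity-volume
histogram (AUC-CSH), total lesion glycolysis (TLG = mean x volume in cm³),
percentage of inactive volume, and generalized effective total uptake (gETU).
Moments are computed from the raw voxel values (the spec-level examples
require exact closed forms); the AUC-CSH uses a 100-threshold histogram
spanning [min, max] of the ROI: the area under "fractional volume above
threshold" vs normalized threshold. Conventions where the method leaves a
choice: the peak is the mean over in-ROI voxels within a 1 cm³ sphere centred
on the hottest voxel; inactive volume is the ROI fraction below 50% of the
maximum (threshold configurable); gETU uses exponent a = 1 by default
(reducing to TLG), configurable.

**Shape**: volume (cm³); size (maximum diameter between voxel centres, mm);
solidity (ROI voxel count over the voxel count of its convex hull, computed
by point-in-hull tests on the bounding-box grid, so it is ≤ 1 by
construction); eccentricity √(1 − λmin/λmax) from the principal axes of the
voxel-centre second moments; compactness V/(√π·A^{3/2}) with the surface
area A from a marching-cubes mesh. The binary mask is smoothed (Gaussian,
σ = 0.8 voxel) before meshing: the raw voxel staircase otherwise inflates
the area of curved surfaces by ~9%, and with smoothing a digital ball of
radius 10 voxels lands within a few percent of the analytic sphere value
1/(6π).

**Texture** (9 GLCM + 13 GLRLM + 13 GLSZM + 5 NGTDM = 40): GLCM energy,
contrast, entropy (log2), homogeneity, correlation, sum-average, variance,
dissimilarity, autocorrelation; the standard 13-feature run-length battery
(SRE, LRE, GLN, RLN, RP, LGRE, HGRE, SRLGE, SRHGE, LRLGE, LRHGE, GLV, RLV)
and its size-zone analogue; NGTDM coarseness, busyness, contrast, complexity,
strength (Amadasun-King forms, ε = 1e-9 guards). The run/zone percentage
denominators are the total weighted voxel-run coverage Σ j·m[g,j] and the
ROI voxel count respectively, keeping both in (0, 1]. Degenerate rules:
single-level ROIs have entropy 0, correlation 0 (zero variance), GLCM
energy/homogeneity 1.

## Statistical primitives

* Spearman rank correlation with midranks; p-values from the t
  approximation, exact permutation enumeration below n = 9 (full
  enumeration beyond 8! permutations buys nothing at three decimal places).
* Benjamini-Hochberg step-up FDR control (statsmodels backend), default
  q = 0.10 in the univariate screen.
* MIC (maximal information coefficient) with the standard constrained grid
  search: B(n) = n^0.6; for each y-equipartition the optimal x-partition for
  all bin counts at once by dynamic programming over clump boundaries,
  coarsened to at most 5·nx superclumps; both axis orientations searched.
  Scores: ~1 for noiseless functional relations, < 0.3 on average for
  independent data at n = 200.
* AUC as the midrank Mann-Whitney statistic (ties count ½); sensitivity/
  specificity/accuracy at a probability threshold of 0.5.
* DeLong's test for paired AUCs via structural components (V10/V01).
* Harrell's concordance index: permissible pairs are those where the shorter
  observed time carries an event (tied times not permissible); score ties
  count ½. Cross-checked against lifelines.
* Kaplan-Meier curves and the log-rank test (lifelines), with unadjusted
  pairwise comparisons in the 3-group mode.

## Imbalance adjustment

A training sample with N⁻ majority and N⁺ minority instances is split into
P = round_half_up(N⁻/N⁺) balanced partitions: the minority is copied into
every partition; the majority is shuffled and dealt without replacement into
parts of size ⌊N⁻/P⌋ or ⌈N⁻/P⌉ (e.g. N⁻ = 168, N⁺ = 32 → five partitions,
two with 33 and three with 34 majority instances). One classifier is trained
per partition; logistic ensembles average coefficients, forests append one
tree per partition. On top of this, the minority of each partition can be
under/oversampled by a weight w ∈ [0.5, 2.0] (grid step 0.1, 16 values):
round(w·N⁺) slots, sampled without replacement for w < 1 and
duplicate-all-then-sample-with-replacement for w > 1, so every minority
instance survives oversampling at least once.

## Radiomic model construction

1. **Reduction to 25 features.** Greedy forward pass balancing predictive
   power and non-redundancy: the first pick maximizes |ρ_s(f, y)|; each next
   pick maximizes Gain(f|S) = w·|ρ_s(f,y)| + (1−w)·(1 − R(f,S)) with
   w = 0.5 and R the mean (optionally max) MIC to the already-selected
   features. The mixing weight and aggregation are configurable; an optional
   prescreen (top-k by |ρ_s|, default 150 in the pipeline config) bounds the
   quadratic MIC pass on very wide batteries.
2. **0.632+ bootstrap AUC.** For a candidate feature set: apparent AUC from
   an imbalance-adjusted fit on the full sample; out-of-bag AUC averaged
   over class-stratified bootstrap samples (stratification guarantees both
   classes in every fit — a deliberate deviation from the naive bootstrap);
   combined as AUC = (1−w)·app + w·oob′ with oob′ = max(oob, 0.5),
   R = (app − oob′)/(app − 0.5) clipped to [0,1], w = 0.632/(1 − 0.368·R).
   The no-information value is 0.5 for AUC.
3. **Forward selection over orders 1-10.** The order-k model extends the best
   order-(k−1) model with the candidate maximizing the 0.632+ AUC (ties break
   by reduced-set rank); bootstrap draws are shared across the candidates of
   one order (common random numbers).
4. **Order choice.** The smallest order whose estimate is within one standard
   error of the best estimate (parsimony); manual override is possible.
5. **Final model.** Coefficients averaged over partition fits within each of
   a fresh set of stratified bootstrap samples, then across samples;
   prediction through the logistic transform. n_boot = 1 is a no-resampling
   mode that, on balanced data (P = 1), reduces exactly to a single logistic
   fit.

Logistic fits use an in-package IRLS solver (standardized internally,
coefficients returned on the raw scale, zero-variance columns pinned to 0)
with a ridge fallback (λ = 1e-2 on the standardized scale) under
quasi-separation; the selection loop performs tens of thousands of tiny fits
and per-call overhead, not numerics, dictated this. Agreement with
scikit-learn's unpenalized solver is asserted in the test suite.

Resampling is keyed to patient ids sorted lexicographically, making every
selection and fit invariant to the row order of the input table.

## Radiomic + clinical forests

Clinical covariates are age (years), H&N site (oropharynx / hypopharynx /
nasopharynx / larynx; one-hot encoded) and ordinal stage variables (T, N,
TNM; kept as integer codes — a single tree threshold then captures a
monotone stage effect, and one-hot stage dummies were observed to act as
random-subspace noise that rewards irrelevant staging candidates).

Forests use the partition ensemble: each of n_boot (default 100)
class-stratified bootstrap samples is partitioned, each partition minority-
reweighted by w, and one CART tree (Gini, mtry = ⌈√p⌉, unlimited depth,
min leaf 1) grown per partition. The forest probability (prob_RF) is the
exact fraction of trees voting for the event class; the tree count is the
sum of partition counts over bootstraps.

Staging-group selection ({T}, {N}, {T,N}, {TNM}, combined with age + site)
and the minority weight are tuned by stratified random sub-sampling: n = 10
splits at a 2:1 sub-train:sub-test ratio with the event proportion preserved
exactly up to rounding. All candidates are scored on the same pre-drawn
splits, and a later candidate displaces the incumbent only when its mean AUC
improves by more than one standard error of the paired per-split difference
(2.5 SE for the 16-point weight grid, a family-wise guard), anchored at the
first-listed candidate and at the identity weight w = 1 respectively.
Measured candidate differences on synthetic cohorts sit at the 0.003-0.008
level against paired SEs of 0.005-0.01, so an unguarded argmax mostly ranks
noise; the guarded rule prefers the simpler candidate / least-distorting
weight unless the data argue otherwise — the same statistical language as
the model-order rule.

Permutation importance is the mean AUC drop when one raw variable's column
is permuted; it is meaningful on data not used for training (on the training
table a forest rewards even pure-noise columns it overfitted on).

Cox proportional-hazards linear models (lifelines) provide the volume-only /
radiomics-only prognostic baselines; the training-set median of the linear
predictor is stored as the two-group stratification threshold for test data.

## Risk stratification

Two-group: prob_RF ≤ 0.5 → low, > 0.5 → high. Three-group: [0, 1/3) low,
[1/3, 2/3) medium, [2/3, 1] high; probability 1 belongs to the high group
(the intervals are left-closed; the top interval closes at 1 so every
probability is assignable). Evaluation reports AUC/sensitivity/specificity/
accuracy at 0.5, the concordance index between prob_RF and time-to-event,
and Kaplan-Meier log-rank p-values for both stratifications. Train/test
tables must not share subjects (hard error); passing the training table
itself is allowed and flagged as resubstitution.

## Synthetic data

The generators define the study conditions for every test:

* **Phantoms**: Gaussian-smoothed white noise inside an ellipsoidal ROI on a
  regular grid; the smoothing length (mm) is the single heterogeneity knob
  (longer correlation → fewer, larger iso-intensity zones — the GLSZM zone
  count decreases monotonically, which is itself a test). The field is
  rescaled to the requested mean/variance; variance 0 gives a constant ROI.
  Defaults are SUV-like (mean 5, variance 2, background 0.5) on 1 mm grids.
  Not emulated: PET point-spread blur and count noise correlations, CT
  artefacts, partial-volume effects at the ROI rim, non-ellipsoidal tumour
  shapes. Passing texture tests therefore demonstrates correctness of the
  operators and the pipeline, not clinical performance on real scans.
* **Cohorts**: named features (standard normal, or realistic clinical
  marginals for age/site/stages), a known generative logistic risk
  βᵀx with the intercept calibrated by root finding so the expected event
  proportion matches the requested rate (defaults 10-20%, the imbalance
  regime of interest; n = 200 training / 300 testing in the acceptance
  suites); event times exponential with log-hazard proportional to the same
  risk (0.03/month baseline, 0.7 per risk unit); event-free follow-up (60
  months) censored by an independent exponential calibrated to the requested
  censoring fraction. The binary event flag is drawn from the logistic
  model directly rather than derived from latent time vs censoring
  competition — a deliberate simplification that keeps the classification
  ground truth exact; the survival mechanism remains risk-ordered, which is
  what the concordance/Kaplan-Meier machinery needs.

## Problem sizes and numerical choices

The acceptance suites run at deliberately scaled problem sizes chosen as the
package's own defaults: phantoms of 16-18³ voxels with ~6 mm ROIs for
battery enumeration; 25 Monte-Carlo seeds for the stochastic checks;
selection with 30 bootstrap samples over orders 1-6 on 30-feature tables
(the pipeline default remains 100 bootstraps and orders 1-10). Key numerical
conventions collected in one place: round-half-up for partition counts, run
lengths and weight targets; IRLS tolerance 1e-10, step cap |β| ≤ 40
(standardized) before the ridge fallback; MIC superclump factor 5; ε = 1e-9
in NGTDM coarseness/strength; GLCM entropy in bits.

## Known limitations

* The distance-aware texture conventions (inverse-distance weights, rounded
  geometric run lengths) are one defensible reading; published
  implementations vary, so absolute texture values are comparable only
  within this package (the unweighted variants are provided).
* The Gain reduction uses a fixed 0.5 mixing weight between predictive power
  and non-redundancy; no claim of optimality.
* MIC uses the heuristic grid search (a lower bound on the exhaustive
  definition); the test suite bounds its gap against an exhaustive oracle at
  tiny n.
* No DICOM RTSTRUCT handling, no deformable registration, no SUV conversion
  from raw PET counts: inputs are assumed already in SUV/HU with
  voxelized masks.
* Forest hyperparameters are fixed conventions (CART/Gini, √p features per
  split); no per-dataset tuning beyond the minority weight.
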