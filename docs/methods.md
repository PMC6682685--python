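# Methods

This note documents the models, conventions and numerical choices behind
`radiorobust`, in the spirit of the methods documentation of mature
scientific packages: what is computed, under which assumptions, and which
design points were genuinely open.

## Synthetic phantom cohort

The generator emulates a pre-registered, skull-stripped multi-modal
glioma study. Each patient is a pure function of `(seed, patient_index)`:

- **Geometry.** The brain is an ellipsoid filling ~84% of each axis of
  the grid (default 96×96×64 voxels at 1 mm). The tumor is a union of
  5–8 randomly offset balls (radius scaled by `tumor_radius`, default
  14 mm) clipped to the eroded brain interior — a lumpy blob whose
  irregular contour makes volume and contour perturbations non-trivial.
  Tumors that would be empty or touch the volume boundary are
  regenerated up to 20 times before failing.
- **Contrast.** Per-modality (tissue, tumor) intensity pairs give each
  sequence a distinct contrast (e.g. tumor hypointense on T1,
  hyperintense on T2/FLAIR/T1-post). An intra-tumor Gaussian random
  field (correlation length 1.5 voxels, amplitude 15% of the tumor
  intensity) provides texture.
- **Noise and bias.** Additive Gaussian noise per modality (default
  σ = 0.02, i.e. 2–3% of tissue intensity). Rician noise is deliberately
  out of scope. An optional multiplicative bias field (smooth linear
  ramp, amplitude 0.3) can be switched on to exercise bias removal.
- **Class signal.** `topology-holes` plants 1 + magnitude ring-shaped
  hypointense shells (annular cylinders running the full tumor depth, so
  every large axial cross-section carries an annulus) in label-1 tumors;
  these create long finite H1 bars. `texture-contrast` lengthens the
  intra-tumor autocorrelation of label-1 tumors by 1.5·magnitude voxels.
  `none` yields an exchangeable null cohort.
- **Covariates.** Age ~ Normal(50, 12) truncated to [18, 90], KPS
  uniform on {60, …, 100}, sex uniform — independent of the label by
  default, so the clinical model is null-calibrated.
- The default cohort shape (13 codeleted vs 130 non-codeleted) mirrors
  the severe class imbalance of real codeletion cohorts; tests and
  examples use smaller cohorts (2–4 positive, 4–8 negative patients,
  48–96-voxel grids, tumor radius 7–9 mm) chosen so the full pipeline
  runs at desk scale.

What the phantoms do **not** emulate: real anatomy, scanner-dependent
noise spectra, inter-site intensity variation, registration error, or
segmentation disagreement between raters. Passing tests demonstrate the
machinery is correct and calibrated, not that any feature family will
perform comparably on clinical data.

## Preprocessing

- **Resampling** to isotropic 1 mm: trilinear for intensities,
  nearest-neighbor for masks; output shape is `round(shape·dx/target)`
  per axis (scipy zoom convention).
- **Bias removal** fits a polynomial of total degree ≤ 3 to the
  log-intensity over the *non-tumor* brain (tumor excluded so its
  contrast does not leak into the field estimate; 20 000 voxels
  subsampled deterministically) and divides out the exponentiated fit,
  normalized to unit geometric mean. A multiplicative field is
  identifiable only up to a global scalar — the constant term of the fit
  absorbs both the field mean and the true intensity scale — so recovery
  of a corrupted phantom is exact modulo one global factor, which is how
  the recovery contract is tested. Non-positive intensities are shifted
  before the logarithm.
- **IQR normalization** per modality: `(x − median) / IQR` over the
  non-tumor brain reference region, quartiles by linear interpolation
  (NumPy default). The reference median maps exactly to 0 and its IQR to
  1; the operation is idempotent and affine-invariant.
- **Patch extraction**: the tumor bounding box of an axial slice is
  padded symmetrically to a square (preserving aspect ratio), then
  rescaled to 142×142 — bilinear for channels (edge padding), bilinear +
  0.5 threshold for the mask.
- **Slice selection** implements the 20:3 oversampling of the rare
  class: label-1 scans contribute their 20 largest tumor cross-sections
  (all, if fewer exist), in descending area order; label-0 scans the
  slices at the 50th/75th/100th percentile of per-slice tumor area under
  the nearest-rank convention, ties broken toward the lower slice index.
  "Largest" is measured by tumor area, not bounding-box size.

## Texture features

89 features per modality in six families, following the IBSI-standard
definitions; 4 modalities give 356. Composition: 19 first-order, 9 2-D
shape, 24 GLCM, 16 GLRLM, 16 GLSZM, 5 NGTDM.

- **Discretization**: fixed bin *count* (32 levels) over the masked
  intensity range. A fixed bin width would interact badly with IQR
  normalization (the effective level count would depend on the
  reference-region noise); fixed count makes all gray-level families
  invariant to affine intensity rescaling, which is tested.
- **GLCM**: symmetric, distance 1, the four 2-D angles pooled before
  normalization. Out-of-mask pixels occupy level 0 and their
  co-occurrence row/column is discarded, restricting pairs to the mask.
- **GLRLM**: runs in the four directions; feature values averaged over
  directions. Out-of-mask pixels break runs.
- **GLSZM**: zones are 8-connected constant-level regions.
- **NGTDM**: 8-neighborhood averages with out-of-mask neighbors
  excluded; Coarseness capped at 10⁶ when its denominator vanishes.
- **Shape** is computed once from the shared mask (area, perimeter,
  their ratio, circularity, major/minor axis, elongation, eccentricity,
  maximum Feret diameter) and emitted per modality to preserve the
  89-per-modality layout.
- **NaN policy**: degenerate values (zero-variance denominators,
  single-pixel masks) are set to 0 with a logged warning, keeping the
  feature table dense for ICC computation and modeling.

## Topological features

Sublevel-set cubical persistence of each masked channel, with pixels as
top-dimensional cells:

- Out-of-mask pixels are +∞ and never enter the filtration. Sublevel
  components are 8-connected (two pixels sharing a corner are joined
  through the shared vertex); consequently the complementary superlevel
  sets are 4-connected. These conventions change H1 counts and are
  fixed.
- **H0** comes from an elder-rule union-find sweep over pixels sorted by
  value (numba kernels). **H1** comes from duality: finite H1 bars
  (s, M) of the sublevel filtration correspond one-to-one to H0 merges
  of the superlevel filtration of the same image — the enclosed
  high-intensity region is born at its maximum M and merges with the
  exterior through the ring's saddle s. The sweep therefore runs on the
  negated image with 4-connectivity, with a −∞ border playing the
  unenclosed exterior. Zero-length pairs are discarded (plateau
  bookkeeping, not topology).
- **Essential classes** (components that never die; holes whose interior
  is masked out) are finite-ized at the masked maximum intensity, the
  common convention in image TDA, so every statistic is finite.
- Each barcode is summarized by 4 polynomial descriptors
  (P1 = Σ bᵢLᵢ, P2 = Σ (d*−dᵢ)Lᵢ, P3 = Σ bᵢ²Lᵢ⁴, P4 = Σ (d*−dᵢ)²Lᵢ⁴
  with Lᵢ = dᵢ−bᵢ, d* = max dᵢ) and 11 statistics (bar count; mean/SD of
  births; mean/SD/median/skewness of deaths; mean/SD/max/sum of
  lengths). The 11-statistic set is a reconstruction covering the birth,
  death, length and death-distribution categories with 15 descriptors
  per (modality, dimension), hence 4·2·15 = 120 features. Skewness is
  the bias-uncorrected moment estimator, defined as 0 at zero variance.
  Empty barcodes map to all-zero descriptors.
- Superlevel filtration is available behind a flag (intervals are then
  reported on the negated intensity scale); barcodes are computed on the
  masked patch, treating the tumor as the region of interest.
- Correctness is checked against implementations that share no code with
  the sweep: scipy connected-component labeling for β0 at every
  threshold, and the Euler characteristic of the sublevel cell complex
  (V − E + F) for β1, plus analytic disk/annulus/double-annulus
  phantoms.

## Perturbations

Five classes, each producing "relatively small" changes; identity
parameters return the input bit-exactly. Defaults (4 replicates per
class for a balanced ICC design): R ∈ {+3, −6, +9, −12}°, T ∈
{(.25,.25), (.5,.5), (.75,.75), (.25,.75)} px, N scale ∈ {0.5, 1, 1.5,
2} with per-replicate seeds, V fraction ∈ {−.15, −.05, +.05, +.15}, C
with 4 seeds. Perturbation magnitudes are configurable and recorded in
every output; they are applied singly, not chained.

- **R** rotates channels and mask about the mask center of mass
  (bilinear; mask re-thresholded at 0.5; out-of-frame pixels filled with
  the background median).
- **T** is a subpixel bilinear shift; integer shifts are lattice-exact.
- **N** adds Gaussian noise with σ = scale × the channel's own noise
  level, estimated as median |finest-level diagonal wavelet detail| /
  0.6745 (Haar).
- **V** thresholds the signed Euclidean distance transform at the level
  whose area is closest to (1+f)·area; channels are untouched.
- **C** segments the mean channel into ≈64-pixel SLIC superpixels
  (compactness 0.1) and includes each superpixel with probability equal
  to its overlap fraction with the mask; a mask that is an exact union
  of superpixels is a fixed point, and the expected area equals the
  input area (tested by Monte Carlo over 200 seeds). Empty results are
  retried with derived seeds up to 10 times.

## Robustness filter

For each feature and perturbation class, the slices × replicates matrix
(original included as replicate 0 — the test-retest framing) feeds the
one-way random-effects single-rater ICC(1,1). The variant choice was
open: perturbation replicates are not distinguishable "raters", so the
one-way model is the defensible default; ICC(2,1) is available behind a
flag for sensitivity analysis. A constant matrix (0/0 in the formula) is
defined as ICC 1 — a feature that never moves is perfectly stable.
Replicates are pooled across parameter values within a class. A feature
survives iff ICC ≥ cutoff (default 0.75) for **all** classes; NaN cells
count as failures. The threshold sweep reports per-class survival
fractions over cutoffs in [0, 1]; a cutoff ≤ 0 is vacuous (negative ICCs
survive), so survival starts at 100% of non-NaN features and is
monotone non-increasing.

## Models

Samples are slices; all grouping is by patient. Splits are stratified by
patient label, 80/20, repeated (default 10×). RFE uses grouped
cross-validated AUROC to choose the feature count (logistic estimator,
10% elimination steps); PCA standardizes on train and keeps the smallest
component count reaching 95% cumulative explained variance. Classifiers
are tuned by patient-grouped stratified 5-fold CV maximizing AUROC over
the grids: RF trees {200, 650, 1100, 1550, 2000} × depth {10, 40, 70,
100} × min-split {2, 5, 10} × min-leaf {1, 2, 4}; LR penalty L1/L2 ×
strength 10⁻³…10⁵ (9 log steps). Desk-scale runs (tests, pipeline
default) use reduced grids over the same ranges (RF 200 trees × depth
{10, 100}; LR L1/L2 × C {0.01, 1, 100}); the grids are arguments, not
constants. Fold counts are capped by the minority class's patient-group
count; if a class has a single patient group, grouped CV is impossible
and an ungrouped stratified split is used with a logged warning; with a
single sample in a class, the first grid configuration is fitted without
search. Metrics (AUROC; sensitivity/specificity/accuracy at score 0.5)
are slice-level by default, matching the oversampled design; a
per-patient mean-score aggregation flag exists. All fitting sees
training patients only, and every patient id touched during fit is
recorded for leakage auditing.

## k-top-scoring-pairs

Pairs are oriented so x_i < x_j votes for class 1; the primary score is
Δ = |P(x_i < x_j | 1) − P(x_i < x_j | 0)| with ties x_i = x_j counting as
not-less-than. Ties in Δ break by the secondary score |mean within-
profile rank difference between classes|, then lexicographically; both
scores are exact multiples of small rationals and are quantized to those
grids so ties are genuine and the tie-break deterministic. Selection is
greedy under disjointness (no feature reused). Prediction is a majority
vote; an even-k split defers to the top pair. k is chosen in [3, 15] by
training AUC of the vote margins (smallest k on ties). The experiment
repeats a grouped label-stratified 70:30 patient split (default 5000×;
tests use 100×), re-running the Wilcoxon/BH prefilter (two-sided
rank-sum, Benjamini–Hochberg, adjusted p < 0.1) inside each repetition
on training data only to avoid selection leakage; when the prefilter
retains fewer than 2·k_min features, the lowest-p features are kept so a
model can still be formed. Test AUCs are summarized by the 95% HPD
interval — the shortest window of ⌈0.95·n⌉ consecutive sorted values.
The decision rule depends only on within-sample orderings, so one
strictly monotone normalization applied to all values (consistently to
train and test) changes neither pair scores nor votes.

## Pipeline and reproducibility

`run_all` executes cohort → preprocess → features → perturb → ICC →
models (pre- and post-filter) → kTSP from one YAML-serializable config;
a single master seed is propagated (derived seeds stay below 2³¹), and
rerunning a config reproduces every CSV byte-for-byte. Each run writes
its config, per-stage timings, provenance columns (patient, slice,
perturbation id) on every feature row, and a SHA-256 manifest of the
artifacts.

## Known limitations

- H2 and 3-D persistence are out of scope (patches are 2-D), as are
  persistence images/landscapes and Vietoris–Rips complexes.
- 3-D texture and filtered-image (wavelet/LoG) features are not
  computed.
- The exact statistical summaries of barcodes and the family composition
  summing to 89 per modality are principled reconstructions; alternative
  compositions of the same families would shift individual feature
  values but not the machinery.
- CNN-based features are represented only by a pluggable
  feature-backend hook (any callable mapping a patch to named features
  can be passed to the feature-table builder); no pre-trained network is
  bundled.
- Phantom realism limits: see the synthetic-cohort section.
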