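# Methods

This note documents the models, conventions and numerical choices behind
`wavradiomics`, in the order the pipeline runs.

## Geometry and preprocessing

Volumes are 3D scalar grids in Hounsfield units (HU) with physical voxel
spacing; the public API fixes axis order `(x, y, z)`, 0-based indices, and
world coordinates `origin + index * spacing` (mm).  Contrast phases are
assumed registered upstream; the loader only verifies equal grids and
errors otherwise.

Before extraction every phase/mask pair is resampled to a uniform target
spacing (default 1 mm isotropic).  The image uses cubic-spline
interpolation, sampled at world positions `j * target`, with overshoot
clipped back to the input intensity range (HU sanity).  The mask uses
nearest-neighbour interpolation to stay binary; both grids are resampled
together.  The ROI is then cropped to the mask bounding box plus a
`crop_pad` margin (default 2 voxels) so wavelet filtering sees some
context beyond the lesion boundary.

## Undecimated 3D wavelet decomposition

One level splits a volume into 8 subbands by applying the analysis
low-pass (L) or high-pass (H) filter along each axis; the label `XYZ`
assigns letter `X` to axis 0, `Y` to axis 1, `Z` to axis 2 (the axis
convention must be fixed somewhere; this is ours and it is recorded in
feature names).  The transform is undecimated, so subbands keep the input
shape and stay voxel-aligned with the mask — masked per-subband feature
extraction requires this.

Filtering is plain discrete convolution `y[n] = Σ_k h[k] x[n−k]` with
periodic extension by default (symmetric available; the mode is part of
the extraction config).  Periodic wrap-around is well defined for any
grid size, so small ROIs may be decomposed with long filters (db7,
bior6.8); symmetric mode requires the grid to cover the filter support
and errors otherwise.  Levels above 1 re-decompose the previous LLL band
with à-trous (zero-upsampled) filters.  Supported families include haar,
db2, db4, db7, sym4, coif1, bior6.8 and rbio6.8.

## Feature rosters

Per contrast phase:

| domain            | first-order | shape | texture | total |
|-------------------|------------:|------:|--------:|------:|
| original          | 18          | 14    | 68      | 100   |
| each wavelet subband | 18       | —     | 68      | 86    |

Shape features depend only on the mask, hence are not recomputed per
subband.  Three phases at one wavelet level give 300 original + 2064
wavelet = 2364 features.

Intensities are discretised with a fixed bin width (default 25 HU),
min-anchored inside the mask: `level = floor((v − min)/width) + 1`.  The
same width applies in every domain (wavelet subbands are not
re-parameterised), and min-anchoring makes all texture features invariant
to constant HU offsets.

Texture conventions (the usual 3D radiomics choices; the field's common
definitions are followed so the rosters are auditable):

- GLCM and GLRLM use the 13 unique 3D offsets (symmetric closure 26);
  features are computed per direction and averaged.  GLCM matrices are
  symmetrised.  The 22-name GLCM roster omits SumAverage (a duplicate of
  2·JointAverage for symmetric matrices) and MCC.
- GLSZM zones and GLDM dependences use 26-connectivity; GLDM dependence
  tolerance α = 0, and the dependence size includes the center voxel.
- Runs and zones never cross the mask boundary.
- Degenerate single-gray-level ROIs yield defined values (contrast 0,
  normalised non-uniformities 1, correlation 1 by the constant-region
  convention).

Shape features are mesh-based: marching cubes on the zero-padded binary
mask gives surface area and (divergence-theorem) mesh volume; axis
lengths are `4√λ` from a PCA of physical voxel coordinates; maximum
diameters use convex-hull-reduced pairwise distances.  A single-voxel
mask gets elongation = flatness = 1 and zero diameters.

## Sparse logistic regression (selector and classifier)

The model is the MAP estimate under a logistic likelihood and a Laplacian
coefficient prior, equivalently

```
f(θ) = Σᵢ −[yᵢ log pᵢ + (1−yᵢ) log(1−pᵢ)] + λ‖θ‖₁ ,  pᵢ = σ(b + θᵀxᵢ).
```

The prior's `(λ/2)^N` normalisation constant is optimisation-irrelevant
and dropped.  An unpenalised intercept `b` is included by default:
without it predictions are anchored at p = 0.5 for mean-valued inputs,
which is wrong whenever classes are imbalanced (an off-switch exists).
Features are standardized per column (training rows only, population SD);
zero-variance columns are flagged and mapped to 0.

Solver: accelerated proximal gradient with backtracking line search,
initial step `4/‖[X,1]‖²_op` (inverse Lipschitz bound of the logistic
loss), θ₀ = 0, and a function-value restart: a momentum step that would
increase the objective is rejected and the momentum reset, so accepted
objectives are non-increasing.  The L1 part is handled by exact
soft-thresholding, so reported zeros are exact and the support size K is
well defined.  Convergence: relative objective change < 1e-9 (default)
or 20 000 iterations, with an honest `converged` flag.  Probabilities are
clipped at 1e-15 inside the log-loss.  Useful identities: with an
intercept, `λ_max = ‖Xᵀ(y − ȳ)‖_∞` is the smallest λ with θ = 0; KKT
residuals are available for verification.

Ridge (`λ‖θ‖₂²`) and elastic net (`λ(α‖θ‖₁ + (1−α)‖θ‖₂²)`, default
α = 0.5) reuse the same scheme with the quadratic part moved into the
smooth gradient.  Because non-sparse penalties produce no exact zeros,
"selection" for them uses a relative magnitude cutoff
`|θⱼ| ≥ 0.01·max|θ|` — an explicitly heuristic rule.  A linear-response
LASSO (`‖y − Xθ‖² + λ‖θ‖₁`) shares the proximal machinery as the
selection baseline.

## Regularisation search

`lambda_search.optimize` maximises repeated, stratified, leakage-free CV
AUC over log₁₀ λ in [10⁻⁶, 10⁶]: per fold, standardization and fitting
use training rows only.  The surrogate is a Gaussian process
(Matern-5/2 kernel with estimated observation noise, normalised targets)
with expected-improvement acquisition maximised over 512 random
candidates per step; the initial design is one uniform draw per
equal-width stratum of the log-range.  Defaults: 5 initial points,
25 acquisitions.  Repeat r of the CV shuffles folds with seed `seed + r`,
so the whole search is deterministic given its seed.

## Evaluation machinery

- AUC is the Mann–Whitney statistic (ties count ½), computed from ranks.
- F1 uses a 0.5 probability threshold by default (the threshold is a free
  parameter of the report).
- Repeated stratified k-fold CV refits the entire pipeline inside every
  training fold.  One replicate = one held-out fold.  The CI is a normal
  approximation over replicates with the Nadeau–Bengio dependence
  correction `se = sd · √(1/R + 1/(k−1))`: CV replicates share the
  dataset, and the naive `sd/√R` interval undercovers badly in null
  simulations (~50–70% instead of 95%); with the correction coverage is
  close to nominal.  This correction is the one deliberate refinement of
  the plain replicate-CI recipe.
- Test-set uncertainty uses B = 200 bootstrap resamples of the test rows
  (resamples missing a class are redrawn) with percentile (2.5, 97.5)
  CIs.
- AUC comparisons on a shared test set use DeLong's structural-components
  test (placement values V₁₀/V₀₁; z = ΔAUC/sd; identical score vectors
  give p = 1 by convention).  CV replicate distributions are compared
  with Welch's t-test.
- Cohort splitting is patient-level (no patient on both sides), greedy
  within (class, lesion-size-tercile) strata, train fraction capped at
  the requested ratio.  Lesions remain the samples; splitting at patient
  level avoids leakage from multi-lesion patients.

## Synthetic data

The phantom generator emulates the acquisition setting: three
co-registered phases on an anisotropic grid (default 0.85 × 0.85 ×
1.25 mm), a smooth background around 55 HU, and an ellipsoidal lesion
(≥ 5 mm diameter, per-case jittered semi-axes).  The class signal is
placed primarily in *texture*: positive lesions carry a spatially
correlated Gaussian field (correlation length 2.5 mm) plus an
arterial-enhancement/washout offset pattern, negative lesions carry
white-noise texture of equal amplitude and a milder, flat enhancement.
This is the mechanism wavelet/texture features are supposed to measure;
mean-intensity differences exist (as they do clinically) but the
co-occurrence structure is the designed discriminator.  All HU stay
within [−200, 400].

What the phantoms do **not** model: CT physics (beam hardening, noise
spectra), anatomy, registration error, annotation variability.  Passing
tests on phantoms therefore demonstrates the pipeline's correctness and
sensitivity to texture structure, not clinical performance.

The feature-table generator produces the M ≪ N regime directly: rows from
an equicorrelated Gaussian (ρ = 0.2 by default, mimicking radiomics
features' heavy mutual correlation), a sparse θ* with `k_true` unit
nonzeros at random positions and signs, labels from the logistic link.
It returns the true support (and optionally θ*) for recovery tests.

## Problem sizes used in the shipped experiments

The test suite and `scripts/acceptance.py` run at desk scale, chosen so a
single CPU completes them comfortably: phantom grids of 24 × 24 × 16
voxels with ~4–5 mm semi-axes, cohorts of 40–60 cases, recovery at
M = 300 × N = 500 with 10 true features, BO budgets of ~12 evaluations
with 1×3-fold CV inside the search, and 5–10×5-fold CV for reporting.
These sizes are the package's reference configuration; all are ordinary
parameters and scale up directly.

## Known limitations

- The exact membership of the 18/14/68 rosters follows the field's
  de-facto standard definitions; other toolkits' binning or aggregation
  options (merged-matrix GLCM, 2D variants, NGTDM) are out of scope.
- The FCT drop rule (drop the later column of a correlated pair) and the
  FVT-before-standardization ordering are deterministic conventions; the
  thresholds τ_v = 0.5, τ_c = 0.99 only make sense on raw features.
- The BO acquisition optimises over random candidates, which is adequate
  in one dimension but not a multi-dimensional strategy.
- GLCM/GLRLM direction averaging is the only aggregation implemented
  (per-direction features averaged, not matrices merged).
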