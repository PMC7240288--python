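# Methods

This note documents the models, numerical choices and known limits of the
`boldvar` pipeline: SD_BOLD mapping, battery factor reduction, partial
least squares correlation (PLSC), and the synthetic cohort generator that
makes the chain testable end to end.

## SD_BOLD: the variability map

For a 4-D resting-state series the map is built in a fixed, logged order:

1. **Band-pass filter**, 0.01–0.1 Hz, 4th-order Butterworth applied
   forward–backward (zero phase, `scipy.signal.sosfiltfilt`). A zero-phase
   IIR realization keeps SD estimates free of phase artifacts; the
   stop-band attenuation of the squared 4th-order response is far below
   the 10% amplitude contract at 0.2 Hz and 0.005 Hz. Filter performance
   is assessed on the steady-state (central two-thirds) portion of a test
   sinusoid because forward–backward filtering leaves edge transients.
2. **Polynomial detrend**, order 2 (linear + quadratic), per voxel, by
   least squares on a basis rescaled to [-1, 1] (well conditioned at any
   series length). The residual is orthogonal to the basis, so the
   operation is idempotent.
3. **Noise-component removal.** ICA estimation itself is pluggable (a
   whitened-PCA + FastICA adapter ships for tests); the pipeline only
   *classifies* components with three quantitative criteria and regresses
   out the flagged ones (OLS projection with intercept):
   - *spike*: any time-course point ≥ 6 SD from the mean;
   - *high-frequency*: ≥ 75% of DC-excluded periodogram power above
     0.13 Hz;
   - *spotty*: suprathreshold support (|z| ≥ 2) covering ≥ 25% of the
     mask with no 26-connected cluster of ≥ 10 voxels. Spatial maps are
     treated as z-statistic images (the MELODIC convention) and
     thresholded directly — a self-standardized map could never put 25%
     of its mass beyond 2 SD (Chebyshev), so re-scoring would void the
     criterion.
   Classification is conservative: a component with no flag is kept.
   Criteria that need human visual judgment (motion ringing,
   susceptibility, white-matter/ventricle topography, drift) are out of
   scope.
4. **Grand-mean scaling** to 100: one scalar per subject over all in-mask
   voxels and timepoints, which preserves the temporal SD structure and
   makes SD_BOLD invariant to positive rescaling of the raw data. The
   band-pass and detrend steps strip each voxel's mean, so the pipeline
   restores the raw mean volume before scaling; the restored constant
   does not affect the SD.
5. **Gray-matter mask**: probability strictly > 0.43.
6. **Voxelwise SD** of the mean-deviation series, sample convention
   (denominator T−1, unbiased in variance).

Motion QC summarizes a per-timepoint trace and fails a subject if any
absolute displacement exceeds 2.0 mm or any relative displacement exceeds
2.5 mm.

## Battery factor reduction

The 14-test battery is oriented (timed tests reflected via max+min − x so
higher always means better), tested for skew per column (D'Agostino), and
transformed when significantly skewed (p < 0.05): square root first,
log10 as fallback, negative skew handled by reflect-then-transform with
the orientation restored afterwards (a reflected transform is
order-reversing; without re-negation it would silently flip the column's
meaning). A transform is kept only if it improves the skew-test p-value
over the raw column — a transform that fails to help is worse than none.
Every choice is recorded and replayable bit-for-bit.

PCA runs on the correlation matrix (so factor scores are invariant to
affine rescaling of any input column). The number of components is chosen
at the scree elbow, operationalized as the interior eigenvalue lying
furthest below the chord joining the first and last eigenvalues (ties
toward fewer components). The raw max-second-difference rule was
considered and rejected: batteries with cross-loadings have a dominant
first eigenvalue, which puts the largest raw curvature at k=1 even when
four clearly separated components follow; the chord rule finds the
flattening point a human reads off a scree plot and agrees with it on all
hand-worked cases.

An oblimin (direct quartimin, gradient-projection) rotation is computed
first; if no off-diagonal factor correlation exceeds 0.32 (< 10% shared
variance) the solution is declared near-orthogonal and a varimax rotation
(Kaiser row-normalized, switchable) is used instead. Factor scores use
the regression (Thurstone) method, `Z R⁻¹ (L Φ)`, with a pseudo-inverse
when small samples make R rank-deficient. Loadings are signed so each
factor's largest-magnitude loading is positive, making solutions stable
across runs.

## PLS correlation

Two model families over a subjects × elements block X with a two-level
group label:

- **Mean-centered (group-comparison) PLS** decomposes M_dev, the
  within-group column means expressed as deviations from the grand mean.
  With one element and equal groups, S₁ reduces to √2 × |group-mean
  deviation|.
- **Behavioral PLS** decomposes R, the within-group Pearson correlations
  of each element with each behavioral variable, stacked group-major
  (rows = group × behavior, columns = elements). Left singular vectors
  are therefore behavior/design saliences, right singular vectors element
  (voxel) saliences.

The SVD uses a deterministic sign convention (largest-magnitude
design/behavior salience positive per LV) and reports
covariance fraction Sᵢ²/ΣSⱼ² per latent variable.

**Permutation test**: subject rows of X are shuffled relative to the
group labels (and behavior rows), the model rebuilt, and same-index
singular values compared; p = (1 + #{S_perm ≥ S_obs}) / (1 + n_perm)
(add-one, so p is never zero; under exchangeability the test is exactly
calibrated up to the 1/(n_perm+1) discretization). The same-index
comparison without Procrustes is the simple, conservative variant.

**Stratified bootstrap**: subjects resampled with replacement within
group; each resampled solution is aligned to the point estimate by the
orthogonal Procrustes rotation of V onto the original V (the rotation
applied to U as well) — without alignment, axis reflections inflate the
SEs. Bootstrap SE is the SD over resamples; bootstrap ratios (original
salience / SE) behave like z-scores; 95% percentile CIs are formed on the
design/behavior saliences. SEs below 1e-12 yield an ±inf bootstrap-ratio
sentinel plus a flag, never a silent division. Zero-variance element
columns get correlation 0 (keeping voxel indexing stable); degenerate
*resamples* with a zero-variance behavior contribute zero correlations
rather than an error.

Brain scores are X·U with X exactly as the model analyzed it: raw for the
mean-centered model, within-group z-scored for the behavioral model. The
per-LV sign is a convention, so only magnitudes of cross-model
brain-score correlations are meaningful.

Cluster reporting binarizes a bootstrap-ratio map at |BSR| ≥ threshold
(defaults: 4 whole-brain, 2.5 for the MTL analysis), labels 26-connected
components, drops clusters below 5 voxels, and reports size and peak per
cluster (voxel indices, plus affine-mapped world coordinates when an
affine is supplied).

The demographic t-test is pooled-variance by default (df = n₁+n₂−2,
matching published df = 38 at n = 20+20), Welch by flag, and accepts
printed (mean, SD, n) summaries so published table rows can be checked
directly.

## Synthetic cohort generator

The generator emulates the *statistical* shape of a two-group (at-risk /
control, n = 20 each) older-adult resting-state study; it does not
emulate scanner physics, physiological noise, motion corruption or
anatomy.

- **Geometry**: a 12×12×12 grid (configurable) with a gray-matter
  probability volume (interior 0.9, rim 0.1) and integer region labels —
  an MTL block (~6% of the interior) and a posterior occipital slab
  (~10%), so salient loci occupy a realistic minority of gray matter.
- **Voxel salience**: a smoothed Gaussian field gives in-region weights
  with mean 1 and relative variation ~0.3, near-zero residue elsewhere;
  stored unit-norm as ground truth.
- **Series**: per-voxel zero-mean white Gaussian fluctuation (optional
  AR(1) for robustness tests) on a constant signal level of 100, with SD
  = baseline × (1 + effect × score × salience), clipped below at 10% of
  baseline. White noise keeps the analytic SD targets exact, and SD_BOLD
  is agnostic to autocorrelation by construction. The planted structure
  lives entirely in the variance because every analyzed statistic is a
  function of SD_BOLD; group differences are planted only in
  brain-behavior and volume *coupling*, not in mean SD_BOLD, so the
  group-comparison PLS is null by design.
- **Effect size semantics**: `effect_size` is the fractional SD
  modulation at the most salient voxel per unit latent score, and equally
  the correlation between the score and the most strongly loaded
  behavioral variable (internally the stored unit-norm salience vectors
  are rescaled to unit maximum before use). This makes the parameter
  interpretable and independent of how many voxels carry signal.
- **Behavior panel**: age, MoCA, global FA, global MD and four cognitive
  factor channels, each correlating with the latent score by effect ×
  pattern weight (closed-form noise: σ² = w²(1−r²)/r²), mapped onto
  realistic units with group-specific demographics (MoCA 23.4 ± 1.9 vs
  27.9 ± 1.7; age 71.5 ± 6.1 vs 70.3 ± 4.5). The cognitive-control/speed
  channel flips its coupling sign in the at-risk group, emulating the
  reversed relation; group-specific affine maps leave within-group
  correlations untouched.
- **Battery**: linear common-factor model over the reference 14×4
  varimax loading pattern, i.i.d. standard-normal factors, per-test
  unique SD √(1−communality) so tests have unit variance before affine
  unit scaling; timed tests are negated (lower = better) to exercise
  orientation. A component model and this factor model differ negligibly
  at these noise levels, and the factor model gives controllable ground
  truth. The full loading matrix (not only the strong loadings) is the
  default because it reproduces the published per-factor variance
  proportions (3.30/2.45/2.12/1.84 out of 14 vs the published
  3.36/2.52/2.10/1.82).
- **MTL volumes**: seven subregion columns (CA1, CA2/3-DG, subiculum,
  alERC, pmERC, PRC, PHC) at plausible mm³ means with 10% CV; CA1,
  CA2/3-DG, alERC and PHC are negatively coupled (target correlation =
  `volume_coupling` ∈ [−1, 0], default −0.5) to the subject's expected
  mean MTL SD_BOLD, by default in the at-risk group only.
- **Determinism**: all randomness derives from the single cohort seed
  via spawned seed sequences; identical specs give byte-identical CSV
  output.

## What the tests do and do not show

Passing recovery tests show the chain correctly extracts a planted
low-rank variance-coupling structure from data matching its assumptions
(white noise, shared grid, no motion corruption, exactly two groups).
They do not show robustness to realistic fMRI artifacts, registration
error, or autocorrelated noise (the AR(1) switch exists for targeted
robustness checks but is off by default).

A quantitative limit worth knowing: at T = 180 the sampling error of a
sample SD is 1/√(2·179) ≈ 5.3%, so per-voxel SD–score correlations
saturate for strongly modulated voxels and the *within-region weight
profile* of the planted salience is essentially unrecoverable — the
cosine between estimated and planted salience is capped near
1/√(1+c²) ≈ 0.96 for in-region weight variation c = 0.3, before
correlation sampling noise (SE ≈ 1/√17 per entry at n = 20 per group) is
even considered. At effect size 0.5 with 500 voxels the measured median
|cosine| is ≈ 0.86 with permutation p < 0.05 essentially always; larger
effects, more subjects or longer series move the cosine toward its
ceiling.

## Problem sizes used by the test suite and acceptance script

Calibration and recovery suites run at deliberately chosen sizes: null
calibration uses 200 simulated null cohorts × 200 permutations (~200
gray-matter voxels, T = 180); latent recovery uses 50 replicates at 512
masked voxels; the acceptance script uses 120 null cohorts and 40
recovery replicates with the same per-dataset geometry. The battery
recovery suite uses 50 seeds at n = 200. These sizes give rate estimates
with standard errors of 1.5–3 percentage points.

## Known limitations

- Exactly two groups; no split-half or cross-validated PLS variants; no
  canonical correlation analysis.
- ICA estimation quality is outside the package's responsibility; only
  classification/removal of supplied components is covered.
- The visual component-classification criteria have no algorithmic
  surrogate here.
- Published cluster peak coordinates cannot be meaningfully reproduced
  from synthetic grids; cluster tables report voxel indices (plus affine
  world coordinates when available) and are validated against a
  flood-fill oracle instead.
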