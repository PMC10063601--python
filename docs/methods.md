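# Methods

## The INT estimator

The intrinsic neural timescale of a voxel is defined operationally: the
biased ("1/N") sample autocorrelation function with a single global mean
removal is evaluated on a lag grid of TR multiples up to a 20 s window,
the coefficients are summed from lag 1 while strictly positive, the walk
stops at the first coefficient ≤ 0 (a coefficient exactly 0 terminates the
run), and the sum is multiplied by the TR.  Three choices deserve note:

- **Lag grid.** Lags advance in TR steps, giving
  `floor(20 / 0.475) = 42` lags at the default acquisition, not 1-second
  bins.  Since the final index is scaled by the TR, the sampling grid is
  the only lag spacing under which the index has consistent units; the
  window length (`max_lag_seconds`) is configurable.
- **Lag 0.** Excluded from the sum by default: its coefficient is
  identically 1, so including it adds a constant TR offset and no
  dynamics.  An `include_lag_zero` flag exists for sensitivity analysis;
  it shifts every in-mask voxel by exactly one TR and leaves every group
  contrast unchanged.
- **Truncation.** If no non-positive coefficient occurs inside the window
  the positive sum is window-capped; such voxels are counted in the QC log
  (`n_window_capped`) because their INT is a lower bound.

The biased ACF estimator guarantees coefficients in [−1, 1] and makes the
index invariant to affine rescaling of the signal.  Every finite output
lies in `[0, TR × max_lag_samples]`.

**Finite-sample bias.** The sample ACF of a stationary process has
negative bias of order 1/T, so sampling noise truncates the positive run
earlier than the population ACF would: single-series INT estimates sit
below the closed-form value (for AR(1) with φ = 0.9 and T = 947, the mean
estimate is ≈ 4.0 s against a population value of 4.22 s, and a single
series can land far lower).  Group comparisons are unaffected because the
bias is shared across groups; recovery tests therefore compare the
estimator against a Monte-Carlo oracle (the same estimator on independent
realizations), not against the closed form.

Degenerate voxels — constant series or series containing non-finite
samples — are recorded as NaN and counted (`n_degenerate`), never raised,
when mapping whole volumes; the scalar API raises an explicit
degenerate-input error instead.

## Sphere ROIs

The packaged table holds the 13 published peak MNI coordinates (8 tagged
`W`, 5 tagged `U` after their source studies), realized as 6 mm radius
spheres.  Discretization uses the voxel-center rule with an inclusive
boundary: a voxel belongs to the sphere iff the Euclidean distance from
its world-space center to the sphere center is ≤ radius.  On a 3 mm
isotropic grid a 6 mm sphere centered on a voxel center covers exactly 33
voxels.  The ROI value is the mean of voxelwise INT inside the sphere
(estimate-then-average), matching a per-voxel definition of the index;
averaging the time series first and then estimating is deliberately not
the default.  Coordinates are interpreted in the image's world space; no
registration is performed or checked.

## Motion QC

Framewise displacement is the Power-style sum of absolute backward
differences of the three translations (mm) plus 50 mm times the sum of
absolute backward differences of the three rotations (radians).  The
exclusion rule reads "head motion > 10 mm" as peak absolute translation
over the run; a peak-FD variant is available (`metric="peak_fd"`) since
the published description does not pin the exact definition.  Mean FD is
carried forward as the motion covariate.

## Statistics

- **Welch t / Hedges g** are computed from group summary statistics
  (mean, sd, n); raw-sample overloads reduce to these exactly.  Hedges g
  is the pooled-SD standardized difference times
  J = 1 − 3/(4(n₁+n₂) − 9).  One-tailed tests default to the *hypothesized
  direction* (first-listed group larger); an observed-direction convention
  (`tail="one_sided_observed"`) is provided because published one-tailed
  tables sometimes report the tail of the observed sign.
- **ANCOVA** fits `INT ~ group + age + sex + IQ + FD` by least squares
  with treatment-coded group (sex coded 0/1) and tests the group factor by
  model comparison against the covariates-only model; partial eta squared
  is SS_group/(SS_group + SS_residual).  The design matrix is checked for
  rank deficiency and the offending columns are named.  Degrees of freedom
  are reported as computed from the analyzed sample (k − 1, N − p); no
  attempt is made to mimic externally reported dfs that do not follow from
  the sample size.
- **FDR families**: the ANCOVA table is one BH family of 13 p-values; each
  pairwise column (TD v. ASD, TD v. SZ, ASD v. SZ) is its own family of
  13; each clinical group's correlation grid is one family across all
  ROI × measure cells.
- **Voxelwise maps** use per-voxel one-way ANOVA F and pooled-variance
  two-sample t (both tails of each pair), thresholded at uncorrected
  p < 0.001, with 26-connectivity clusters and peak world coordinates.  No
  random-field or permutation correction is applied.
- Shapiro–Wilk acts only as a reporting gate (Spearman is always what the
  pipeline reports for clinical correlations); Spearman uses average ranks
  on ties and pairwise-complete observations with a 4-pair minimum.

Printed-table reproduction note: table output rounds half away from zero
at 2 decimals, the convention used by the published tables (plain
banker's rounding prints 0.065 as 0.06 and fails to match).

## Synthetic cohorts

Each voxel is an independent stationary unit-variance Gaussian AR(1)
process whose coefficient φ comes from a ground-truth field; the
population INT is `TR·φ(1−φ^K)/(1−φ)`, inverted by monotone root-finding
(tolerance 1e−10) when a target INT is specified.  Defaults mirror the
target study design:

| parameter | default | rationale |
| --- | --- | --- |
| group sizes | 55 / 30 / 39 (TD / ASD / SZ) | study sample sizes |
| TR | 0.475 s | study acquisition |
| volumes | 947 | 7.5 min at TR 0.475 (`floor(450/0.475)`) |
| φ field | linear posterior→anterior gradient 0.55 → 0.85 | reproduces the known increasing INT gradient; spans ROI INT values of roughly 0.6–3 s |
| subject φ jitter sd | 0.05 | produces between-subject ROI INT sd ≈ 0.15 s, the scale needed for realistic effect sizes |
| SZ effect | φ decrement 0.035 inside the U_lLatOccC and U_rPostCenG spheres | calibrated by simulation to give Hedges g ≈ 0.6 on estimated ROI INT at the default n |
| phenotypes | group marginals for age, sex, IQ, FD, ADOS, PANSS | case-control demographic structure; sex counts hit the configured female fraction exactly |
| motion | random walks tuned to a target mean FD (70% translation / 30% rotation share) | makes the FD covariate and the exclusion rule exercisable |

Randomness is counter-based: a single master seed spawns independent
streams per subject and per purpose (phenotypes, motion, BOLD, φ jitter),
so subject *i* is bit-reproducible regardless of cohort size or generation
order, and identical configs give bit-identical cohorts.

**Scale.** The default grid is a compact 3 mm box covering all 13 spheres
(plus 9 mm padding), and by default only voxels inside the sphere union
carry simulated signal (`mask_mode="rois"`, 437 voxels); `mask_mode="full"`
simulates the whole box.  A full cohort (124 subjects × 947 volumes)
simulates and analyzes in a few seconds through the masked fast path
(`SyntheticCohort.masked_series` / `pipeline.analyze_cohort`), which is
numerically identical to streaming full 4D volumes apart from float32
storage rounding.

**What the generator does not emulate** — and hence what passing tests do
not certify about real data: spatial smoothness and physiological/scanner
noise structure (the AR(1) model is exactly the structure the estimator
assumes, so recovery here is a best case), covariance between phenotypes
(age/IQ/symptoms are drawn independently), any relation between motion and
signal, and the preprocessing chain (motion correction, denoising,
normalization are assumed already done on real inputs).

## Numerical and design choices

- ACF via exact dot products per lag (42 passes), not FFT; exactness
  against a double-loop oracle is tested to 1e−12.
- Sphere search is restricted to a bounding box derived from the affine's
  smallest singular value, so masks are exact for any invertible affine.
- BH-FDR delegates to the standard step-up implementation and is pinned
  by a brute-force oracle test; note that BH is *not* idempotent —
  re-adjusting adjusted values inflates them — so adjusted p-values must
  be computed once per family from raw p-values.
- Missing covariates drop the subject with a logged reason (no
  imputation), mirroring exclusion of incomplete phenotypic assessments.
- TR is read from the NIfTI header but can be overridden; header
  `pixdim[4]` is unreliable in the wild.
- Pipeline outputs are written in full precision TSV; 2-decimal rounding
  is presentation-only.

## Known limitations

- Spheres only; no parcellation/atlas ROIs.
- No alternative timescale estimators (exponential decay fit, spectral).
- Voxelwise inference is uncorrected by design; cluster tables are
  descriptive.
- The exclusion rule's exact published FD definition is not recoverable;
  both implemented variants are documented above.
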