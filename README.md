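# neurotimescales

Estimation and group analysis of **intrinsic neural timescales (INT)** from
resting-state BOLD fMRI, with a fully synthetic AR(1) validation harness.

The intrinsic neural timescale of a brain region measures how long
fluctuations of its spontaneous activity persist — a window of temporal
integration that is altered in autism spectrum disorder (ASD) and
schizophrenia (SZ).  This package is aimed at researchers running
case-control resting-state studies who want the complete INT analysis chain
as tested, reusable code: voxelwise estimation, spherical MNI region
extraction, the full group-comparison/correlation battery, and a generator
of synthetic cohorts with known ground truth to validate every stage.

## The estimator

For each voxel with time series $x_t$ sampled at repetition time
$\mathrm{TR}$, compute the sample autocorrelation function

$$r_k = \frac{\sum_t (x_t-\bar x)(x_{t+k}-\bar x)}{\sum_t (x_t-\bar x)^2},
\qquad k = 0, 1, \dots, K,\quad K = \lfloor 20\,\mathrm{s}/\mathrm{TR}\rfloor ,$$

walk the lags upward from $k=1$, and sum the coefficients while they remain
strictly positive, stopping at the first $r_k \le 0$:

$$\mathrm{INT} = \mathrm{TR}\cdot\sum_{k=1}^{k^*-1} r_k ,
\qquad k^* = \min\{k : r_k \le 0\}.$$

The result is an index in seconds; long-memory signals keep their ACF
positive over many lags and score high.  At the study acquisition
(TR = 0.475 s, 20 s window) the lag grid has exactly 42 lags.  For a
stationary AR(1) process with lag-one coefficient $\varphi$ the population
value is available in closed form,
$\mathrm{INT}(\varphi) = \mathrm{TR}\,\varphi(1-\varphi^K)/(1-\varphi)$,
which the synthetic module inverts to plant ground-truth timescale fields.

On top of the estimator the package implements: 6 mm-radius sphere ROIs at
13 published MNI peak coordinates, framewise-displacement QC with a
head-motion exclusion rule, ANCOVA of ROI INT on group with age/sex/IQ/FD
covariates (partial $\eta^2$), one-tailed Welch tests with Hedges *g*,
Benjamini–Hochberg FDR, Spearman correlation grids against clinical scores
(ADOS, PANSS), and simplified mass-univariate voxelwise maps with
26-connectivity cluster tables.

## Worked example

```python
from neurotimescales import (
    TimeSeries, sample_acf, int_from_acf, welch_t, hedges_g,
    simulate_voxel_series,
)

# one voxel with a long timescale: AR(1), phi = 0.9, 947 volumes at TR 0.475 s
acf = sample_acf(simulate_voxel_series(phi=0.9, n_volumes=947, seed=42), 42)
print("lag-1 autocorrelation:", round(acf.coefficients[1], 3))
print("INT estimate (s):     ", round(int_from_acf(acf, tr=0.475), 3))

# group comparison from summary statistics: mean, sd, n per group
t, df, p = welch_t(2.48, 1.15, 55, 1.73, 1.19, 39, tail="one_sided_first_larger")
g = hedges_g(2.48, 1.15, 55, 1.73, 1.19, 39)
print(f"Welch t = {t:.2f}, df = {df:.1f}, one-tailed p = {p:.4f}, Hedges g = {g:.2f}")
```

prints

```
lag-1 autocorrelation: 0.897
INT estimate (s):      2.846
Welch t = 3.05, df = 80.2, one-tailed p = 0.0015, Hedges g = 0.64
```

The lag-1 coefficient recovers $\varphi = 0.9$; the single-series INT
estimate (2.85 s) sits below the population value (4.22 s) because sampling
noise in the ACF tail truncates the positive run early — a finite-sample
bias that averages out over voxels (see `docs/methods.md`).  The Welch line
is the comparison of typically-developed controls against the schizophrenia
group in one occipital ROI, recomputed from group summary statistics: a
moderate effect (g = 0.64) with the first group hypothesized larger.

End-to-end on synthetic data:

```bash
neurotimescales make-fixture /tmp/cohort --n-per-group 4 3 3 --n-volumes 200
neurotimescales run /tmp/cohort/run_config.yaml
```

writes per-subject INT maps (NIfTI), the subjects-by-ROI table, the ANCOVA
and pairwise tables, correlation grids, and a QC manifest under
`/tmp/cohort/results/`.

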