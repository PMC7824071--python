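# Methods

## Model and assumptions

All procedures assume the standard method-comparison model for a complete
n × m table of continuous ratings:

    X_ij = mu_i + gamma_j + eps_ij,   eps_ij ~ N(0, sigma^2) iid,

with deterministic subject values mu_i and rater biases gamma_j, and a
common error SD sigma across subjects and raters (homoscedasticity). The
extended plot summarises each subject by (x̄_i, s_i), the sample mean and
the sample SD (divisor m − 1) of its m ratings. Every statistic in the
package is location-invariant in mu_i and scale-equivariant in sigma;
rater bias does not shift s_i's distribution when the biases are equal, but
unequal gamma_j inflate the s_i — that is exactly what the bias diagnostics
are for.

## The chi-based limit of agreement

When the m ratings of a subject share their mean, (m−1)·s_i²/sigma² is
chi-square with m−1 degrees of freedom, so s_i·√(m−1)/sigma is
chi-distributed. The one-sided 95% limit for the intra-subject SD is

    L = chi_{0.95,m-1} / sqrt(m-1) * sigma_hat.

`loa_factor(m, level)` evaluates the multiplier from the chi-square quantile
(`sqrt(chi2.ppf(level, m-1)/(m-1))`) rather than a lookup table, so any
m ≥ 2 and any level work; the m = 2..5 values at level 0.95 are 1.959964,
1.730818, 1.613973, 1.540108.

**Scale estimator.** The average intra-subject SD s̄ = n⁻¹Σ s_i has
expectation c4(m)·sigma with c4(m) = √(2/(m−1))·Γ(m/2)/Γ((m−1)/2) < 1
(≈ 0.798 at m = 2, ≈ 0.886 at m = 3), so plugging s̄ in directly would
underestimate the limit systematically — at m = 2 the new-subject coverage
would drop to ≈ 0.88. The package therefore uses the calibrated estimator

    sigma_hat = s̄ / c4(m),

equivalently L = chi_{0.95,m-1} · s̄ / E[chi_{m-1}]. This keeps the
"average intra-subject SD" as the sufficient summary while making sigma_hat
consistent for sigma; the Monte-Carlo coverage study validates precisely
this calibration (coverages ≈ 0.95 across the whole grid). `expected_sd_ratio(m)`
exposes c4, computed via log-gamma for numerical stability.

The limit is asymptotic in n: it accounts for neither the sampling noise of
sigma_hat nor the extra spread of a new subject's SD (there is no analogue
of the classical √(1+1/n) inflation), which is why in-sample coverage sits
slightly above and new-subject coverage slightly below 0.95 at n = 10, both
converging to 0.95 by n = 100. No finite-n correction is applied.

For m = 2 the package also provides the classical difference-scale
quantities: d_i = x_i1 − x_i2 (first minus second column; reorder columns to
flip), bias d̄, and limits d̄ ± t_{0.975,n−1}·√(1+1/n)·s_d with the exact
small-sample factor. The extended plot at m = 2 is the classical plot's
lower half mirrored at the bias line with the y-axis compressed by √2
(s_i = |d_i|/√2 exactly); the optional `rescale_sqrt2` plot flag undoes the
compression for comparison with difference-scale thresholds, and is off by
default because the plain axis keeps its interpretation as a within-subject
SD.

## Bootstrap confidence interval

The uncertainty of L is quantified by a bias-corrected and accelerated
(BCa) bootstrap: subjects (whole rows) are the resampling unit, 1000
repetitions by default, confidence level 0.95. Since L is a function of the
s_i alone, resampling rows reduces to resampling the SD vector. The bias
correction z0 uses the fraction of resampled limits strictly below the
observed one; the acceleration uses the leave-one-subject-out jackknife
skewness (closed form, as the statistic is linear in the s_i). Numerical
policies:

* all resampled limits identical → the interval collapses to the point
  estimate, with a warning;
* all resampled limits on one side of the estimate (z0 infinite) → plain
  percentile bounds, with a warning;
* endpoints are finally clamped to bracket the point estimate (a no-op in
  any non-pathological case);
* a fixed seed makes the interval bit-reproducible; the same seed with a
  wider level can never produce a narrower interval, because the resample
  set is drawn before the level is used.

At n = 100, m = 3 the interval covers the asymptotic limit
chi-factor × sigma in ≈ 95% of simulated datasets (measured in the test
suite over 1000 replications).

## Coverage study

`coverage_study` reproduces the validation grid: for each (m, n) with
m ∈ {2,3,4,5}, n ∈ {10,20,100}, it simulates 10,000 datasets of n + 1
subjects from the bias-free model (mu_i = 0, as subject values cancel in
every statistic used), estimates L from the first n subjects, and records

* `coverage_original` — per-dataset fraction of the n estimation SDs ≤ L,
  averaged over datasets;
* `coverage_new` — fraction of datasets whose held-out subject's SD ≤ L;
* `q95_original` / `q95_new` — empirical 95% quantiles of the
  scale-normalised SDs s/sigma_hat (estimation SDs pooled across datasets;
  held-out SD one per dataset). The normalisation makes the quantiles
  directly comparable with the closed-form multiplier — they are the
  factors that would have achieved exact 95% coverage — and equal to raw SD
  units when sigma = 1. Because sigma_hat is noisy at small n, the held-out
  quantile exceeds the multiplier at n = 10 (e.g. ≈ 2.19 vs 1.96 at m = 2)
  and approaches it by n = 100.

Simulation is vectorised and chunked (~2M gaussians per chunk); the full
grid at 10,000 simulations runs in a few seconds. One master seed spawns an
independent substream per cell (recorded in the cell), so any cell is
reproducible in isolation. With 10,000 simulations the MC standard error of
a coverage near 0.95 is ≈ 0.002 (per-dataset averaging makes
`coverage_original` even tighter), while the held-out 95% quantile — an
extreme quantile from one draw per dataset — has an MC SE up to ≈ 0.025 at
n = 10; comparisons of those quantiles between independent runs should
allow for noise of that size.

## Synthetic scenarios

`datagen` generates the four study conditions used throughout the tests and
docs; defaults are fixed and are the conditions the tests probe:

* **homogeneous** — common sigma = 2 (the baseline illustration scale).
* **rater_bias** — gamma_2 = sigma (the second rater measures one error-SD
  high); its tick mark B_2 has expectation sigma·(1−1/m) while the others
  sit at sigma/m, and at n = 100 B_2 is the largest indicator in
  essentially every replication.
* **rater_heteroscedastic** — sigma_2 = 40 vs 2 for the rest. Deviations
  from the subject mean mix raters, so the deviation-SD ratio is the
  contracted sqrt(712/180.02) ≈ 2 (m = 3), not 40/2 = 20; the noisy rater
  still wins the max-deviation attribution for well over half the subjects.
* **funnel** — error SD grows with the subject's true value as
  sigma + 0.1·mu_i, mu_i ~ U(10, 50). The affine form is the simplest
  monotone violation of homoscedasticity; it produces the classic funnel
  (Spearman correlation between x̄_i and s_i ≈ 0.4 at n = 200, m = 4).

Subject true values are uniform on (10, 50) by default — irrelevant to
every SD-based statistic, but giving plots x-axis spread. What the
generator does **not** emulate: correlated errors within subject, repeated
ratings per rater, non-normal error distributions, missing cells. Passing
tests therefore demonstrate correctness under the model's assumptions, not
robustness of the limit to their violation.

## Numerical and design choices

* Missing cells are rejected (complete-case input contract), never imputed:
  every formula assumes the complete grid.
* Max-deviation attribution breaks ties toward the first rater column;
  deviations within 1e−12 (relative) of the row maximum count as tied so
  the exact m = 2 tie survives floating-point rounding of the subject mean.
* s̄ = 0 (all raters agree exactly on every subject) yields L = 0 with a
  warning rather than an error.
* Empirical quantiles use linear interpolation (numpy default, R type 7).
* Figures are built without pyplot state; every drawn quantity carries a
  stable `gid` so tests assert against the figure's data model, not pixels.
* CSV is the only tabular format (UTF-8, comma, '.' decimal); `#` lines
  carry artifact metadata (scenario, seed, version) so every generated file
  is self-describing and reproducible.

## Limitations

* The limit is asymptotic in n; no closed-form confidence interval is
  provided (bootstrap only), and no exact small-sample limit exists here.
* Homoscedasticity is inherited from the classical construction; the
  funnel scenario shows how its violation looks, but no
  heteroscedasticity-adjusted limit is implemented.
* Bias and heterogeneity diagnostics are visual indicators, not hypothesis
  tests.
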