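# Methods

This note documents the models, algorithms, defaults, and design decisions
behind `lifespan_ec`, and what the synthetic benchmarks do and do not
demonstrate about real data.

## 1. Effective connectivity by regression DCM

### Model

Neuronal dynamics are linear: `dx/dt = A x + C u`, with `A` the R×R directed
coupling matrix (diagonal entries are self-decay terms and are expected
negative for stability) and `C u` optional exogenous input. BOLD is the
convolution of `x` with a linear hemodynamic response `h`, observed with white
Gaussian noise of per-region variance `σ_i²`.

Taking the DFT and using its differential property, the ODE becomes algebraic
per frequency bin. The continuous derivative `iω` is replaced by the discrete
difference operator `z_m = (exp(2πi m/N) − 1)/T` (N time points, sampling
interval T), which is exact for the discrete forward recursion. For each
target region *i* this yields a linear regression

    Y_i = X θ_i + ν,   Y_i = z_m · ŷ_i,   X = [ŷ_1 … ŷ_R, ĥû_1 … ĥû_K],

where `ŷ_r` are the DFTs of the (mean-centered) regional series. Under a
partial-independence assumption the R regressions are inverted separately;
complex rows are stacked as real and imaginary parts, keeping all arithmetic
real with an equivalent likelihood.

Frequency policy: the DC bin is always dropped; by default all bins up to the
Nyquist index are retained (no low-pass — empirically the full band also
recovers planted couplings best, because the high bins, though
signal-poor, regularize the near-collinear low-frequency block). The
retained fraction is configurable (`RdcmConfig.nyquist_fraction`).

### Variational Bayes inversion

Each regression gets a conjugate Gaussian–Gamma mean-field treatment:
`θ ~ N(m₀, L₀⁻¹)`, `τ ~ Gamma(a₀, b₀)`, with coordinate updates

    Σ = (E[τ] XᵀX + L₀)⁻¹,  μ = Σ (E[τ] Xᵀy + L₀ m₀)
    a = a₀ + n/2,           b = b₀ + ½ E[‖y − Xθ‖²]

iterated until the negative free energy changes by < 1e−8 relative (max 500
iterations; non-convergence is flagged, never fatal). The free-energy trace is
exposed and is non-decreasing — asserted in tests. With a degenerate (fixed)
noise precision the posterior mean is the closed-form ridge solution, which
serves as an oracle in tests.

Priors: off-diagonal couplings `N(0, 1)`; self connections `N(−1, 1)`
(negative expectation encodes self-decay); inputs `N(0, 1)`; noise
`Gamma(2, 1)`. All configurable. In the regime the benchmarks probe the
likelihood dominates, so results are insensitive to these within wide ranges.

Resting-state mode simply omits the input columns (`C·u` support exists and is
used by the exact-recovery fixtures, which construct data bin-by-bin as
`ŷ_m = (z_m I − A)⁻¹ C (ĥû)_m` so the discrete model holds exactly and the
regression has a zero-residual solution at the generating parameters).

### Known estimator limitations

In resting state the driving fluctuations are the *only* excitation and are
unmodeled, so the regression residual *is* the (HRF-filtered) drive — which is
correlated with the regressors. The estimator is therefore not consistent:
noise-free data give strongly biased estimates, moderate observation noise
(SNR ≈ 3) paradoxically regularizes the near-collinear design, and the
off-diagonal correlation between planted and estimated couplings plateaus
around 0.80–0.85 for 10-region hierarchical motifs at T = 600 volumes,
TR = 0.72 s, SNR = 3 (sign agreement of the strongest edges is robustly
≥ 95%). Alternatives evaluated and rejected: restricting or
whitening the frequency band, errors-in-variables moment corrections, the
exact-`iω` operator, matrix-logarithm discretization corrections, and
parametric-bootstrap debiasing — all performed worse than the plain
full-band estimator. Absolute coupling magnitudes are attenuated (roughly
proportionally), so analyses downstream should rely on patterns, signs and
relative change, which is what the lifespan metrics do.

### Canonical HRF

Double-gamma kernel parameterized by the *modes* of its two lobes (peak 6 s,
undershoot 16 s, dispersions 1 s, undershoot ratio 1/6), sampled at TR; the
argmax therefore sits at ~6 s regardless of dispersion rounding.

## 2. Synthetic lifespan cohorts

The generator plants, per directed edge, a smooth lifespan curve in
transformed age `t = log2(age + 1)`: a difference of logistics
`g(t) = σ(r(t − a)) − σ(s(t − b))` whose inflection offsets are solved
(Brent's method on the derivative condition) so the maximum sits exactly at a
requested peak age, plus an optional early-infancy Gaussian dip. Inhibitory
edges carry a fixed negative sign with the curve describing magnitude, giving
U-shaped signed trajectories. Edge value = baseline + amplitude·bump + sex
effect·sex + site offset + subject intercept. Generating matrices get
self-decay −1 on the diagonal and are rescaled (off-diagonal shrink, factor
recorded) if the spectral abscissa is not below −0.05; 100% of emitted
matrices are stable, asserted in tests.

Default planted networks are sparse and strong (edge density 0.12, within-
network baseline 0.35, between 0.18) — the realistic regime in which a
log-normal-like weight distribution is dominated by few strong connections,
and the regime in which recovery is informative. The 10-region recovery
benchmark uses a fixed *hierarchical motif* (feedforward chain 0.4–0.7 with
weaker feedback 0.15–0.35 and five long-range inhibitory edges), the
structure these analyses target, rather than an iid-random matrix.

BOLD simulation: Euler–Maruyama at `dt = TR/16` with per-region white driving
noise (SD 1.0), 32 burn-in volumes, convolution with the canonical HRF at
neuronal resolution, decimation to TR, then white observation noise scaled so
SD(signal)/SD(noise) equals the stated SNR per region (SNR is otherwise
ambiguous; this definition is pinned). Everything is deterministic given the
seed; cohorts are byte-reproducible.

Cohort structure: ages uniform in `t` over the requested range (default
10 days–100 years), which emphasizes infancy and childhood the way
transformed-age lifespan designs do; four acquisition sites assigned by age
band (infancy, development, young adult, aging), mirroring a multi-study
aggregate; balanced sexes (counts differ by ≤ 1); infancy-band subjects
eligible for one longitudinal repeat.

The **metric-level cohort** (`simulate_metric_cohort`) bypasses the BOLD and
estimation stages and draws a scalar metric directly from a planted curve plus
sex, subject, site, and residual terms. Its defaults are calibrated to the
package's recovery benchmark: amplitude 1.0, symmetric rise/fall rates 2.0 in
`t`, peak at 9 y, residual SD 0.25, subject SD 0.15, site SD 0.05, 400 scans.
With these, the fitted peak lands within ±1.5 y of truth and the 95%
bootstrap CI covers truth in ≥ 8/10 seeded replicates. This calibration is a
design requirement of the benchmark, *not* an empirical claim about real
cohorts: with per-scan scatter comparable to the curve amplitude (as real
global-EC data show), peak ages are only identifiable to several years even
at thousands of scans, and the penalized fit's argmax acquires a late bias of
1–2 y for flat-tailed curves. Passing the synthetic benchmark demonstrates
correctness of the machinery at a stated signal-to-noise, not precision on
any given real dataset.

Features of real data the generator does **not** emulate: head motion and its
age correlation, physiological (cardiac/respiratory) noise, nonlinear
(balloon-model) hemodynamics and regional HRF variability, scanner drift,
non-white neuronal fluctuations, and parcellation misassignment.

## 3. Growth-curve layer

Model per metric: `y_i(t) = f1(t) + f2(t)·sex_i + α_subject + β_site + ε`,
sex coded +1/−1, `t = log2(age+1)`.

* **Basis**: cubic B-splines, dimension k, clamped knots, interior knots
  evenly spaced on the observed `t` range. Penalty = exact Gram matrix of
  second derivatives (two-point Gauss–Legendre per knot interval, exact for
  the piecewise-linear second derivatives).
* **Mixed-model form**: the penalty's 2-dimensional null space (constant +
  linear, and their sex interactions) enters as fixed effects; the range
  space is eigen-reparameterized to iid random coefficients. Subject and site
  random intercepts are included whenever more than one level exists (logged
  otherwise).
* **REML**: the restricted likelihood is optimized over log-variances with
  bounded Powell iterations; bounds tie each variance to the data variance
  (`log var(y) − 18` to `+4`) with a smooth quadratic barrier, because
  near-saturated components (e.g. a 2-level site factor) have flat restricted
  likelihoods along which the intercept split is indeterminate.
* **Coefficient posterior**: conditional on the variance components, the
  joint Gaussian posterior of all coefficients is formed from the penalized
  normal equations. Smoothing-parameter uncertainty is then propagated: the
  covariance of the REML log-variances (finite-difference Hessian of the
  restricted deviance, eigenvalues floored at 0.5 so unidentified directions
  contribute at most O(1)) is pushed through the coefficient solution by
  central differences and added to the conditional covariance. Without this
  correction the bootstrap peak-age intervals undercover noticeably.
* **BIC / k selection**: k runs 5–14; the criterion is the marginal ML
  deviance at the REML variances plus `(p_fixed + n_variance_components)·log n`
  — the mixed-model convention in which each smooth contributes its
  null-space fixed effects and one variance parameter, so the parameter count
  is constant in k and selection compares marginal likelihoods. (An
  edf-based count was tried and over-penalized k, pinning the winner at the
  coarsest basis.) Failed k values are skipped with a warning.
* **Prediction**: fixed-effect curve with random intercepts at zero;
  `CI = y_pred ± Φ⁻¹(1 − α/2) · y_se` with α = 0.05 by default; sex-specific
  curves are predictions of the single joint fit at sex = ±1; the
  sex-independent curve sets sex = 0. Extrapolation beyond the fitted range
  is flagged. The prediction grid is 512 points equally spaced in `t`; grid
  error is far below reported CI widths.

## 4. Peaks, velocities, bootstrap

The peak is the largest *interior* local maximum (strictly greater than both
neighbors; endpoints excluded); no interior maximum is an explicit no-peak
value, not an error. Inhibitory metrics are negated first. Velocity is the
forward difference of the fitted curve with respect to age in *years* (curves
are displayed against age, not t); the ages of maximal growth and decline are
reported.

Peak-age CIs resample the age-smooth coefficient posterior (the sex-0 curve's
null-space and range coefficients jointly, i.e. intercept and linear trend are
perturbed along with the wiggly part): each of 20,000 draws (2,000 in the
test suite) rebuilds the curve on the grid and contributes its peak age;
peakless draws are dropped and counted, and the CI is reported missing if
they exceed half the draws. The CI is the (α/2, 1−α/2) percentile pair.

## 5. Trajectory patterns

* **Clustering**: K-means (squared Euclidean) on the raw sex-0 curves — no
  z-scoring by default, so amplitude differences remain part of the pattern
  (a `standardize` flag exists). k-means++ seeding, 50 restarts, fixed seed.
  Labels are renumbered by descending centroid value at the final grid point
  so runs are comparable; network composition percentages accompany the
  labels. K is pinned in configuration (default 5); `select_k` reports
  inertia and silhouette for K = 2–10 without choosing, since cluster count
  selection is ultimately substantive.
* **Correlation**: Pearson between fitted curves, with within/between-network
  block means; zero-variance curves yield missing rows rather than errors.
* **Early/late variability**: SD of each curve over grid points with age < 12
  and age > 20 (cutoffs configurable); the per-network paired comparison uses
  the signed-rank test.
* **Gradient**: curves are centered per grid point and the first principal
  axis over regions is extracted by SVD; the loading sign is fixed so the
  VIS-network mean loading is non-negative (eigen-sign is arbitrary);
  excitatory/inhibitory ECS variants use the same machinery.

## 6. Inference utilities

Rank-sum: exact enumeration when both groups have < 10 observations and no
ties, otherwise the tie-corrected, continuity-corrected normal approximation
(Z reported, positive when the first sample tends larger). Signed-rank: zero
differences dropped and counted; exact for ≤ 25 nonzero differences without
tied magnitudes. Degenerate all-tied inputs return p = 1. BH-FDR is the
step-up adjustment with monotonicity enforcement; Cohen's d uses the pooled
SD with the n₁+n₂−2 denominator and is NaN when the pooled SD is zero. Under
the null the rank-sum test rejects at 4.8–5.2% at α = 0.05 (10,000-rep
calibration in the acceptance checks).

## 7. Pipeline, seeds, determinism

Stages: simulate → estimate → metrics → fit → peaks → cluster → gradient →
stats. All artifacts are TSV/JSON; a stage is skipped when its outputs exist,
so deleting an intermediate reruns only downstream work. One master seed;
stage seeds are `(master·1000 + stage_index) mod 2³¹`, recorded in the run
record together with config snapshot, timings, and SHA-256 digests. Identical
config + seed reproduce every artifact byte for byte (floats are written with
`%.17g` where bit-exact round-trips matter). The config validator rejects
unknown keys.

Benchmark problem sizes (the package's own choices): the end-to-end toy runs
12–20 regions, 60–128 scans, 150–400 volumes; EC recovery uses 10 regions ×
600 volumes; growth-curve recovery uses 400 metric-level scans × 10
replicates; bootstrap CIs use 2,000 draws in tests and 20,000 by default in
the analysis drivers.

## 8. Known limitations

* Per-scan NSI from noisy desk-scale EC estimates is unstable (the
  within-network denominator can approach zero), so network-level indices are
  best interpreted on fitted or averaged quantities; the whole-cohort mean
  NSI printed by the toy drivers illustrates this.
* The overall mean EC of sparse toy connectomes is dominated by zero edges;
  its fitted lifespan curve can be flat at small n while the excitatory mean
  carries the planted signal (step 04 of the analysis narrates this).
* Coupling magnitudes are attenuated by the estimator (see §1); sign patterns
  and relative trajectories are the reliable outputs.
* The GAMM layer fits a single smooth per sex coding, not centile curves; it
  charts means, not distributional references.
* FD-based motion exclusion consumes a supplied mean-FD column (threshold
  0.5 mm, scans *exceeding* the threshold removed — boundary scans kept);
  motion itself is not modeled or simulated.
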