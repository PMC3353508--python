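# Methods

## Models and estimation

Leaf dry weight *w* (g) is related to leaf length *l* (mm) either
allometrically, w = a·l^b, or isometrically, w = c·l. Units are fixed
package-wide as grams and millimetres; readers reject or convert other
units explicitly.

**Allometric fit.** (a, b) minimize Σ(w_i − a·l_i^b)² on the original
gram scale, via bounded trust-region least squares (a, b > 0, analytic
Jacobian), initialized from an OLS regression of ln w on ln l.
Convergence tolerances are fixed (ftol = xtol = 1e−12, gtol = 1e−10,
≤ 500 function evaluations) so results reproduce across platforms.
Standard errors use the Gauss-Newton approximation
se_j = √(σ̂²·[JᵀJ]⁻¹_jj) with σ̂² = rss/(n−2). Fitting on the raw scale
(rather than on logs) keeps R² and the residual battery defined on the
weights practitioners care about; a `log_scale=True` switch fits
ln w = ln a + b·ln l by OLS instead (the maximum-likelihood estimator
when errors are multiplicative lognormal), reporting fitted values and
residuals back on the gram scale.

**Isometric fit.** Regression through the origin in closed form:
c = Σw_i·l_i / Σl_i², se(c) = √(σ̂²/Σl_i²), σ̂² = rss/(n−1).

**Shoot aggregates.** When only shoot biomass w_s is known, the same
criteria are minimized with the per-leaf prediction replaced by
Σ_k a·l_k^b (or c·ΣL). The allometric shoot fit is initialized by
treating each shoot's total length as a pseudo-leaf; this is exact for
single-leaf shoots and an adequate start otherwise. Fitting is
unweighted throughout; no heteroscedasticity weighting is applied to
the point estimates.

Records missing a weight are excluded from fitting with a logged count;
they still contribute lengths to the threshold partition.

## Threshold diagnostics

For b ≠ 1 the deviation θ(l) = c·l − a·l^b vanishes at the origin and at
l\* = (c/a)^(1/(b−1)); |θ| peaks at l_θm = l\*·b^(−1/(b−1)) < l\* with
maximum θ_max = (c/(a·b))^(b/(b−1))·a·|b−1|. For b > 1 the ratio proxy
over-predicts below l\* and under-predicts beyond it; for b < 1 the
signs reverse. At b = 1 exactly, θ ≡ 0 and the threshold quantities
raise a typed `UndefinedThresholdError` rather than returning infinity,
because every consumer must branch on that case explicitly. In the
below/above-l\* partition, ties (l = l\*) count as below; rounding
happens only in the report's `display` block (0.1 mm for l\*, two
significant figures for θ_max, the precision such values are
conventionally tabulated at).

l\* is extremely sensitive to rounding in b (it involves b through
1/(b−1) in the exponent): with b printed to 2–4 decimals, recomputed
thresholds can differ from tabulated ones by factors of several. The
package always computes from the closed form at full precision.

The bias profile reports, per leaf, θ and the relative error
(c·l − w)/w, plus the fraction of observed weights underestimated by
the ratio proxy (overall and restricted to l > l\*) and the mean
absolute relative error. For shoot data the profile is computed on
shoot totals and the beyond-threshold restriction is omitted (l\* is a
per-leaf notion). Zero-weight records are excluded with a warning.

## Selection battery

- **R²** = 1 − Σ(o−p)²/Σ(o−ō)² on raw weights; may be negative for a
  model worse than the mean, as usual for nonlinear fits.
- **CCC** (Lin): ρ̂ = 2s_xy/(s_x² + s_y² + (x̄−ȳ)²) with n-denominator
  moments; a `bias_corrected` flag switches to n−1 denominators. ρ̂
  never exceeds |Pearson r|.
- **AIC**: n·ln(rss/n) + 2K, K = mean-function parameters + 1 (the
  error variance is counted). Additive likelihood constants are
  dropped, so absolute AIC values are convention-dependent and only
  within-dataset differences are meaningful; the report therefore
  surfaces ΔAIC = AIC_iso − AIC_allo prominently. |ΔAIC| > 10 is
  labelled "strong", 4 < |ΔAIC| ≤ 10 "positive", otherwise
  "indistinguishable". rss = 0 raises a perfect-fit signal instead of
  returning −∞.
- **Lack of fit**: observations are grouped by length rounded to a
  configurable resolution (default 1 mm — measured lengths are
  effectively discrete), rss is split into pure error (within-group)
  and lack of fit, and F = (SS_lof/(m−p))/(SS_pe/(n−m)) is referred to
  F(m−p, n−m). Both degrees of freedom are reported with explicit
  labels. Designs without replicate groups yield a typed
  "not applicable" result rather than an error.
- **Mean test**: two-sided paired t-test of observed vs predicted.
  All-zero differences give p = 1; constant nonzero differences give
  p = 0 with a warning.
- **Residuals**: Shapiro-Wilk normality for n ≤ 5000 (D'Agostino K²
  above), Breusch-Pagan regression of squared residuals on fitted
  values for homoscedasticity; both not-applicable below n = 8 or for
  constant residuals.

p-values across the battery are reported raw, without multiplicity
adjustment — the battery is descriptive, and adjusting would change the
meaning of each individual diagnostic.

## Synthetic data

The generator emulates the structure of leaf-census data: right-skewed
lengths (lognormal by default; gamma/uniform available), conditional
mean weights a·l^b, and noise that grows with the mean. Default noise
is multiplicative lognormal with σ = 0.2 and the mean-one correction
exp(−σ²/2), so E[w|l] = a·l^b exactly; additive normal and
power-variance (sd ∝ mean^γ) noise are available. Additive noise can
produce negative weights; these are floored at 1e−9 g and counted, with
a warning when more than 1% are truncated. Default study conditions:
n = 500 leaves, a = 1e−5, b = 1.41, lognormal lengths with median
150 mm and log-sd 0.5; shoots draw 3–6 leaves each and sum their noisy
weights. Seeds are explicit and mandatory; identical configs give
identical datasets.

Four site-style presets mirror the archetypal threshold partitions of
eelgrass surveys (80%, 20%, 70% and 82% of lengths below l\*). Each
preset carries a published (a, b, c) triple and solves its lognormal
location analytically, mu = ln l\* − σ·Φ⁻¹(target), against the l\*
implied by its own triple — not against tabulated thresholds, which are
not reproducible from the printed parameters (see above). The mesocosm
preset consequently implies very long leaves (median ≈ 1.5 m); it is a
partition archetype, not a morphological one.

What the generator does **not** emulate: temporal leaf growth and
plastochrone intervals, site-level mixtures, measurement error in
length, seasonal covariates, or the detailed length-weight joint
distribution of any real meadow. Passing recovery and selection tests
therefore demonstrates correctness of the estimators under the stated
error model, not field validity of any particular parameter set.

## Parameter recovery and interval coverage

`recovery_experiment` spawns per-replicate seeds deterministically,
refits each simulated dataset, and reports bias, relative bias, RMSE
and the coverage of nominal 95% Wald intervals. Under the default
multiplicative noise, the additive-NLS point estimate of b is nearly
unbiased (mean bias ≈ 0.002 at n = 500), but its Gauss-Newton intervals
undercover severely (≈ 0.50 observed), because the covariance assumes a
constant error variance that the noise model deliberately violates;
heteroscedasticity-robust (sandwich/HC3) variants still cover only
≈ 0.82–0.90 at this sample size under the long-tailed length design.
Nominal coverage is obtained by matching the estimator to the noise:
the log-scale fit is the MLE under multiplicative lognormal errors and
its Wald intervals for b cover ≈ 0.95–0.96. The experiment exposes
`log_scale` for exactly this purpose, and coverage claims in the test
suite are made on the noise-matched estimator while bias claims are
made on the default raw-scale fit. This is a known, documented
limitation of naive NLS standard errors on heteroscedastic biological
data, not an implementation defect.

## Numerical and I/O conventions

Grid oracles in the tests scan b at 1e−4 resolution (allometric fit)
and |θ| at up to 10⁶ points on (0, l\*) (deviation maximum); the closed
forms agree to 1e−6 relative. CSV dialects are UTF-8 with a mandatory
header and dot decimals, comma-separated by default with a delimiter
flag; missing weights are empty fields, never 0. Shoot datasets are a
pair of files (per-leaf lengths + per-shoot weights) joined on
(site, shoot_id); duplicate shoot weights, orphan leaves and weighted
shoots without leaves are row-level errors naming the offender. Reports
serialize full-precision numbers plus a rounded `display` block. CLI
exit codes: 0 success, 2 usage, 3 configuration, 4 data, 5 optimizer
non-convergence.

Simulation sizes in the test suite (replicate counts of 100–2000,
n = 500–1000 leaves) are chosen so the binomial/Monte-Carlo error of
each checked rate is several times smaller than the asserted tolerance.
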