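# Methods

## Data-generating model

Each simulated trial draws, independently per patient, a treatment indicator
T ~ Bernoulli(0.5) (simple randomisation — no blocking, so arm sizes are
random), a baseline covariate X ~ N(0, 1), and an outcome from

    Y = α + β_T·T + β_cov·f(X) + ε.

Three association shapes are studied: f(X) = X (`linear`), e^X (`monotonic`,
i.e. non-linear but monotone) and X² (`nonmonotonic`, U-shaped). For
continuous outcomes ε ~ N(0, σ_e) with σ_e = 1 and α = 0 (the intercept has no
effect on the bias, type I error or power of the treatment test, so it is
fixed). For binary outcomes ε is standard logistic (variance π²/3, SD
σ_e = π/√3) and the observed response is 1{Y > 0}; under this latent-variable
construction every coefficient is a **conditional log odds ratio**, which is
the estimand all analyses target.

Degenerate draws (an empty arm, or a binary outcome vector that is all 0 or
all 1 — essentially impossible at the default sizes) are regenerated from the
same stream rather than dropped, keeping the replicate count fixed; more than
100 attempts raises an error.

### Effect-size calibration

None of the effect sizes are free parameters:

* **β_cov** solves β_cov·(p90 − p10) = σ_e, where p10/p90 are the 10th/90th
  percentiles of f(X). The percentiles are *theoretical* — normal quantiles
  for f(X) = X, lognormal(0,1) for e^X, χ²₁ for X² — so the calibration is
  closed-form, reproducible and seed-free. Values: 0.3902 / 0.3008 / 0.3718
  (continuous) and 0.7077 / 0.5456 / 0.6743 (binary) for linear / monotone /
  U-shaped. The reference values this work is checked against print 0.385 and
  0.700 for the linear shape (third-decimal difference of unknown origin,
  possibly empirical percentiles or rounding); the χ²-based values agree to
  three decimals.
* The **binary intercept** α solves E_X[expit(α + β_cov f(X))] = 1/2 — a 50%
  marginal control-arm event rate — by Brent root-finding with the expectation
  computed by 80-point Gauss–Hermite quadrature (event-rate error far below
  the 10⁻⁶ tolerance).
* **β_T** targets 80% power at a two-sided 5% level. Continuous outcomes use
  the classical two-sample formula on the residual scale,
  (z_{0.975} + z_{0.80})·σ_e·√(4/n) = 0.3962 at n = 200. For binary outcomes
  no closed form exists once the covariate enters the latent model, so β_T is
  found by monotone bisection on the empirical power of the *correctly
  specified* adjusted logistic analysis (model: intercept + T + f(X)),
  estimated from 10 000 simulated trials per candidate with common random
  numbers across candidates (which makes the empirical power curve monotone
  and the bisection stable); the accepted candidate is within one percentage
  point of the target. Typical values at n = 600: ≈ 0.49 (both shapes
  reported here).

Sample sizes default to n = 200 (continuous) and n = 600 (binary), the median
sizes of published trials with those outcome types; 5000 replications is the
default study size.

## Covariate representations

All sample percentiles (median, quartile cutpoints, knot placement) use linear
interpolation between order statistics (numpy's default, the "type 7" rule),
and group membership is decided by strict `>` against the cutpoint — with
continuous data ties are measure-zero, but the rule must be fixed for the
analyze mode.

* **Dichotomised / categorised**: indicators for exceeding the sample median,
  or for the quartile groups (q25, q50], (q50, q75], (q75, ∞) with the lowest
  quartile as reference. Both are invariant to monotone transforms of X that
  preserve percentile ranks.
* **Fractional polynomials**: powers from {−2, −1, −0.5, 0, 0.5, 1, 2, 3},
  p = 0 meaning log X and a repeated pair (p, p) meaning X^p and X^p·log X.
  Because X can be non-positive, the covariate is first shifted by
  −min(x) + δ, δ the smallest positive gap between adjacent sorted distinct
  values (the Royston–Sauerbrei convention), with a float-resolution guard so
  the output is strictly positive even when δ underflows the addition. No
  power-of-10 rescaling is applied — the simulated covariate is O(1), and
  scaling is statistically a no-op for FP model spaces (it only affects
  conditioning, which the fitting kernels handle internally; see below). This
  choice is worth revisiting if the analyze mode meets covariates of very
  different magnitude.
* **Restricted cubic splines**: K total knots at Harrell's percentiles
  ({10, 50, 90} for K = 3; {5, 27.5, 50, 72.5, 95} for K = 5), the outer pair
  acting as boundary knots, so RCS-3 contributes 2 df and RCS-5 4 df. Columns
  are the linear term plus, per interior knot k_j,
  (x − k_j)₊³ − λ_j(x − k_min)₊³ − (1 − λ_j)(x − k_max)₊³ with
  λ_j = (k_max − k_j)/(k_max − k_min); the cubic and quadratic parts cancel
  identically beyond the boundary knots (tail linearity) and each column is C²
  everywhere. Bases are deliberately neither centred nor orthogonalised:
  treatment inference is invariant to such reparameterisations and the raw
  parameters stay interpretable.

## Fitting and inference

Continuous outcomes: ordinary least squares, Wald t-test on the treatment
coefficient with n − p degrees of freedom. Binary outcomes: logistic maximum
likelihood by Newton–Raphson/IRLS, convergence when the maximum absolute score
is ≤ 10⁻⁸ (on the standardised scale) or the relative deviance change is
≤ 10⁻¹⁰, with at most 100 iterations; the Wald z-test is used. Wald (rather
than likelihood-ratio) inference is the conventional default for both.

Numerical choices worth stating:

* Inside the fitting kernels, non-intercept columns are standardised before
  solving and estimates/SEs are mapped back. This is invisible statistically
  but essential numerically: FP candidates such as x^(−2) applied after the
  minimum-gap shift produce columns spanning many orders of magnitude.
* The kernels are *batched* — they fit R stacked trials at once — because an
  FP2 analysis alone refits 36 candidate models per replicate. A plain-Newton
  fast path handles the vast majority of replicates; rows that have not
  converged after 30 iterations are re-fit with deviance-monotone step
  halving. The single-trial API calls the same kernels with R = 1, so there is
  exactly one implementation (a replicate-by-replicate reference engine is
  kept and tested for equality).
* Complete separation is detected as a deviance collapsing below 10⁻⁶ (a
  perfect fit, unattainable by a legitimately noisy logistic model); such fits
  — and any with non-finite or non-positive SEs or diverging coefficients —
  are flagged unconverged. Non-converged replicates count as non-rejections
  and are excluded from bias averages, with counts reported; this is
  deterministic and conservative.
* FP selection minimises deviance (RSS for least squares) over the candidate
  grid with the treatment term included in every candidate fit; candidates
  that fail to converge are skipped. Ties break to the first candidate in
  canonical order — singletons ascending for FP1, lexicographic pairs
  (p1 ≤ p2) for FP2 — which only matters for bit-reproducibility, since ties
  have measure zero with continuous data.

## Monte-Carlo design and metrics

One named RNG stream per (scenario seed, replicate) — derived via
`SeedSequence(seed, spawn_key=(rep,))` — so all seven analyses of a replicate
see the identical dataset, runs are bit-reproducible, and any execution order
(batched, looped, parallel) yields identical aggregates.

Per method and scenario: mean estimate; bias (mean estimate − β_T); percent
attenuation 100·(β_T − mean estimate)/β_T against the *true conditional* β_T
(defined only when β_T ≠ 0; positive = shrunk toward the null); rejection rate
of the Wald test at α = 0.05 (type I error under the null, power otherwise).
Monte-Carlo SEs accompany every quantity: binomial √(r(1−r)/R) for rates,
sample SD/√R for means. Method contrasts (e.g. power lost relative to FP2)
are computed from per-replicate rejection indicators, whose paired SE is much
smaller than the independent-samples one because the analyses share data.

## What the generator does and does not emulate

It reproduces the study conditions exactly: one standard-normal covariate,
three association shapes, calibrated effects, simple 1:1 randomisation, and
latent-logistic binary outcomes. It does not emulate measurement error,
covariate distributions with skew or ties, more than one covariate, stratified
or blocked randomisation, missing data, or time-to-event outcomes — so
passing tests demonstrate the relative behaviour of the adjustment methods
under clean conditions, not their performance on any particular real trial.

## Known limitations and discrepancies

* **Binary-outcome attenuation under this DGM is smaller than some reference
  figures.** The asymptotic probability limits of the misspecified logistic
  estimators under the latent model above are fully computable by quadrature:
  with the calibrated β_cov values, dichotomised adjustment under the linear
  shape attenuates the log OR by ≈ 3.5% (≈ 5% at n = 600 in simulation) and
  linear/dichotomised adjustment under the U-shape by ≈ 10%, essentially
  independently of β_T; reference figures of ≈ 11.7% and ≈ 20% for these cells
  are not attainable from this model with these effect sizes, and no single
  rescaling of β_cov reconciles all of the reported cells at once (median
  splitting yields the *same* design column under the linear and monotone
  shapes, so its attenuation cannot differ much between them). The
  corresponding binary power-loss contrasts are smaller in the same
  proportion. The continuous-outcome power results, which do not involve
  non-collapsibility, reproduce the reference figures closely.
* The acceptance run uses 2500 replications for powered scenarios and 5000
  for null scenarios — the former chosen as the smallest study size at which
  the paired power contrasts have MC SEs well under one percentage point.
* Binary β_T calibration is itself simulation-based, so the targeted 80%
  power carries ±1-point tolerance; power *contrasts* between methods are
  insensitive to this.
* The analyze mode handles continuous and binary outcomes with a single
  continuous covariate (plus the trial arm); time-to-event outcomes and
  multi-covariate adjustment are out of scope.
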