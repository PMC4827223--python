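# covadjust

Tools for studying — and applying — different ways of adjusting for a
**continuous baseline covariate** in the analysis of a two-arm randomised
controlled trial.

Trial analysts routinely face a continuous prognostic variable (age, BMI,
baseline severity, effusion size, ...) whose relationship with the outcome is
unknown. Common practice is to dichotomise it at the median or cut it into
quartile groups; flexible alternatives keep it continuous. This package
implements the seven covariate representations most often compared in that
debate and a Monte-Carlo framework that quantifies what each one costs in
bias, type I error and power:

| method | design columns | df |
|---|---|---|
| `dichotomised` | 1{X > sample median} | 1 |
| `categorised` | quartile-group indicators (lowest group reference) | 3 |
| `linear` | X | 1 |
| `fp1` | X^p, p selected from {−2, −1, −0.5, 0, 0.5, 1, 2, 3} (0 ≡ log X) | 1 |
| `fp2` | X^p1, X^p2 from the same grid (p1 = p2 ≡ X^p, X^p log X) | 2 |
| `rcs3` | restricted cubic spline, 3 knots at the 10/50/90 percentiles | 2 |
| `rcs5` | restricted cubic spline, 5 knots at the 5/27.5/50/72.5/95 percentiles | 4 |

## Model

Outcomes are generated from

    Y_i = α + β_T·T_i + β_cov·f(X_i) + ε_i,     X_i ~ N(0, 1)

with f(X) ∈ {X, e^X, X²} (linear / monotone / U-shaped association) and
per-patient Bernoulli(0.5) randomisation T_i. Continuous outcomes use
ε ~ N(0, 1); binary outcomes are 1{Y_i > 0} with standard-logistic ε, so every
coefficient is a conditional log odds ratio and the latent error SD is π/√3.
Effect sizes are calibrated, not chosen ad hoc: β_cov solves
β_cov·(p90 − p10 of f(X)) = σ_e using closed-form percentiles; the binary
intercept fixes a 50% control-arm event rate by quadrature; β_T targets 80%
power (closed form for continuous outcomes, simulation-based bisection against
the correctly specified adjusted logistic analysis for binary ones).

Each simulated trial is analysed by OLS (continuous) or maximum-likelihood
logistic regression (binary) with the treatment indicator plus one of the
representations above; fractional polynomials refit every candidate power and
keep the deviance-minimising model, always retaining the treatment term.
Inference is a two-sided Wald test on the treatment coefficient.

## Worked example

```python
import covadjust as ca

# a calibrated U-shaped-association scenario, continuous outcome, n=200
spec = ca.make_scenario("continuous", "nonmonotonic", effect="powered",
                        reps=2000, seed=91)
res = ca.run_scenario(spec)
for m in ("dichotomised", "linear", "fp2", "rcs3"):
    s = res.summaries[m]
    print(f"{m:13s} power {100*s.rejection_rate:5.1f}%  "
          f"loss vs FP2 {res.power_vs_fp2[m]:5.1f} pts  bias {s.bias:+.4f}")
```

prints

```
dichotomised  power  69.0%  loss vs FP2   9.5 pts  bias +0.0000
linear        power  69.0%  loss vs FP2   9.4 pts  bias -0.0001
fp2           power  78.5%  loss vs FP2   0.0 pts  bias -0.0039
rcs3          power  78.2%  loss vs FP2   0.2 pts  bias -0.0039
```

i.e. when the covariate-outcome association is U-shaped, median-splitting or a
linear term forfeits about ten percentage points of power relative to a
two-term fractional polynomial, while a 3-knot spline keeps essentially all of
it — and (continuous outcome) every method remains unbiased.

Single datasets can be analysed the same way from Python
(`TreatmentEffectEstimator(method="rcs3", family="binary").fit(X, y)` with
`X = [arm, covariate]` columns, a scikit-learn-style estimator) or from the
shell:

```sh
covadjust analyze --data trial.csv --outcome y --arm arm --covariate x \
                  --family binary --method all     # unadjusted + all 7
covadjust simulate --out results/                  # full 12-scenario grid
covadjust calibrate --family binary --shape nonmonotonic
```

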