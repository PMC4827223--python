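"""Data-generating model for the simulated randomised trials.

A single continuous baseline covariate ``X ~ N(0, 1)`` influences the outcome
through one of three association shapes ``f``:

* ``linear``: f(X) = X
* ``monotonic``: f(X) = exp(X)  (non-linear, monotone)
* ``nonmonotonic``: f(X) = X**2 (non-linear, U-shaped)

Continuous outcomes follow ``Y = alpha + beta_T*arm + beta_cov*f(X) + eps`` with
Gaussian noise of SD ``sigma_e``.  Binary outcomes arise from the same linear
predictor with standard-logistic noise on a latent scale: the observed response
is ``1{Y* > 0}``, so ``beta_T`` is a conditional log odds ratio and the latent
error SD is ``pi/sqrt(3)``.

Effect sizes are calibrated, not free dials:

* ``beta_cov`` is fixed so that moving from the 10th to the 90th percentile of
  f(X) shifts the outcome by one latent/observed error SD, using the
  closed-form percentiles of f(X) (normal, lognormal(0,1) or chi-square_1).
* ``beta_T`` for continuous outcomes is the two-sample difference in means that
  gives the requested power at the residual SD; for binary outcomes it is found
  by simulation-based bisection against the correctly specified adjusted
  logistic analysis (the binary power calculation has no closed form once the
  covariate effect enters the latent model).
* The binary-outcome intercept is chosen so the marginal control-arm event rate
  is 50%, by quadrature over X.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy import optimize, stats
from scipy.special import expit

__all__ = [
    "SHAPES",
    "SIGMA_LATENT_LOGISTIC",
    "ScenarioSpec",
    "TrialData",
    "CalibrationError",
    "DegenerateTrialError",
    "generate_covariate",
    "transform",
    "quantile_spread",
    "calibrate_beta_cov",
    "calibrate_beta_T_continuous",
    "calibrate_binary_intercept",
    "calibrate_beta_T_binary",
    "simulate_trial",
    "replicate_rng",
    "make_scenario",
]

SHAPES = ("linear", "monotonic", "nonmonotonic")
FAMILIES = ("continuous", "binary")

#: Standard deviation of the standard logistic distribution, the latent error
#: scale of the binary-outcome model.
SIGMA_LATENT_LOGISTIC = math.pi / math.sqrt(3.0)

#: Default trial sizes per outcome family (median sizes of published trials).
DEFAULT_N = {"continuous": 200, "binary": 600}


class CalibrationError(RuntimeError):
    """A calibration root/bisection search failed to bracket its target."""


class DegenerateTrialError(RuntimeError):
    """Trial regeneration exceeded the retry budget."""


@dataclass(frozen=True)
class ScenarioSpec:
    """Complete description of one simulation scenario.

    ``sigma_e`` may be omitted; it defaults to 1 for continuous outcomes and is
    pinned to ``pi/sqrt(3)`` (the latent logistic SD) for binary outcomes.
    """

    outcome_family: str
    shape: str
    n: int
    beta_cov: float
    beta_T: float
    intercept: float = 0.0
    sigma_e: float | None = None
    alpha_level: float = 0.05
    reps: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outcome_family not in FAMILIES:
            raise ValueError(f"unknown outcome_family {self.outcome_family!r}")
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.n < 20:
            raise ValueError("n must be >= 20")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not 0.0 < self.alpha_level < 1.0:
            raise ValueError("alpha_level must lie in (0, 1)")
        if self.sigma_e is None:
            default = 1.0 if self.outcome_family == "continuous" else SIGMA_LATENT_LOGISTIC
            object.__setattr__(self, "sigma_e", default)
        if self.sigma_e <= 0:
            raise ValueError("sigma_e must be positive")
        if self.outcome_family == "binary" and not math.isclose(
            self.sigma_e, SIGMA_LATENT_LOGISTIC, rel_tol=0.0, abs_tol=1e-12
        ):
            raise ValueError(
                "binary outcomes use a standard logistic latent error; "
                f"sigma_e must equal pi/sqrt(3) = {SIGMA_LATENT_LOGISTIC!r}"
            )

    def replace(self, **changes) -> "ScenarioSpec":
        return dataclasses.replace(self, **changes)


@dataclass
class TrialData:
    """One (simulated or loaded) two-arm trial."""

    arm: np.ndarray
    covariate: np.ndarray
    outcome: np.ndarray

    def __post_init__(self) -> None:
        self.arm = np.asarray(self.arm, dtype=float)
        self.covariate = np.asarray(self.covariate, dtype=float)
        self.outcome = np.asarray(self.outcome, dtype=float)
        n = self.arm.shape[0]
        if self.covariate.shape != (n,) or self.outcome.shape != (n,):
            raise ValueError("arm, covariate and outcome must share one length")
        if not np.isin(self.arm, (0.0, 1.0)).all():
            raise ValueError("arm must contain only 0/1")

    @property
    def n(self) -> int:
        return self.arm.shape[0]

    def to_frame(self):
        """One row per patient with header ``id,arm,x,y`` (debug export)."""
        import pandas as pd

        return pd.DataFrame({
            "id": np.arange(self.n),
            "arm": self.arm.astype(int),
            "x": self.covariate,
            "y": self.outcome,
        })


def generate_covariate(n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` i.i.d. standard-normal baseline covariate values."""
    if n < 1:
        raise ValueError("n must be a positive integer")
    return rng.standard_normal(int(n))


def transform(x: np.ndarray, shape: str) -> np.ndarray:
    """Apply the association shape f elementwise: X, exp(X) or X**2."""
    x = np.asarray(x, dtype=float)
    if shape == "linear":
        return x
    if shape == "monotonic":
        return np.exp(x)
    if shape == "nonmonotonic":
        return np.square(x)
    raise ValueError(f"unknown shape {shape!r}")


def quantile_spread(shape: str) -> float:
    """Theoretical 90th-minus-10th percentile spread of f(X) for X ~ N(0,1).

    f(X) is normal (linear), lognormal(0,1) (monotonic) or chi-square with one
    degree of freedom (nonmonotonic); all three spreads are closed form.
    """
    z90 = stats.norm.ppf(0.9)
    if shape == "linear":
        return 2.0 * z90
    if shape == "monotonic":
        return math.exp(z90) - math.exp(-z90)
    if shape == "nonmonotonic":
        return stats.chi2.ppf(0.9, df=1) - stats.chi2.ppf(0.1, df=1)
    raise ValueError(f"unknown shape {shape!r}")


def calibrate_beta_cov(shape: str, sigma_e: float = 1.0) -> float:
    """Covariate effect such that the p10->p90 shift in f(X) equals sigma_e."""
    if sigma_e <= 0:
        raise ValueError("sigma_e must be positive")
    return sigma_e / quantile_spread(shape)


def calibrate_beta_T_continuous(
    n: int, sigma_e: float = 1.0, power: float = 0.8, alpha_level: float = 0.05
) -> float:
    """Two-sample difference in means giving the target power at residual SD sigma_e.

    Standard normal-approximation formula for a 1:1 trial of total size n:
    ``(z_{1-alpha/2} + z_power) * sigma_e * sqrt(4/n)``.
    """
    if not 0.0 < power < 1.0:
        raise ValueError("power must lie in (0, 1)")
    if not 0.0 < alpha_level < 1.0:
        raise ValueError("alpha_level must lie in (0, 1)")
    if n < 2:
        raise ValueError("n must be >= 2")
    if sigma_e <= 0:
        raise ValueError("sigma_e must be positive")
    z = stats.norm.ppf(1.0 - alpha_level / 2.0) + stats.norm.ppf(power)
    return float(z * sigma_e * math.sqrt(4.0 / n))


# 80-point Gauss-Hermite rule: exact enough that the event-rate error from
# quadrature is far below the 1e-6 tolerance for every shape used here.
_GH_NODES, _GH_WEIGHTS = hermegauss(80)
_GH_WEIGHTS = _GH_WEIGHTS / math.sqrt(2.0 * math.pi)


def _marginal_event_rate(alpha: float, beta_cov: float, shape: str) -> float:
    fx = transform(_GH_NODES, shape)
    return float(np.sum(_GH_WEIGHTS * expit(alpha + beta_cov * fx)))


def calibrate_binary_intercept(shape: str, beta_cov: float) -> float:
    """Intercept alpha giving a 50% marginal control-arm event rate.

    Solves ``E_X[expit(alpha + beta_cov f(X))] = 1/2`` by Brent root finding
    with the expectation computed by Gauss-Hermite quadrature over X ~ N(0,1).
    """
    if not math.isfinite(beta_cov):
        raise ValueError("beta_cov must be finite")

    def g(a: float) -> float:
        return _marginal_event_rate(a, beta_cov, shape) - 0.5

    lo, hi = -30.0, 30.0
    if g(lo) > 0 or g(hi) < 0:
        raise CalibrationError(
            f"event-rate equation not bracketed on [{lo}, {hi}] "
            f"(shape={shape}, beta_cov={beta_cov}; g(lo)={g(lo):.3g}, g(hi)={g(hi):.3g})"
        )
    alpha = optimize.brentq(g, lo, hi, xtol=1e-12)
    assert abs(g(alpha)) <= 1e-6
    return float(alpha)


def replicate_rng(seed: int, rep: int) -> np.random.Generator:
    """Independent named stream for one replicate of one scenario.

    Every analysis method within a replicate sees the identical dataset; the
    stream depends only on (seed, rep), so runs are reproducible regardless of
    execution order.
    """
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(int(rep),)))


def simulate_trial(spec: ScenarioSpec, rng: np.random.Generator) -> TrialData:
    """Simulate one trial under ``spec``.

    Simple randomisation: each patient is assigned Bernoulli(0.5).  Degenerate
    draws (an empty arm, or a binary outcome that is all 0 or all 1) are
    regenerated with fresh draws from the same stream; more than 100 attempts
    raises :class:`DegenerateTrialError`.
    """
    n = spec.n
    for _attempt in range(100):
        arm = (rng.random(n) < 0.5).astype(float)
        x = generate_covariate(n, rng)
        linpred = spec.intercept + spec.beta_T * arm + spec.beta_cov * transform(x, spec.shape)
        if spec.outcome_family == "continuous":
            y = linpred + rng.normal(0.0, spec.sigma_e, n)
        else:
            latent = linpred + rng.logistic(0.0, 1.0, n)
            y = (latent > 0.0).astype(float)
        if arm.min() == arm.max():
            continue
        if spec.outcome_family == "binary" and y.min() == y.max():
            continue
        return TrialData(arm=arm, covariate=x, outcome=y)
    raise DegenerateTrialError("could not generate a non-degenerate trial in 100 attempts")


def calibrate_beta_T_binary(
    spec: ScenarioSpec,
    power: float = 0.8,
    reps: int = 10_000,
    rng: np.random.Generator | None = None,
    tol: float = 0.01,
    max_beta: float = 3.0,
) -> float:
    """Conditional log odds ratio at which the correctly specified adjusted
    logistic analysis attains the target power.

    Empirical power at each candidate is estimated from ``reps`` simulated
    trials analysed with the true covariate transform in the model; common
    random numbers across candidates make power monotone in beta_T, and the
    bracket is refined by bisection until the midpoint power is within ``tol``
    of the target.
    """
    from ._engine import logistic_irls  # local import avoids a cycle

    if spec.outcome_family != "binary":
        raise ValueError("binary-outcome calibration requires a binary spec")
    if not 0.0 < power < 1.0:
        raise ValueError("power must lie in (0, 1)")
    if reps < 1000:
        raise ValueError("reps too small for a stable power estimate")
    if rng is None:
        rng = np.random.default_rng(spec.seed)

    n = spec.n
    arm = (rng.random((reps, n)) < 0.5).astype(float)
    x = rng.standard_normal((reps, n))
    eps = rng.logistic(0.0, 1.0, (reps, n))
    fx = transform(x, spec.shape)
    base = spec.intercept + spec.beta_cov * fx + eps
    design = np.empty((reps, n, 3))
    design[:, :, 0] = 1.0
    design[:, :, 1] = arm
    design[:, :, 2] = fx
    zcrit = stats.norm.ppf(1.0 - spec.alpha_level / 2.0)

    def empirical_power(beta_T: float) -> float:
        y = (base + beta_T * arm > 0.0).astype(float)
        ok = (y.min(axis=1) < y.max(axis=1)) & (arm.min(axis=1) < arm.max(axis=1))
        res = logistic_irls(design[ok], y[ok])
        reject = res.converged & (np.abs(res.beta_target / res.se_target) > zcrit)
        return float(reject.sum()) / reps

    lo, p_lo = 0.0, empirical_power(0.0)
    hi = 0.4
    p_hi = empirical_power(hi)
    while p_hi < power:
        lo, p_lo = hi, p_hi
        hi *= 1.5
        if hi > max_beta:
            raise CalibrationError(f"no bracket for target power {power} below beta_T={max_beta}")
        p_hi = empirical_power(hi)

    for _ in range(40):
        mid = 0.5 * (lo + hi)
        p_mid = empirical_power(mid)
        if abs(p_mid - power) <= tol:
            return float(mid)
        if p_mid < power:
            lo = mid
        else:
            hi = mid
    raise CalibrationError("bisection failed to reach the power tolerance")


def make_scenario(
    outcome_family: str,
    shape: str,
    *,
    effect: str = "powered",
    n: int | None = None,
    reps: int = 5000,
    seed: int = 0,
    alpha_level: float = 0.05,
    power: float = 0.8,
    beta_T: float | None = None,
    beta_cov: float | None = None,
    calibration_reps: int = 10_000,
) -> ScenarioSpec:
    """Build a fully calibrated scenario.

    ``effect="null"`` sets beta_T = 0 (type-I-error scenarios); ``"powered"``
    calibrates beta_T for the target power, which for binary outcomes runs the
    simulation-based bisection (seeded from ``seed``) unless ``beta_T`` is
    given explicitly.
    """
    if effect not in ("null", "powered"):
        raise ValueError("effect must be 'null' or 'powered'")
    if n is None:
        n = DEFAULT_N[outcome_family]
    sigma_e = 1.0 if outcome_family == "continuous" else SIGMA_LATENT_LOGISTIC
    if beta_cov is None:
        beta_cov = calibrate_beta_cov(shape, sigma_e)
    intercept = 0.0
    if outcome_family == "binary":
        intercept = calibrate_binary_intercept(shape, beta_cov)
    if effect == "null":
        beta_T = 0.0
    elif beta_T is None:
        if outcome_family == "continuous":
            beta_T = calibrate_beta_T_continuous(n, sigma_e, power, alpha_level)
        else:
            template = ScenarioSpec(
                outcome_family, shape, n, beta_cov, 0.0,
                intercept=intercept, alpha_level=alpha_level, reps=reps, seed=seed,
            )
            beta_T = calibrate_beta_T_binary(
                template, power=power, reps=calibration_reps,
                rng=np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(987,))),
            )
    return ScenarioSpec(
        outcome_family=outcome_family,
        shape=shape,
        n=n,
        beta_cov=float(beta_cov),
        beta_T=float(beta_T),
        intercept=float(intercept),
        alpha_level=alpha_level,
        reps=reps,
        seed=seed,
    )
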