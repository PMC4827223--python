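"""Single-trial adjusted analyses and Wald inference on the treatment effect.

Continuous outcomes are analysed by ordinary least squares with a t-reference
for the treatment coefficient (n - p degrees of freedom); binary outcomes by
maximum-likelihood logistic regression (Newton/IRLS) with a z-reference.  The
covariate enters through one of the seven representations in
:mod:`covadjust.basis`; fractional-polynomial methods additionally select the
power tuple minimising the deviance (RSS for least squares) over the candidate
grid, with the treatment term included in every candidate fit and ties broken
by canonical grid order.

The numerical work happens in the batched kernels of
:mod:`covadjust._engine`; the functions here are the R = 1 entry points, so a
single-trial analysis and a Monte-Carlo replicate are computed by the same
code.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from sklearn.base import BaseEstimator

from . import _engine
from .basis import METHODS, CovariateBasis, build_basis
from .dgm import TrialData

__all__ = [
    "FitResult",
    "FitError",
    "fit_ols",
    "fit_logistic",
    "fit_fp",
    "fit_unadjusted",
    "analyze_all_methods",
    "TreatmentEffectEstimator",
]

logger = logging.getLogger(__name__)


class FitError(RuntimeError):
    """No usable fit could be produced (e.g. every FP candidate failed)."""


@dataclass
class FitResult:
    """Treatment-effect inference from one adjusted analysis."""

    method: str
    beta_T_hat: float
    se: float
    p_value: float
    converged: bool
    selected_powers: tuple[float, ...] = ()
    deviance: float = float("nan")
    n_dropped: int = 0
    error: str | None = None

    def conf_int(self, level: float = 0.95) -> tuple[float, float]:
        from scipy import stats

        z = stats.norm.ppf(0.5 + level / 2.0)
        return (self.beta_T_hat - z * self.se, self.beta_T_hat + z * self.se)


def _stack_design(arm: np.ndarray, columns: np.ndarray | None) -> np.ndarray:
    arm = np.asarray(arm, dtype=float).ravel()
    parts = [np.ones((arm.size, 1)), arm[:, None]]
    if columns is not None and columns.size:
        parts.append(np.atleast_2d(np.asarray(columns, dtype=float)))
    return np.column_stack(parts)


def _drop_collinear(X: np.ndarray) -> tuple[np.ndarray, int]:
    """Drop basis columns until the design has full column rank.

    Uses a pivoted QR; the intercept and treatment columns are never dropped
    (a design where they are collinear is rejected upstream).
    """
    _, R, piv = sla.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank == X.shape[1]:
        return X, 0
    keep = np.sort(piv[:rank])
    if 0 not in keep or 1 not in keep:
        raise FitError("intercept or treatment column is collinear with the basis")
    n_dropped = X.shape[1] - rank
    warnings.warn(
        f"design is rank deficient; dropped {n_dropped} basis column(s)", stacklevel=3
    )
    return X[:, keep], n_dropped


def _basis_columns(basis) -> np.ndarray | None:
    if basis is None:
        return None
    if isinstance(basis, CovariateBasis):
        if basis.meta.get("unselected"):
            raise ValueError(
                "FP basis has no selected powers; use fit_fp for fractional polynomials"
            )
        return basis.columns
    return np.atleast_2d(np.asarray(basis, dtype=float))


def fit_ols(y, arm, basis=None) -> FitResult:
    """Least-squares adjusted analysis; Wald t-test on the treatment column."""
    y = np.asarray(y, dtype=float).ravel()
    X = _stack_design(arm, _basis_columns(basis))
    if not np.isfinite(X).all() or not np.isfinite(y).all():
        raise ValueError("design or outcome contains non-finite values")
    if X[:, 1].min() == X[:, 1].max():
        raise ValueError("both arms must be represented")
    X, n_dropped = _drop_collinear(X)
    res = _engine.ols(X[None], y[None])
    method = basis.method if isinstance(basis, CovariateBasis) else "unadjusted"
    return FitResult(
        method=method,
        beta_T_hat=float(res.beta_target[0]),
        se=float(res.se_target[0]),
        p_value=float(res.p_value[0]),
        converged=True,
        deviance=float(res.deviance[0]),
        n_dropped=n_dropped,
    )


def fit_logistic(y, arm, basis=None) -> FitResult:
    """Maximum-likelihood logistic analysis; Wald z-test on the treatment column.

    Separation or non-convergence yields ``converged=False`` with the last
    iterate rather than an exception; downstream summaries count such
    replicates as non-rejections and exclude them from bias averages.
    """
    y = np.asarray(y, dtype=float).ravel()
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("binary outcome must contain only 0/1")
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    X = _stack_design(arm, _basis_columns(basis))
    if X[:, 1].min() == X[:, 1].max():
        raise ValueError("both arms must be represented")
    X, n_dropped = _drop_collinear(X)
    res = _engine.logistic_irls(X[None], y[None])
    method = basis.method if isinstance(basis, CovariateBasis) else "unadjusted"
    return FitResult(
        method=method,
        beta_T_hat=float(res.beta_target[0]),
        se=float(res.se_target[0]),
        p_value=float(res.p_value[0]),
        converged=bool(res.converged[0]),
        deviance=float(res.deviance[0]),
        n_dropped=n_dropped,
    )


def fit_unadjusted(y, arm, family: str) -> FitResult:
    if family == "continuous":
        return fit_ols(y, arm, None)
    return fit_logistic(y, arm, None)


def fit_fp(y, arm, x, order: int, family: str) -> FitResult:
    """Fractional-polynomial analysis with deviance-minimising power selection.

    Every candidate model contains the intercept, the treatment term and the
    candidate FP columns of the shifted covariate; the fit with the smallest
    deviance wins, candidates that fail to converge are skipped (logged), and
    if all candidates fail a :class:`FitError` is raised.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    y = np.asarray(y, dtype=float).ravel()
    arm = np.asarray(arm, dtype=float).ravel()
    x = np.asarray(x, dtype=float).ravel()
    res, sel = _engine._fp_batch(arm[None], x[None], y[None], family, order)
    n_failed = int(res.n_candidate_failures[0])
    if n_failed:
        logger.info("fp order %d: %d candidate fit(s) failed to converge", order, n_failed)
    if not res.converged[0] and not np.isfinite(res.deviance[0]):
        raise FitError(f"all FP{order} candidate fits failed to converge")
    powers = tuple(float(p) for p in sel[0] if np.isfinite(p))
    return FitResult(
        method=f"fp{order}",
        beta_T_hat=float(res.beta_target[0]),
        se=float(res.se_target[0]),
        p_value=float(res.p_value[0]),
        converged=bool(res.converged[0]),
        selected_powers=powers,
        deviance=float(res.deviance[0]),
    )


def analyze_all_methods(trial: TrialData, family: str) -> list[FitResult]:
    """All seven adjusted analyses on one trial; per-method failures are
    returned as flagged results, never raised."""
    results = []
    for method in METHODS:
        try:
            if method in ("fp1", "fp2"):
                res = fit_fp(
                    trial.outcome, trial.arm, trial.covariate,
                    order=1 if method == "fp1" else 2, family=family,
                )
            else:
                b = build_basis(trial.covariate, method)
                if family == "continuous":
                    res = fit_ols(trial.outcome, trial.arm, b)
                else:
                    res = fit_logistic(trial.outcome, trial.arm, b)
        except Exception as exc:  # noqa: BLE001 - contract: flag, don't abort
            res = FitResult(
                method=method, beta_T_hat=float("nan"), se=float("nan"),
                p_value=float("nan"), converged=False, error=str(exc),
            )
        results.append(res)
    return results


class TreatmentEffectEstimator(BaseEstimator):
    """Scikit-learn estimator facade for one adjusted treatment-effect analysis.

    Parameters
    ----------
    method : one of the seven adjustment methods, or "unadjusted".
    family : "continuous" (least squares) or "binary" (logistic).

    ``fit(X, y)`` expects ``X`` with two columns, ``[arm, covariate]`` (or a
    DataFrame with those columns first).  Fitted attributes: ``effect_``
    (difference in means / conditional log odds ratio), ``se_``, ``p_value_``,
    ``converged_``, ``selected_powers_`` and the full :class:`FitResult` in
    ``result_``.
    """

    def __init__(self, method: str = "linear", family: str = "continuous"):
        self.method = method
        self.family = family

    def fit(self, X, y):
        if self.method not in METHODS + ("unadjusted",):
            raise ValueError(f"unknown method {self.method!r}")
        if self.family not in ("continuous", "binary"):
            raise ValueError(f"unknown family {self.family!r}")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must have two columns: [arm, covariate]")
        y = np.asarray(y, dtype=float).ravel()
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y length mismatch")
        arm, cov = X[:, 0], X[:, 1]
        if self.method == "unadjusted":
            result = fit_unadjusted(y, arm, self.family)
        elif self.method in ("fp1", "fp2"):
            result = fit_fp(y, arm, cov, 1 if self.method == "fp1" else 2, self.family)
        else:
            b = build_basis(cov, self.method)
            result = (
                fit_ols(y, arm, b) if self.family == "continuous" else fit_logistic(y, arm, b)
            )
        self.n_features_in_ = 2
        self.result_ = result
        self.effect_ = result.beta_T_hat
        self.se_ = result.se
        self.p_value_ = result.p_value
        self.converged_ = result.converged
        self.selected_powers_ = result.selected_powers
        return self

    def conf_int(self, level: float = 0.95) -> tuple[float, float]:
        from sklearn.exceptions import NotFittedError

        if not hasattr(self, "result_"):
            raise NotFittedError("call fit first")
        return self.result_.conf_int(level)
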