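"""Vectorised fitting kernels and the batched per-replicate analysis engine.

The Monte-Carlo study needs hundreds of thousands of small regressions (an FP2
analysis alone fits 36 candidate models per trial).  The kernels here fit R
trials at once on stacked design arrays of shape (R, n, p); the single-trial
fitting functions in :mod:`covadjust.fit` call the same kernels with R = 1, so
the scalar and batched code paths are one implementation.

Non-intercept columns are standardised internally before solving — FP powers
such as x**-2 applied after the minimum-gap positivity shift produce columns
spanning many orders of magnitude, and raw normal equations would lose
precision — and estimates/standard errors are mapped back to the original
scale.  Standardisation changes neither the fitted model nor the deviance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import expit

from . import basis as _basis
from .dgm import ScenarioSpec, replicate_rng, simulate_trial

__all__ = ["BatchFit", "ols", "logistic_irls", "simulate_batch", "analyze_batch"]

#: Column index of the treatment indicator in every design built here
#: (0 = intercept, 1 = arm, 2.. = covariate basis).
ARM_COL = 1


@dataclass
class BatchFit:
    """Per-replicate results of one batched fit (arrays of length R)."""

    beta_target: np.ndarray      # treatment coefficient, original scale
    se_target: np.ndarray        # its standard error
    p_value: np.ndarray          # two-sided Wald p
    deviance: np.ndarray         # RSS (OLS) or -2 log-likelihood (logistic)
    converged: np.ndarray        # bool
    beta_full: np.ndarray        # (R, p) all coefficients, original scale
    n_iter: np.ndarray | None = None
    selected_powers: np.ndarray | None = None  # (R, 2) FP powers, NaN-padded
    n_candidate_failures: np.ndarray | None = None  # per-rep failed FP candidates


def _standardise(X: np.ndarray):
    """Centre/scale non-intercept columns; returns (Xs, centre, scale)."""
    centre = X.mean(axis=1)
    scale = X.std(axis=1)
    centre[:, 0] = 0.0
    scale[:, 0] = 1.0
    scale[scale == 0.0] = 1.0  # constant columns pass through (flagged later)
    Xs = (X - centre[:, None, :]) / scale[:, None, :]
    return Xs, centre, scale


def _unscale(beta_s, cov_diag_s, centre, scale):
    """Map standardised-scale coefficients and variances back."""
    beta = beta_s / scale
    beta[:, 0] = beta_s[:, 0] - np.einsum("rp,rp->r", beta_s[:, 1:] / scale[:, 1:], centre[:, 1:])
    se = np.sqrt(np.maximum(cov_diag_s, 0.0)) / scale
    return beta, se


def _solve_batch(H: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Batched solve with a per-row least-squares fallback for singular rows."""
    try:
        return np.linalg.solve(H, g[..., None])[..., 0]
    except np.linalg.LinAlgError:
        out = np.empty_like(g)
        for i in range(H.shape[0]):
            try:
                out[i] = np.linalg.solve(H[i], g[i])
            except np.linalg.LinAlgError:
                out[i] = np.linalg.lstsq(H[i], g[i], rcond=None)[0]
        return out


def _inv_diag(H: np.ndarray) -> np.ndarray:
    """Diagonal of inv(H) per batch row, with a pinv fallback."""
    try:
        inv = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        inv = np.stack([np.linalg.pinv(h) for h in H])
    return np.einsum("...ii->...i", inv)


def ols(X: np.ndarray, y: np.ndarray, target: int = ARM_COL) -> BatchFit:
    """Batched ordinary least squares with a t-test on the target column.

    X : (R, n, p) stacked designs whose column 0 is the intercept.
    y : (R, n).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    R, n, p = X.shape
    Xs, centre, scale = _standardise(X)
    XtX = np.matmul(Xs.transpose(0, 2, 1), Xs)
    Xty = np.einsum("rnp,rn->rp", Xs, y)
    beta_s = _solve_batch(XtX, Xty)
    resid = y - np.einsum("rnp,rp->rn", Xs, beta_s)
    rss = np.einsum("rn,rn->r", resid, resid)
    df = n - p
    sigma2 = rss / df
    cov_diag = sigma2[:, None] * _inv_diag(XtX)
    beta, se = _unscale(beta_s, cov_diag, centre, scale)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta[:, target] / se[:, target]
    pval = 2.0 * stats.t.sf(np.abs(tstat), df)
    return BatchFit(
        beta_target=beta[:, target],
        se_target=se[:, target],
        p_value=pval,
        deviance=rss,
        converged=np.ones(R, dtype=bool),
        beta_full=beta,
    )


def _neg2ll(eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    # -2 sum [ y*eta - log(1 + e^eta) ]; log1pexp(x) = max(x,0) + log1p(e^-|x|)
    out = np.maximum(eta, 0.0)
    out += np.log1p(np.exp(-np.abs(eta)))
    out -= y * eta
    return 2.0 * out.sum(axis=-1)


def _newton_fast(Xs, y, max_iter, score_tol):
    """Plain Newton with score-based convergence; no deviance guard.

    Fast path for the overwhelming majority of replicates; rows that have not
    converged when it returns (overshoot, quasi-separation) are re-fit by the
    guarded variant.
    """
    R, n, p = Xs.shape
    beta = np.zeros((R, p))
    converged = np.zeros(R, dtype=bool)
    active = np.arange(R)
    Xa, ya, beta_a = Xs, y, beta.copy()
    with np.errstate(all="ignore"):
        for _ in range(max_iter):
            eta = np.matmul(Xa, beta_a[:, :, None])[:, :, 0]
            mu = expit(eta)
            score = np.matmul(Xa.transpose(0, 2, 1), (ya - mu)[:, :, None])[:, :, 0]
            done = np.abs(score).max(axis=1) <= score_tol
            if done.any():
                converged[active[done]] = True
                beta[active[done]] = beta_a[done]
                keep = ~done
                active = active[keep]
                if active.size == 0:
                    return beta, converged
                Xa, ya, beta_a, score = Xa[keep], ya[keep], beta_a[keep], score[keep]
                mu = mu[keep]
            w = mu * (1.0 - mu)
            H = np.matmul(Xa.transpose(0, 2, 1), Xa * w[:, :, None])
            beta_a = beta_a + _solve_batch(H, score)
    beta[active] = beta_a
    return beta, converged


def _newton_guarded(Xs, y, max_iter, score_tol, dev_tol):
    """Newton/IRLS with deviance-monotone step halving (robust slow path)."""
    R, n, p = Xs.shape
    beta = np.zeros((R, p))
    dev = _neg2ll(np.zeros((R, n)), y)
    converged = np.zeros(R, dtype=bool)
    active = np.arange(R)
    Xa, ya, beta_a, dev_a = Xs, y, beta.copy(), dev.copy()
    for _ in range(max_iter):
        eta = np.matmul(Xa, beta_a[:, :, None])[:, :, 0]
        mu = expit(eta)
        w = mu * (1.0 - mu)
        score = np.matmul(Xa.transpose(0, 2, 1), (ya - mu)[:, :, None])[:, :, 0]
        H = np.matmul(Xa.transpose(0, 2, 1), Xa * w[:, :, None])
        with np.errstate(all="ignore"):
            step = _solve_batch(H, score)
        step[~np.isfinite(step)] = 0.0
        new_beta = beta_a + step
        new_dev = _neg2ll(np.matmul(Xa, new_beta[:, :, None])[:, :, 0], ya)
        for _half in range(25):
            worse = ~(new_dev <= dev_a + 1e-10)  # catches NaN too
            if not worse.any():
                break
            step[worse] *= 0.5
            new_beta[worse] = beta_a[worse] + step[worse]
            new_dev[worse] = _neg2ll(
                np.matmul(Xa[worse], new_beta[worse][:, :, None])[:, :, 0], ya[worse]
            )
        done = (np.abs(score).max(axis=1) <= score_tol) | (
            np.abs(dev_a - new_dev) <= dev_tol * np.maximum(np.abs(new_dev), 1.0)
        )
        beta_a, dev_a = new_beta, new_dev
        beta[active], dev[active] = beta_a, dev_a
        if done.any():
            converged[active[done]] = True
            keep = ~done
            active = active[keep]
            if active.size == 0:
                break
            Xa, ya, beta_a, dev_a = Xa[keep], ya[keep], beta_a[keep], dev_a[keep]
    return beta, converged


def logistic_irls(
    X: np.ndarray,
    y: np.ndarray,
    target: int = ARM_COL,
    max_iter: int = 100,
    score_tol: float = 1e-8,
    dev_tol: float = 1e-10,
) -> BatchFit:
    """Batched logistic maximum likelihood by Newton-Raphson (IRLS).

    Convergence per replicate: max |score| <= ``score_tol`` (standardised
    columns) or relative deviance change <= ``dev_tol``, within ``max_iter``
    iterations.  A plain-Newton fast path handles well-behaved replicates;
    rows still unconverged after 30 iterations are re-fit with
    deviance-monotone step halving, and rows unconverged at the cap (or with
    a separated/saturated solution) are flagged, not raised.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    R, n, p = X.shape
    Xs, centre, scale = _standardise(X)

    beta, converged = _newton_fast(Xs, y, min(30, max_iter), score_tol)
    bad = ~converged
    if bad.any():
        beta_g, conv_g = _newton_guarded(Xs[bad], y[bad], max_iter, score_tol, dev_tol)
        beta[bad] = beta_g
        converged[bad] = conv_g

    with np.errstate(all="ignore"):
        eta = np.matmul(Xs, beta[:, :, None])[:, :, 0]
        dev = _neg2ll(eta, y)
        mu = expit(eta)
        w = mu * (1.0 - mu)
        H = np.matmul(Xs.transpose(0, 2, 1), Xs * w[:, :, None])
        cov_diag = _inv_diag(H)
        beta_o, se = _unscale(beta, cov_diag, centre, scale)
    # complete separation drives the deviance to zero (a perfect fit, which a
    # noisy logistic model cannot legitimately achieve) and the MLE to
    # infinity; flag it, together with diverging coefficients and broken SEs
    converged &= dev > 1e-6
    converged &= np.abs(beta).max(axis=1) < 1e3
    ok = np.isfinite(se[:, target]) & (se[:, target] > 0)
    converged &= ok
    z = np.divide(
        beta_o[:, target], se[:, target],
        out=np.zeros(R), where=ok,
    )
    pval = np.where(ok, 2.0 * stats.norm.sf(np.abs(z)), np.nan)
    return BatchFit(
        beta_target=beta_o[:, target],
        se_target=se[:, target],
        p_value=pval,
        deviance=dev,
        converged=converged,
        beta_full=beta_o,
    )


# --------------------------------------------------------------------------
# batched trial generation and basis construction


def simulate_batch(spec: ScenarioSpec, reps: int | None = None):
    """Stack ``reps`` simulated trials into (R, n) arrays.

    Each replicate uses its own named stream (``replicate_rng(spec.seed, rep)``)
    via the scalar :func:`covadjust.dgm.simulate_trial`, so the batched study
    sees bit-identical data to a replicate-by-replicate loop.
    """
    reps = spec.reps if reps is None else reps
    arm = np.empty((reps, spec.n))
    x = np.empty((reps, spec.n))
    y = np.empty((reps, spec.n))
    for rep in range(reps):
        trial = simulate_trial(spec, replicate_rng(spec.seed, rep))
        arm[rep] = trial.arm
        x[rep] = trial.covariate
        y[rep] = trial.outcome
    return arm, x, y


def _design(arm: np.ndarray, cols: np.ndarray) -> np.ndarray:
    R, n = arm.shape
    d = cols.shape[-1] if cols.ndim == 3 else 0
    X = np.empty((R, n, 2 + d))
    X[:, :, 0] = 1.0
    X[:, :, 1] = arm
    if d:
        X[:, :, 2:] = cols
    return X


def _basis_cols_batch(x: np.ndarray, method: str) -> np.ndarray:
    """(R, n, d) basis columns for one non-FP method, all replicates at once.

    Mirrors the scalar builders in :mod:`covadjust.basis` exactly: same
    percentile rule (numpy linear interpolation), same strict-``>`` cutpoint
    convention, same knot percentiles.
    """
    if method == "dichotomised":
        med = np.median(x, axis=1, keepdims=True)
        return (x > med).astype(float)[:, :, None]
    if method == "categorised":
        q = np.quantile(x, [0.25, 0.50, 0.75], axis=1)
        q25, q50, q75 = (qq[:, None] for qq in q)
        return np.stack(
            [(x > q25) & (x <= q50), (x > q50) & (x <= q75), x > q75], axis=-1
        ).astype(float)
    if method == "linear":
        return x[:, :, None]
    if method in ("rcs3", "rcs5"):
        pct = np.asarray(_basis.HARRELL_PERCENTILES[3 if method == "rcs3" else 5]) / 100.0
        knots = np.quantile(x, pct, axis=1).T  # (R, K)
        return _basis.rcs_columns(x, knots)
    raise ValueError(f"unknown fixed-basis method {method!r}")


def _fp_shift_batch(x: np.ndarray) -> np.ndarray:
    """Per-replicate positivity shift (Royston–Sauerbrei minimum-gap rule)."""
    xs = np.sort(x, axis=1)
    gaps = np.diff(xs, axis=1)
    gaps = np.where(gaps > 0, gaps, np.inf)
    delta = gaps.min(axis=1)
    if not np.isfinite(delta).all():
        raise ValueError("constant covariate in at least one replicate")
    mn = x.min(axis=1)
    return np.where(mn > 0, 0.0, -mn + delta)


def _fit_family(X, y, family):
    return ols(X, y) if family == "continuous" else logistic_irls(X, y)


def _fp_batch(arm, x, y, family, order) -> tuple[BatchFit, np.ndarray]:
    """FP analysis for all replicates: fit every candidate, keep min deviance.

    Candidates that fail to converge are excluded from selection (deviance set
    to +inf); a replicate where every candidate fails is flagged unconverged.
    Ties break to the first candidate in canonical grid order via argmin.
    """
    R = arm.shape[0]
    shift = _fp_shift_batch(x)
    xs = x + shift[:, None]
    candidates = _basis.fp_candidates(order)
    C = len(candidates)
    beta = np.empty((R, C))
    se = np.empty((R, C))
    pval = np.empty((R, C))
    dev = np.empty((R, C))
    conv = np.empty((R, C), dtype=bool)
    for j, powers in enumerate(candidates):
        cols = _basis.fp_columns(xs, powers)
        res = _fit_family(_design(arm, cols), y, family)
        beta[:, j] = res.beta_target
        se[:, j] = res.se_target
        pval[:, j] = res.p_value
        conv[:, j] = res.converged
        dev[:, j] = np.where(res.converged, res.deviance, np.inf)
    sel = np.argmin(dev, axis=1)
    rows = np.arange(R)
    any_ok = conv.any(axis=1)
    powers_arr = np.array([c + (np.nan,) * (2 - len(c)) for c in candidates])
    out = BatchFit(
        beta_target=beta[rows, sel],
        se_target=se[rows, sel],
        p_value=pval[rows, sel],
        deviance=dev[rows, sel],
        converged=any_ok & conv[rows, sel],
        beta_full=np.empty((R, 0)),
        n_candidate_failures=(~conv).sum(axis=1),
    )
    return out, powers_arr[sel]


def analyze_batch(
    arm: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    family: str,
    methods=_basis.METHODS,
) -> dict[str, BatchFit]:
    """Run the requested adjustment methods on identical stacked trial data.

    Returns one :class:`BatchFit` per method; FP results additionally carry the
    selected powers in ``fit.selected_powers`` (an (R, 2) array, NaN-padded for
    FP1).
    """
    results: dict[str, BatchFit] = {}
    for method in methods:
        if method in ("fp1", "fp2"):
            res, sel = _fp_batch(arm, x, y, family, 1 if method == "fp1" else 2)
            res.selected_powers = sel
        else:
            cols = _basis_cols_batch(x, method)
            res = _fit_family(_design(arm, cols), y, family)
            res.selected_powers = None
        results[method] = res
    return results
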