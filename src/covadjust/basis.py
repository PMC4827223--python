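"""The seven covariate representations used in the adjusted analyses.

Each representation maps a continuous baseline covariate to the design-matrix
columns entered alongside the intercept and the treatment indicator:

* ``dichotomised`` — indicator of exceeding the sample median (1 column)
* ``categorised`` — quartile-group indicators, lowest quartile reference (3)
* ``linear`` — the covariate itself (1)
* ``fp1`` / ``fp2`` — fractional polynomials with 1 or 2 power terms drawn
  from {-2, -1, -0.5, 0, 0.5, 1, 2, 3}, p=0 meaning log; a repeated pair
  (p, p) means x**p and x**p*log(x) (1 or 2 columns)
* ``rcs3`` / ``rcs5`` — restricted cubic splines with 3 or 5 knots at
  Harrell's percentiles: the linear term plus one truncated-cubic term per
  interior knot, constrained to be linear beyond the boundary knots (2 or 4)

The primitives are exposed both as plain functions returning a
:class:`CovariateBasis` and as scikit-learn transformers (fit learns the
sample-dependent pieces — cutpoints, knots, FP shift — transform emits the
columns), so the representations compose with sklearn pipelines.

All sample percentiles (median, quartile cutpoints, knot locations) use linear
interpolation between order statistics (numpy's default, the "type 7" rule).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "METHODS",
    "FP_POWER_GRID",
    "CovariateBasis",
    "dichotomise",
    "categorise",
    "fp_shift",
    "fp_candidates",
    "fp_basis",
    "rcs_knots",
    "rcs_basis",
    "build_basis",
    "MedianSplit",
    "QuartileIndicators",
    "FractionalPolynomialFeatures",
    "RestrictedCubicSplineFeatures",
]

#: Canonical method names, in the order the study reports them.
METHODS = ("dichotomised", "categorised", "linear", "fp1", "fp2", "rcs3", "rcs5")

#: The conventional fractional-polynomial power grid.
FP_POWER_GRID = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)

#: Harrell's recommended knot percentiles, keyed by total knot count
#: (boundary knots included).
HARRELL_PERCENTILES = {3: (10.0, 50.0, 90.0), 5: (5.0, 27.5, 50.0, 72.5, 95.0)}


@dataclass
class CovariateBasis:
    """Design-matrix columns for one covariate representation.

    ``columns`` excludes the intercept and the treatment indicator; ``meta``
    carries the method-specific parameters (cutpoints, powers, knots and their
    lambda weights), and ``shift`` the additive constant applied before FP
    transforms.
    """

    method: str
    columns: np.ndarray
    meta: dict = field(default_factory=dict)
    shift: float = 0.0

    def __post_init__(self) -> None:
        self.columns = np.atleast_2d(np.asarray(self.columns, dtype=float))
        if self.columns.ndim != 2:
            raise ValueError("columns must be a 2-D array")

    @property
    def n_columns(self) -> int:
        return self.columns.shape[1]


def _as_vector(x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if not np.isfinite(x).all():
        raise ValueError("covariate contains non-finite values")
    return x


def dichotomise(x) -> CovariateBasis:
    """Indicator of exceeding the sample median (strict ``>``)."""
    x = _as_vector(x)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    med = float(np.median(x))
    col = (x > med).astype(float)
    if x.min() == x.max():
        warnings.warn("constant covariate: dichotomised column is all zero", stacklevel=2)
    return CovariateBasis("dichotomised", col[:, None], meta={"cutpoints": (med,)})


def categorise(x) -> CovariateBasis:
    """Quartile-group indicators with the lowest quartile as reference.

    Groups are the half-open intervals (q25, q50], (q50, q75], (q75, inf),
    membership decided by strict ``>`` against the lower cutpoint.
    """
    x = _as_vector(x)
    if x.size < 8:
        raise ValueError("need at least 8 observations to categorise into quartiles")
    q25, q50, q75 = (float(q) for q in np.quantile(x, [0.25, 0.50, 0.75]))
    if not q25 < q50 < q75:
        raise ValueError(
            f"tied quartile cutpoints (q25={q25}, q50={q50}, q75={q75}): "
            "some categories would be empty"
        )
    cols = np.column_stack([
        (x > q25) & (x <= q50),
        (x > q50) & (x <= q75),
        x > q75,
    ]).astype(float)
    return CovariateBasis("categorised", cols, meta={"cutpoints": (q25, q50, q75)})


def fp_shift(x) -> tuple[np.ndarray, float]:
    """Shift a covariate to strict positivity for fractional polynomials.

    If min(x) > 0 no shift is applied; otherwise the shift is
    ``-min(x) + delta`` with ``delta`` the smallest positive gap between
    adjacent sorted distinct values (the Royston–Sauerbrei convention).
    """
    x = _as_vector(x)
    if x.size < 2 or x.min() == x.max():
        raise ValueError("need a non-constant covariate of length >= 2")
    mn = float(x.min())
    if mn > 0:
        return x, 0.0
    gaps = np.diff(np.sort(x))
    gaps = gaps[gaps > 0]
    delta = float(gaps.min())
    shift = -mn + delta
    # guard against delta vanishing in the addition when it is far below the
    # float resolution at |min(x)|
    while (x + shift).min() <= 0:
        shift = float(np.nextafter(shift, np.inf))
    return x + shift, shift


def fp_candidates(order: int) -> list[tuple[float, ...]]:
    """Candidate power tuples: 8 singletons (order 1) or 36 pairs (order 2).

    Order-2 candidates are the unordered pairs p1 <= p2 from the grid,
    repeated pairs included, enumerated in lexicographic order — the canonical
    order used for deterministic tie-breaking during selection.
    """
    if order == 1:
        return [(p,) for p in FP_POWER_GRID]
    if order == 2:
        return list(itertools.combinations_with_replacement(FP_POWER_GRID, 2))
    raise ValueError("order must be 1 or 2")


def _fp_term(x: np.ndarray, p: float) -> np.ndarray:
    # x must already be strictly positive
    if p == 0.0:
        return np.log(x)
    return np.power(x, p)


def fp_columns(x_shifted: np.ndarray, powers: tuple[float, ...]) -> np.ndarray:
    """Fractional-polynomial columns for already-positive input.

    Works elementwise on arrays of any shape (columns are stacked on a new
    trailing axis), which lets the batched simulation engine reuse it.
    """
    x = np.asarray(x_shifted, dtype=float)
    if np.any(x <= 0):
        raise ValueError("fractional polynomials need strictly positive input; shift first")
    if len(powers) == 2 and powers[0] == powers[1]:
        first = _fp_term(x, powers[0])
        cols = [first, first * np.log(x)]
    else:
        cols = [_fp_term(x, p) for p in powers]
    return np.stack(cols, axis=-1)


def fp_basis(x_shifted, powers: tuple[float, ...]) -> CovariateBasis:
    x = _as_vector(x_shifted)
    cols = fp_columns(x, tuple(powers))
    method = "fp1" if len(powers) == 1 else "fp2"
    return CovariateBasis(method, cols, meta={"powers": tuple(powers)})


def rcs_knots(x, total_knots: int) -> np.ndarray:
    """Knot locations at Harrell's percentiles (boundary knots included)."""
    x = _as_vector(x)
    if x.size < 20:
        raise ValueError("need at least 20 observations to place spline knots")
    try:
        pct = HARRELL_PERCENTILES[int(total_knots)]
    except (KeyError, TypeError):
        raise ValueError("total_knots must be 3 or 5") from None
    knots = np.quantile(x, np.asarray(pct) / 100.0)
    if not np.all(np.diff(knots) > 0):
        raise ValueError(f"non-distinct knots {knots.tolist()}")
    return knots


def rcs_columns(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted-cubic-spline columns ``[x, nl_1(x), ..., nl_m(x)]``.

    With boundary knots k_min < k_1 < ... < k_m < k_max and
    ``lambda_j = (k_max - k_j) / (k_max - k_min)``, each nonlinear term is

        nl_j(x) = (x - k_j)+^3 - lambda_j (x - k_min)+^3
                  - (1 - lambda_j) (x - k_max)+^3

    where ``(u)+^3`` is the truncated cube.  The cubic and quadratic parts of
    the three truncated cubes cancel beyond k_max, so every column is linear
    outside the boundary knots, and each column is C^2 at every knot.

    Broadcasts over leading axes: ``x`` of shape (..., n) with ``knots`` of
    shape (..., K) yields (..., n, 1 + (K - 2)).
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    if knots.shape[-1] < 3:
        raise ValueError("need at least 3 knots (one interior)")
    if not np.all(np.diff(knots, axis=-1) > 0):
        raise ValueError("knots must be strictly increasing")
    if not np.isfinite(x).all():
        raise ValueError("covariate contains non-finite values")
    kmin = knots[..., :1]
    kmax = knots[..., -1:]
    kint = knots[..., 1:-1]
    lam = (kmax - kint) / (kmax - kmin)  # (..., m), each in (0, 1)
    xe = x[..., None]

    def tcube(k):
        return np.maximum(xe - k[..., None, :], 0.0) ** 3

    nl = tcube(kint) - lam[..., None, :] * tcube(kmin) - (1.0 - lam[..., None, :]) * tcube(kmax)
    return np.concatenate([xe, nl], axis=-1)


def rcs_basis(x, knots) -> CovariateBasis:
    x = _as_vector(x)
    knots = np.asarray(knots, dtype=float).ravel()
    cols = rcs_columns(x, knots)
    lam = (knots[-1] - knots[1:-1]) / (knots[-1] - knots[0])
    method = "rcs3" if knots.size == 3 else "rcs5" if knots.size == 5 else "rcs"
    return CovariateBasis(method, cols, meta={"knots": tuple(knots), "lambdas": tuple(lam)})


def build_basis(x, method: str) -> CovariateBasis:
    """Build the fixed (non-FP-selected) basis for one method name.

    FP methods return the shifted covariate wrapped with the candidate grid in
    ``meta`` — power selection is part of model fitting, not basis building.
    """
    x = _as_vector(x)
    if method == "dichotomised":
        return dichotomise(x)
    if method == "categorised":
        return categorise(x)
    if method == "linear":
        return CovariateBasis("linear", x[:, None])
    if method in ("fp1", "fp2"):
        shifted, shift = fp_shift(x)
        order = 1 if method == "fp1" else 2
        return CovariateBasis(
            method, shifted[:, None], shift=shift,
            meta={"candidates": fp_candidates(order), "unselected": True},
        )
    if method in ("rcs3", "rcs5"):
        return rcs_basis(x, rcs_knots(x, 3 if method == "rcs3" else 5))
    raise ValueError(f"unknown method {method!r}")


# --------------------------------------------------------------------------
# scikit-learn transformer facades


class _SingleColumnTransformer(TransformerMixin, BaseEstimator):
    """Shared input handling: accepts a 1-D vector or an (n, 1) array."""

    def _extract(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("expected a single covariate column")
            X = X[:, 0]
        elif X.ndim != 1:
            raise ValueError("expected a 1-D vector or an (n, 1) array")
        self.n_features_in_ = 1
        return X

    def _check_fitted(self):
        from sklearn.exceptions import NotFittedError

        if not hasattr(self, "_fitted_") or not self._fitted_:
            raise NotFittedError(f"{type(self).__name__} is not fitted")


class MedianSplit(_SingleColumnTransformer):
    """Median dichotomisation; ``cutpoint_`` is learned from the training data."""

    def fit(self, X, y=None):
        x = self._extract(X)
        self.cutpoint_ = float(np.median(x))
        self._fitted_ = True
        return self

    def transform(self, X):
        self._check_fitted()
        x = self._extract(X)
        return (x > self.cutpoint_).astype(float)[:, None]


class QuartileIndicators(_SingleColumnTransformer):
    """Quartile-group indicator columns, lowest quartile as reference."""

    def fit(self, X, y=None):
        x = self._extract(X)
        basis = categorise(x)
        self.cutpoints_ = np.asarray(basis.meta["cutpoints"])
        self._fitted_ = True
        return self

    def transform(self, X):
        self._check_fitted()
        x = self._extract(X)
        q25, q50, q75 = self.cutpoints_
        return np.column_stack([
            (x > q25) & (x <= q50),
            (x > q50) & (x <= q75),
            x > q75,
        ]).astype(float)


class FractionalPolynomialFeatures(_SingleColumnTransformer):
    """FP columns for fixed powers; the positivity shift is learned in fit."""

    def __init__(self, powers=(1.0,)):
        self.powers = powers

    def fit(self, X, y=None):
        x = self._extract(X)
        _, self.shift_ = fp_shift(x)
        self._fitted_ = True
        return self

    def transform(self, X):
        self._check_fitted()
        x = self._extract(X) + self.shift_
        return fp_columns(x, tuple(self.powers))


class RestrictedCubicSplineFeatures(_SingleColumnTransformer):
    """RCS columns with knots at Harrell's percentiles of the training data."""

    def __init__(self, n_knots=3):
        self.n_knots = n_knots

    def fit(self, X, y=None):
        x = self._extract(X)
        self.knots_ = rcs_knots(x, self.n_knots)
        self.lambdas_ = (self.knots_[-1] - self.knots_[1:-1]) / (self.knots_[-1] - self.knots_[0])
        self._fitted_ = True
        return self

    def transform(self, X):
        self._check_fitted()
        x = self._extract(X)
        return rcs_columns(x, self.knots_)
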