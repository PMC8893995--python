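"""Possibilistic fuzzy linear regression with triangular fuzzy coefficients.

The model is the Tanaka family: each regression coefficient is a
triangular fuzzy number A_j = (a_j, c_j) with center a_j and spread
c_j >= 0, and the fuzzy response is

    Y(x) = A_0 + A_1 x_1 + ... + A_n x_n .

Fitting minimises the data-weighted total spread

    sum_j c_j * sum_i |x_ij|          (symmetric spreads)
    sum_j (c_j^L + c_j^R)/2 * sum_i |x_ij|   (asymmetric spreads)

subject to the h-level coverage constraints for every observation i:

    sum_j a_j x_ij + (1-h) sum_j c_j^R |x_ij| >= y_i
    sum_j a_j x_ij - (1-h) sum_j c_j^L |x_ij| <= y_i

so that at h = 0 the support band [center - left, center + right]
contains every training observation.  The optimisation is a linear
program: centers are free, spreads non-negative.  Larger h tightens the
constraints and can only widen the fitted band.

The fitted model is summarised as three crisp equations: the central
tendency (coefficient centers), the lower boundary (centers minus left
spreads) and the upper boundary (centers plus right spreads).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .data import ConfigurationError, DesignMatrix, EmptyDataError

logger = logging.getLogger(__name__)

__all__ = [
    "FuzzyCoefficient",
    "FuzzyModel",
    "FuzzyPrediction",
    "FittingError",
    "fit_possibilistic",
    "predict_fuzzy",
    "format_model_equations",
]

_SPREAD_FLOOR = 1e-9  # spreads below this are reported as exactly 0


class FittingError(RuntimeError):
    """The linear program could not be solved."""


@dataclass(frozen=True)
class FuzzyCoefficient:
    """Triangular fuzzy coefficient: center and non-negative spreads.

    The support interval is [center - left_spread, center + right_spread];
    symmetric coefficients have equal spreads.
    """

    center: float
    left_spread: float
    right_spread: float

    def __post_init__(self) -> None:
        if self.left_spread < 0 or self.right_spread < 0:
            raise ConfigurationError("spreads must be non-negative")

    @property
    def support(self) -> tuple[float, float]:
        return (self.center - self.left_spread, self.center + self.right_spread)


@dataclass(frozen=True)
class FuzzyModel:
    """Fitted possibilistic regression model.

    ``objective_value`` is the minimised data-weighted total spread,
    recomputable from the coefficients and the training column weights.
    """

    terms: tuple[str, ...]
    coefficients: tuple[FuzzyCoefficient, ...]
    h_level: float
    mode: str
    objective_value: float
    response_name: str = "y"

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(self.terms):
            raise ConfigurationError("one coefficient per term required")
        if not 0.0 <= self.h_level < 1.0:
            raise ConfigurationError("h_level must lie in [0, 1)")
        if self.mode == "symmetric":
            for c in self.coefficients:
                if c.left_spread != c.right_spread:
                    raise ConfigurationError("symmetric mode requires equal spreads")

    def to_frame(self) -> pd.DataFrame:
        """Per-term central tendency and support boundaries."""
        return pd.DataFrame(
            {
                "Variable": self.terms,
                "Central tendency": [c.center for c in self.coefficients],
                "Lower boundary": [c.center - c.left_spread for c in self.coefficients],
                "Upper boundary": [c.center + c.right_spread for c in self.coefficients],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class FuzzyPrediction:
    """Crisp summary of a fuzzy prediction: center and support bounds."""

    center: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower <= self.center <= self.upper:
            raise ConfigurationError("prediction bounds must bracket the center")


def fit_possibilistic(
    matrix: DesignMatrix, h_level: float = 0.0, mode: str = "symmetric"
) -> FuzzyModel:
    """Fit the minimum-spread fuzzy model by linear programming.

    Parameters
    ----------
    matrix : DesignMatrix
        Dummy-encoded design (intercept column included; its regressor
        value is the constant 1).
    h_level : float in [0, 1)
        Degree-of-fit requirement; 0 asks only that the support band
        contain every observation, larger values force wider spreads.
    mode : {"symmetric", "asymmetric"}
        Whether the left and right spreads of each coefficient are tied.

    Raises
    ------
    FittingError
        If the LP solver reports failure, or the fitted band fails to
        contain a training observation (which a correct solution at any
        admissible h cannot do).
    """
    if matrix.n_rows == 0:
        raise EmptyDataError("cannot fit a fuzzy model to an empty design")
    if not 0.0 <= h_level < 1.0:
        raise ConfigurationError("h_level must lie in [0, 1)")
    if mode not in ("symmetric", "asymmetric"):
        raise ConfigurationError(f"unknown mode {mode!r}")

    X = matrix.X
    y = matrix.y
    m, k = X.shape
    absX = np.abs(X)
    weights = absX.sum(axis=0)  # sum_i |x_ij| per term
    zero_cols = weights == 0.0
    if zero_cols.any():
        warnings.warn(
            f"all-zero predictor column(s) {[matrix.columns[i] for i in np.flatnonzero(zero_cols)]}: "
            "their spreads are fixed at 0"
        )

    shrink = 1.0 - h_level
    n_spread_sets = 1 if mode == "symmetric" else 2
    n_var = k + n_spread_sets * k  # centers then spread block(s)

    cost = np.zeros(n_var)
    if mode == "symmetric":
        cost[k:] = weights
    else:
        cost[k : 2 * k] = weights / 2.0  # left spreads
        cost[2 * k :] = weights / 2.0  # right spreads

    # constraints in A_ub x <= b_ub form
    if mode == "symmetric":
        left_block = right_block = slice(k, 2 * k)
    else:
        left_block, right_block = slice(k, 2 * k), slice(2 * k, 3 * k)

    A_upper = np.zeros((m, n_var))  # -(a.x) - (1-h) cR.|x| <= -y
    A_upper[:, :k] = -X
    A_upper[:, right_block] -= shrink * absX
    A_lower = np.zeros((m, n_var))  # a.x - (1-h) cL.|x| <= y
    A_lower[:, :k] = X
    A_lower[:, left_block] -= shrink * absX
    A_ub = np.vstack([A_upper, A_lower])
    b_ub = np.concatenate([-y, y])

    bounds: list[tuple[float | None, float | None]] = [(None, None)] * k
    for _ in range(n_spread_sets):
        bounds.extend((0.0, 0.0) if zero_cols[j] else (0.0, None) for j in range(k))

    res = linprog(cost, A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs")
    if not res.success:
        raise FittingError(f"LP solver failed: {res.message} (status {res.status})")

    centers = res.x[:k]
    if mode == "symmetric":
        left = right = np.where(res.x[k : 2 * k] < _SPREAD_FLOOR, 0.0, res.x[k : 2 * k])
    else:
        left = np.where(res.x[k : 2 * k] < _SPREAD_FLOOR, 0.0, res.x[k : 2 * k])
        right = np.where(res.x[2 * k :] < _SPREAD_FLOOR, 0.0, res.x[2 * k :])

    objective = float(weights @ ((left + right) / 2.0))

    # containment of every training observation in the full support band
    center_fit = X @ centers
    lo = center_fit - absX @ left
    hi = center_fit + absX @ right
    slack = 1e-6 * max(1.0, float(np.abs(y).max()))
    if np.any(y < lo - slack) or np.any(y > hi + slack):
        raise FittingError("fitted support band fails to contain a training observation")

    model = FuzzyModel(
        terms=matrix.columns,
        coefficients=tuple(
            FuzzyCoefficient(float(a), float(l), float(r))
            for a, l, r in zip(centers, left, right)
        ),
        h_level=h_level,
        mode=mode,
        objective_value=objective,
        response_name=matrix.response_name,
    )
    logger.info(
        "fuzzy fit: %d rows, %d terms, h=%.2f (%s), total spread %.6g",
        m, k, h_level, mode, objective,
    )
    return model


def predict_fuzzy(model: FuzzyModel, x: Mapping[str, float]) -> FuzzyPrediction:
    """Evaluate the fuzzy model at a covariate record.

    The center is the inner product of coefficient centers with (1, x);
    the support bounds subtract/add the spread contributions weighted by
    |x_j| (the intercept contributes with x_0 = 1).
    """
    center = lower_off = upper_off = 0.0
    for term, coef in zip(model.terms, model.coefficients):
        if term == "Intercept":
            xj = 1.0
        elif term in x:
            xj = float(x[term])
        else:
            raise ConfigurationError(f"missing value for term {term!r}")
        center += coef.center * xj
        lower_off += coef.left_spread * abs(xj)
        upper_off += coef.right_spread * abs(xj)
    return FuzzyPrediction(center=center, lower=center - lower_off, upper=center + upper_off)


def _equation(response: str, terms, values, decimals: int) -> str:
    parts = []
    for term, v in zip(terms, values):
        coef = f"{v:.{decimals}f}"
        parts.append(coef if term == "Intercept" else f"{coef}*{term}")
    return f"{response} = " + " + ".join(parts)


def format_model_equations(model: FuzzyModel, decimals: int = 5) -> tuple[str, str, str]:
    """Render the central-tendency, lower-boundary and upper-boundary equations."""
    centers = [c.center for c in model.coefficients]
    lowers = [c.center - c.left_spread for c in model.coefficients]
    uppers = [c.center + c.right_spread for c in model.coefficients]
    return (
        _equation(model.response_name, model.terms, centers, decimals),
        _equation(model.response_name, model.terms, lowers, decimals),
        _equation(model.response_name, model.terms, uppers, decimals),
    )
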