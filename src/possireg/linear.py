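"""Ordinary least-squares fit of the dummy-coded linear model.

Produces a coefficient table (estimate, standard error, t-value, two-sided
p-value) with fit statistics, in the shape clinicians expect from a
regression printout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data import ConfigurationError, DesignMatrix
from .mlp import InsufficientDataError

__all__ = ["CoefficientReport", "SingularDesignError", "fit_ols", "predict_linear"]


class SingularDesignError(ValueError):
    """The design matrix is rank deficient."""


@dataclass(frozen=True)
class CoefficientReport:
    """Per-term OLS inference plus fit statistics.

    ``t_values`` are estimates / standard errors; ``p_values`` are
    two-sided tail probabilities of a t distribution with ``residual_df``
    degrees of freedom.  Both the plain and the adjusted R^2 are carried.
    """

    terms: tuple[str, ...]
    estimates: np.ndarray = field(repr=False)
    std_errors: np.ndarray = field(repr=False)
    t_values: np.ndarray = field(repr=False)
    p_values: np.ndarray = field(repr=False)
    r_squared: float = 0.0
    adj_r_squared: float = 0.0
    residual_df: int = 0

    def __post_init__(self) -> None:
        k = len(self.terms)
        for arr in (self.estimates, self.std_errors, self.t_values, self.p_values):
            if len(arr) != k:
                raise ConfigurationError("report arrays inconsistent with terms")

    def to_frame(self) -> pd.DataFrame:
        """Coefficient table with Estimate / Std error / t-value / P-value columns."""
        return pd.DataFrame(
            {
                "Variable": self.terms,
                "Estimate": self.estimates,
                "Std error": self.std_errors,
                "t-value": self.t_values,
                "P-value": self.p_values,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def fit_ols(matrix: DesignMatrix) -> CoefficientReport:
    """Least-squares fit with standard OLS inference.

    Requires more rows than columns and a full-column-rank design.
    """
    m, k1 = matrix.X.shape
    if m <= k1:
        raise InsufficientDataError(f"{m} rows cannot identify {k1} coefficients")
    rank = np.linalg.matrix_rank(matrix.X)
    if rank < k1:
        # name the columns involved in the dependency via QR pivoting
        _, R = np.linalg.qr(matrix.X)
        small = np.abs(np.diag(R)) < 1e-10 * np.abs(np.diag(R)).max()
        bad = [matrix.columns[i] for i in np.flatnonzero(small)]
        raise SingularDesignError(f"design matrix is rank deficient (columns {bad})")

    res = sm.OLS(matrix.y, matrix.X).fit()
    return CoefficientReport(
        terms=matrix.columns,
        estimates=np.asarray(res.params),
        std_errors=np.asarray(res.bse),
        t_values=np.asarray(res.tvalues),
        p_values=np.asarray(res.pvalues),
        r_squared=float(res.rsquared),
        adj_r_squared=float(res.rsquared_adj),
        residual_df=int(res.df_resid),
    )


def predict_linear(report: CoefficientReport, x: Mapping[str, float]) -> float:
    """Point prediction: inner product of the estimates with (1, x)."""
    total = 0.0
    for term, beta in zip(report.terms, report.estimates):
        if term == "Intercept":
            total += beta
            continue
        if term not in x:
            raise ConfigurationError(f"missing value for term {term!r}")
        total += beta * float(x[term])
    return float(total)
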