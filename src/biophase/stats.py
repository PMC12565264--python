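"""Ordinary least squares with inference statistics, plus the Landau-expansion
coefficient mapping.

The survival models used throughout the package are piecewise linear after a
change of variable (squared survival fraction against time or log-dose), so
every fit in the package reduces to a simple two-parameter regression.  This
module provides that regression once, with the standard inference quantities
(standard errors, t statistics, two-sided p values on n - 2 df, R², adjusted
R² and the overall F statistic), and the mapping from the quartic free-energy
expansion G = G0 + a(X - Xr)q² + bq⁴ to the linear coefficients
α1 = aXr/2b, β1 = a/2b of the ordered-phase solution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .errors import DegenerateDesignError, InvalidInputError

__all__ = ["LinearFitStats", "LandauParams", "ols_fit", "landau_to_linear"]


@dataclass(frozen=True)
class LinearFitStats:
    """Simple-regression fit y = intercept + slope·x with inference statistics.

    For a perfect two-point fit (zero residual degrees of freedom) the
    standard errors and derived statistics are NaN; the coefficients are
    still exact.
    """

    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    t_slope: float
    t_intercept: float
    p_slope: float
    p_intercept: float
    r2: float
    adj_r2: float
    f_stat: float
    df_resid: int
    n_points: int

    def predict(self, x):
        """Evaluate the fitted line at ``x`` (scalar or array)."""
        return self.intercept + self.slope * np.asarray(x, dtype=float)


@dataclass(frozen=True)
class LandauParams:
    """Coefficients of the quartic expansion G = G0 + a(X - Xr)q² + bq⁴.

    ``a`` and ``b`` must be positive for a second-order transition to occur
    at the critical factor value ``xr``.
    """

    g0: float
    a: float
    b: float
    xr: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise InvalidInputError(
                f"Landau coefficients require a > 0 and b > 0; got a={self.a}, b={self.b}"
            )


def ols_fit(x, y) -> LinearFitStats:
    """Least-squares line through (x, y) with full inference statistics.

    Parameters
    ----------
    x, y : array-like of equal length >= 2
        ``x`` must not be constant.

    Returns
    -------
    LinearFitStats
        Two-sided t tests use the t distribution on n - 2 degrees of
        freedom; the F statistic is the standard overall-regression F for a
        single predictor.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
        raise InvalidInputError("x and y must be 1-D arrays of equal length")
    if x.size < 2:
        raise InvalidInputError(f"need at least 2 points, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InvalidInputError("x and y must be finite")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("x is constant; the slope is not identifiable")

    with warnings.catch_warnings():
        # perfect fits / zero residual df trip harmless divide warnings inside
        # statsmodels' summary statistics
        warnings.simplefilter("ignore")
        res = sm.OLS(y, sm.add_constant(x)).fit()
        intercept, slope = res.params
        se_intercept, se_slope = res.bse
        t_intercept, t_slope = res.tvalues
        p_intercept, p_slope = res.pvalues
        r2 = float(res.rsquared)
        adj_r2 = float(res.rsquared_adj)
        f_stat = float(res.fvalue)

    return LinearFitStats(
        slope=float(slope),
        intercept=float(intercept),
        se_slope=float(se_slope),
        se_intercept=float(se_intercept),
        t_slope=float(t_slope),
        t_intercept=float(t_intercept),
        p_slope=float(p_slope),
        p_intercept=float(p_intercept),
        r2=r2,
        adj_r2=adj_r2,
        f_stat=f_stat,
        df_resid=int(res.df_resid),
        n_points=int(x.size),
    )


def landau_to_linear(params: LandauParams) -> tuple[float, float]:
    """Map quartic-expansion coefficients to the linear form q² = α1 − β1·X.

    Minimising G in the ordered phase (X < Xr) gives
    q² = a(Xr − X)/2b, i.e. α1 = a·Xr/(2b) and β1 = a/(2b).
    """
    if params.b == 0:
        raise ZeroDivisionError("b must be nonzero to form α1, β1")
    beta1 = params.a / (2.0 * params.b)
    alpha1 = beta1 * params.xr
    return alpha1, beta1
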