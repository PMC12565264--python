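"""Dose–effect and dose–time relations on the ln(D + 1) scale.

End-of-experiment survival follows the same phase-transition form as the
time course, with log-dose as the external factor:

    q²(D) = 1                  for D <= D0         (no-effect doses)
          = α2 − β2·ln(D + 1)  for D0 < D < Dr     (graded response)
          = q_r²               for D >= Dr         (overkill doses)

β2 = −∂q²/∂ln(1+D) is the susceptibility to dose.  Two companion linear
relations are fitted on the same axis: the dose–time relation
LT100 = A − B·ln(D + 1) and the per-dose-parameter relations
T0 = A1 − B1·ln(D + 1) and q_r = A2 − B2·ln(D + 1).

Coefficients are reported in the "A − B·ln(D+1)" convention (intercept and
slope magnitude, with B positive when the response declines with dose); the
raw OLS slope keeps its sign inside the attached LinearFitStats.  Doses are
taken on whatever scale the user supplies (per-larva doses or suspension
concentrations) and the unit is metadata only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, InvalidInputError, NoCrossingError
from .stats import LinearFitStats, ols_fit

__all__ = [
    "DoseEffectFit",
    "DoseTimeRelation",
    "ParamDoseRelation",
    "log_dose",
    "fit_dose_effect",
    "critical_log_dose",
    "fit_dose_time",
    "fit_param_vs_logdose",
]

_LN_OVERFLOW = 700.0  # expm1 overflows past this


def log_dose(d) -> float | np.ndarray:
    """Natural log of (dose + 1); the model's dose axis.  log_dose(0) = 0."""
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr < 0):
        raise InvalidInputError("dose must be nonnegative")
    out = np.log1p(d_arr)
    if np.isscalar(d) or d_arr.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class DoseEffectFit:
    """Fitted dose–effect model q² = α2 − β2·ln(D + 1) with its boundaries.

    ``d0`` is the largest observed dose with zero mortality (0 if none);
    ``dr`` is the dose at which the fitted line reaches q² = 0, beyond which
    doses are "overkill".  ``no_effect`` marks the degenerate case β2 = 0
    (every dose left q = 1: the virus does not affect the insects).
    """

    alpha2: float
    beta2: float
    d0: float
    dr: float
    ln_dr: float
    line_fit: LinearFitStats | None
    no_effect: bool = False

    def predict_q(self, d) -> float | np.ndarray:
        """Predicted survival fraction at dose ``d`` (clamped to [0, 1])."""
        if self.no_effect:
            out = np.ones_like(np.asarray(d, dtype=float))
        else:
            q2 = np.clip(self.alpha2 - self.beta2 * log_dose(np.asarray(d, dtype=float)), 0.0, 1.0)
            out = np.sqrt(q2)
        if np.isscalar(d):
            return float(out)
        return out


@dataclass(frozen=True)
class DoseTimeRelation:
    """Dose–time relation LT100 = A − B·ln(D + 1).

    ``b_coef`` is the slope magnitude in the A − B·ln(D+1) convention: positive when
    higher doses kill faster.
    """

    a_coef: float
    b_coef: float
    stats: LinearFitStats

    def predict(self, d) -> float | np.ndarray:
        return self.a_coef - self.b_coef * log_dose(d)


@dataclass(frozen=True)
class ParamDoseRelation:
    """Linear relation of a per-dose model parameter to ln(D + 1).

    ``target`` names the parameter ("T0" for lag duration, "qr" for plateau
    survival); the relation reads target = a_coef − b_coef·ln(D + 1).
    """

    target: str
    a_coef: float
    b_coef: float
    stats: LinearFitStats

    def predict(self, d) -> float | np.ndarray:
        return self.a_coef - self.b_coef * log_dose(d)


def fit_dose_effect(doses, q_end) -> DoseEffectFit:
    """Fit q² = α2 − β2·ln(D + 1) to end-of-experiment survival fractions.

    Doses with 0 < q < 1 enter the regression; boundary doses are detected
    from the data: D0 is the largest dose with q = 1, and Dr is where the
    fitted line crosses q² = 0.

    Raises
    ------
    InsufficientDataError
        if fewer than 3 usable (0 < q < 1) doses exist, unless *every* dose
        has q = 1, which returns a flagged no-effect fit with β2 = 0.
    """
    d = np.asarray(doses, dtype=float)
    q = np.asarray(q_end, dtype=float)
    if d.size != q.size or d.size == 0:
        raise InvalidInputError("doses and q_end must be nonempty and equal length")
    if np.any(d < 0):
        raise InvalidInputError("doses must be nonnegative")
    if np.any((q < 0) | (q > 1)):
        raise InvalidInputError("survival fractions must lie in [0, 1]")

    if np.all(q >= 1.0 - 1e-12):
        return DoseEffectFit(
            alpha2=1.0,
            beta2=0.0,
            d0=float(np.max(d)),
            dr=math.inf,
            ln_dr=math.inf,
            line_fit=None,
            no_effect=True,
        )

    interior = (q > 0) & (q < 1)
    if np.count_nonzero(interior) < 3:
        raise InsufficientDataError(
            f"need >= 3 doses with 0 < q < 1, got {np.count_nonzero(interior)}"
        )
    line = ols_fit(np.log1p(d[interior]), q[interior] ** 2)
    alpha2 = line.intercept
    beta2 = -line.slope

    full_survival = q >= 1.0 - 1e-12
    d0 = float(np.max(d[full_survival])) if np.any(full_survival) else 0.0
    if beta2 > 0:
        ln_dr = alpha2 / beta2
        dr = math.inf if ln_dr > _LN_OVERFLOW else float(np.expm1(ln_dr))
    else:
        ln_dr = math.inf
        dr = math.inf
    return DoseEffectFit(
        alpha2=float(alpha2),
        beta2=float(beta2),
        d0=d0,
        dr=dr,
        ln_dr=float(ln_dr),
        line_fit=line,
    )


def critical_log_dose(fit) -> float:
    """ln(D + 1) at which a fitted declining line reaches zero.

    Accepts a DoseEffectFit (uses α2/β2) or a ParamDoseRelation on q_r
    (uses A2/B2); in both cases the value is intercept over slope magnitude.
    """
    if isinstance(fit, DoseEffectFit):
        intercept, slope_mag = fit.alpha2, fit.beta2
    elif isinstance(fit, ParamDoseRelation):
        intercept, slope_mag = fit.a_coef, fit.b_coef
    else:
        raise InvalidInputError(f"unsupported fit type {type(fit).__name__}")
    if slope_mag <= 0:
        raise NoCrossingError("slope magnitude must be positive for a zero crossing")
    return intercept / slope_mag


def fit_dose_time(doses, lt100s) -> DoseTimeRelation:
    """Fit the dose–time relation LT100 = A − B·ln(D + 1) with inference stats."""
    d = np.asarray(doses, dtype=float)
    lt = np.asarray(lt100s, dtype=float)
    if d.size != lt.size:
        raise InvalidInputError("doses and lt100s must have equal length")
    if d.size < 2 or np.unique(d).size < 2:
        raise InsufficientDataError("need at least 2 distinct doses")
    if np.any(d < 0):
        raise InvalidInputError("doses must be nonnegative")
    line = ols_fit(np.log1p(d), lt)
    return DoseTimeRelation(a_coef=line.intercept, b_coef=-line.slope, stats=line)


def fit_param_vs_logdose(doses, values, target: str) -> ParamDoseRelation:
    """Fit a per-dose parameter (``target`` = "T0" or "qr") against ln(D + 1)."""
    if target not in ("T0", "qr"):
        raise InvalidInputError(f"target must be 'T0' or 'qr', got {target!r}")
    d = np.asarray(doses, dtype=float)
    v = np.asarray(values, dtype=float)
    if d.size != v.size:
        raise InvalidInputError("doses and values must have equal length")
    if d.size < 2 or np.unique(d).size < 2:
        raise InsufficientDataError("need at least 2 distinct doses")
    if np.any(d < 0):
        raise InvalidInputError("doses must be nonnegative")
    line = ols_fit(np.log1p(d), v)
    return ParamDoseRelation(target=target, a_coef=line.intercept, b_coef=-line.slope, stats=line)
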