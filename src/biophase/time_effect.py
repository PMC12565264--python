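"""Three-phase time–effect model for one dose's survival time course.

A cohort of larvae exposed to a fixed virus dose passes through three phases:
a lag phase in which nobody dies (q = 1), a dying phase in which the squared
survival fraction declines linearly with time (q² = α1 − β1·T), and a plateau
in which mortality has stopped (q = q_r, possibly 0).  Treating the survival
fraction q as the order parameter of a second-order phase transition, the
cohort curve is

    q²(T) = 1            for T <= T0      (lag)
          = α1 − β1·T    for T0 < T <= Tr (dying)
          = q_r²         for T > Tr       (plateau)

β1 = −∂q²/∂T is the susceptibility of the insects to the virus; the time at
which the fitted line reaches q² = 0 is the lethal time LT100 = α1/β1.

Fitting locates the two breakpoints by exhaustive search over observation
indices (series are short, so the search is exact and cheap), with an OLS
line on the interior points and phase-wise squared error summed over all
three phases.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ExtrapolationWarning,
    InsufficientDataError,
    InvalidInputError,
    NoKillError,
    NoMortalityError,
)
from .stats import LinearFitStats, ols_fit

__all__ = [
    "SurvivalSeries",
    "TimeEffectFit",
    "survival_fractions",
    "fit_time_effect",
    "lt100",
    "time_at_q2",
    "predict_q",
]

_TIE_TOL = 1e-12


@dataclass(frozen=True)
class SurvivalSeries:
    """One dose's time course of alive counts.

    ``alive`` may be fractional (expected counts from the simulator are
    admitted so that noiseless round trips stay exact); observed data are
    integers.  Counts must be non-increasing and never exceed ``n_initial``.
    Larvae excluded from the bioassay (e.g. incomplete droplet ingestion)
    should already be removed from ``n_initial``.
    """

    times: tuple[float, ...]
    alive: tuple[float, ...]
    n_initial: float
    dose: float = 0.0
    dose_units: str = "OBs/larva"

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times)
        alive = tuple(float(a) for a in self.alive)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "alive", alive)
        if len(times) != len(alive) or len(times) == 0:
            raise InvalidInputError("times and alive must be nonempty and equal length")
        if self.n_initial <= 0:
            raise InvalidInputError("n_initial must be positive")
        t = np.asarray(times)
        a = np.asarray(alive)
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise InvalidInputError("times must be nonnegative and strictly increasing")
        if np.any(a < 0) or np.any(a > self.n_initial + 1e-9):
            raise InvalidInputError("alive counts must lie in [0, n_initial]")
        if np.any(np.diff(a) > 1e-9):
            raise InvalidInputError("alive counts must be non-increasing in time")
        if self.dose < 0:
            raise InvalidInputError("dose must be nonnegative")

    def fractions(self) -> np.ndarray:
        """Survival fractions q(t) = alive(t)/n_initial."""
        return np.asarray(self.alive) / self.n_initial


@dataclass(frozen=True)
class TimeEffectFit:
    """Fitted three-phase model for one survival series.

    ``t0`` is the observed lag end (last time with q = 1; 0 if mortality had
    begun by the first observation).  The *fitted* lag end (α1 − 1)/β1 —
    where the interior line crosses q² = 1 — is available via
    ``time_at_q2(fit, 1.0)``.  ``tr`` is where the line meets the plateau
    level q_r², so q_r² = α1 − β1·tr holds by construction.
    """

    alpha1: float
    beta1: float
    t0: float
    tr: float
    qr: float
    r2_segment: float
    n_segment_points: int
    segment_fit: LinearFitStats | None = None
    lag_index: int = 0
    plateau_index: int | None = None
    extrapolated_lt: bool = field(default=False)

    @property
    def qr2(self) -> float:
        return self.qr**2

    @classmethod
    def from_line(cls, alpha1: float, beta1: float, qr: float = 0.0) -> "TimeEffectFit":
        """Build a fit object directly from dying-phase line coefficients.

        Convenience constructor for evaluating published (α1, β1) pairs:
        the lag end is placed at the line's q² = 1 crossing and the plateau
        at its q² = q_r² crossing.
        """
        if beta1 <= 0:
            raise InvalidInputError("from_line requires beta1 > 0")
        if not 0 <= qr <= 1:
            raise InvalidInputError("qr must lie in [0, 1]")
        t0 = max(0.0, (alpha1 - 1.0) / beta1)
        tr = (alpha1 - qr**2) / beta1
        return cls(
            alpha1=alpha1,
            beta1=beta1,
            t0=t0,
            tr=tr,
            qr=qr,
            r2_segment=float("nan"),
            n_segment_points=0,
            extrapolated_lt=qr > 0,
        )


def survival_fractions(series: SurvivalSeries) -> list[tuple[float, float]]:
    """Pairs (time, q) with q = alive/n_initial, in series order."""
    return list(zip(series.times, series.fractions().tolist()))


def _phase_sse(q2: np.ndarray, t: np.ndarray, i0: int, j: int):
    """Total squared error for the partition lag=[0,i0), interior=[i0,j), plateau=[j,m).

    Returns (sse, line_stats, plateau_q2) or None if the interior is degenerate.
    """
    interior_t = t[i0:j]
    interior_q2 = q2[i0:j]
    try:
        line = ols_fit(interior_t, interior_q2)
    except Exception:
        return None
    sse = 0.0
    if i0 > 0:
        sse += float(np.sum((q2[:i0] - 1.0) ** 2))
    resid = interior_q2 - line.predict(interior_t)
    sse += float(np.sum(resid**2))
    plateau_q2 = None
    if j < len(t):
        plateau_q2 = float(np.mean(q2[j:]))
        sse += float(np.sum((q2[j:] - plateau_q2) ** 2))
    return sse, line, plateau_q2


def fit_time_effect(series: SurvivalSeries, min_segment_points: int = 2) -> TimeEffectFit:
    """Fit the three-phase model to one dose's survival series.

    The breakpoint pair (lag end index, plateau start index) is chosen by
    exhaustive enumeration: for every admissible partition the lag points are
    predicted at q² = 1, the interior points by their OLS line and the
    plateau points by their mean q², and the partition minimising the total
    squared error wins.  Ties are broken toward the widest interior segment.

    Raises
    ------
    NoMortalityError
        if every observation has q = 1 (the model is degenerate, q_r = 1).
    InsufficientDataError
        if fewer than 4 observations or no admissible partition exists.
    """
    q = series.fractions()
    q2 = q**2
    t = np.asarray(series.times, dtype=float)
    m = t.size
    if np.all(q >= 1.0 - 1e-12):
        raise NoMortalityError("all larvae alive at every observation; q_r = 1")
    if m < 4:
        raise InsufficientDataError(f"need at least 4 observation times, got {m}")
    if min_segment_points < 2:
        raise InvalidInputError("min_segment_points must be >= 2")

    # Lag points predict q = 1, under which any observed death has probability
    # zero; only the leading run of q = 1 observations is therefore eligible
    # for the lag phase, and the search enumerates how much of that run the
    # interior line absorbs.
    n_prefix = 0
    while n_prefix < m and q[n_prefix] >= 1.0 - 1e-9:
        n_prefix += 1

    best = None  # (sse, -interior_width, i0, j, line, plateau_q2)
    for i0 in range(0, min(n_prefix, m - min_segment_points) + 1):
        for j in range(i0 + min_segment_points, m + 1):
            out = _phase_sse(q2, t, i0, j)
            if out is None:
                continue
            sse, line, plateau_q2 = out
            width = j - i0
            cand = (sse, -width, i0, j, line, plateau_q2)
            if best is None:
                best = cand
            else:
                if sse < best[0] - _TIE_TOL:
                    best = cand
                elif abs(sse - best[0]) <= _TIE_TOL and width > -best[1]:
                    best = cand
    if best is None:
        raise InsufficientDataError("no admissible breakpoint partition")

    _, _, i0, j, line, plateau_q2 = best
    alpha1 = line.intercept
    beta1 = -line.slope  # positive for declining survival
    t0 = float(t[i0 - 1]) if i0 > 0 else 0.0

    line_end = alpha1 - beta1 * t[j - 1]
    if beta1 > 0 and line_end < 0:
        # line has crossed zero before the last interior point: total kill
        qr = 0.0
        tr = alpha1 / beta1
    elif j < m:
        qr = float(np.mean(q[j:]))
        tr = (alpha1 - qr**2) / beta1 if beta1 > 0 else float(t[j])
    else:
        qr2 = float(min(1.0, max(0.0, line_end)))
        qr = math.sqrt(qr2)
        tr = (alpha1 - qr2) / beta1 if beta1 > 0 else float(t[-1])

    return TimeEffectFit(
        alpha1=float(alpha1),
        beta1=float(beta1),
        t0=t0,
        tr=float(tr),
        qr=float(qr),
        r2_segment=float(line.r2),
        n_segment_points=j - i0,
        segment_fit=line,
        lag_index=i0,
        plateau_index=j if j < m else None,
        extrapolated_lt=qr > 0,
    )


def lt100(fit: TimeEffectFit) -> float:
    """Lethal time LT100 = α1/β1, where the fitted line reaches q² = 0.

    When q_r > 0 the cohort never actually reaches q = 0 and the value is an
    extrapolated "would-be" lethal time (``fit.extrapolated_lt`` is True).
    """
    if fit.beta1 <= 0:
        raise NoKillError(f"beta1 = {fit.beta1} <= 0; no lethal time exists")
    return fit.alpha1 / fit.beta1


def time_at_q2(fit: TimeEffectFit, level: float) -> float:
    """Time at which the fitted dying-phase line reaches q² = ``level``.

    level = 1 gives the fitted lag end (α1 − 1)/β1; level = 0 gives LT100.
    Levels outside the reachable range [q_r², 1] are extrapolated with a
    warning.
    """
    if fit.beta1 <= 0:
        raise NoKillError("beta1 must be positive to invert the dying-phase line")
    if not (fit.qr2 - 1e-9 <= level <= 1 + 1e-9):
        warnings.warn(
            f"level {level} outside fitted range [{fit.qr2:.4g}, 1]; extrapolating",
            ExtrapolationWarning,
            stacklevel=2,
        )
    return (fit.alpha1 - level) / fit.beta1


def predict_q(fit: TimeEffectFit, t) -> float | np.ndarray:
    """Survival fraction predicted by the fitted three-phase model.

    Returns 1 during the lag, sqrt(clamp(α1 − β1·t, q_r², 1)) during the
    dying phase and q_r on the plateau; non-increasing in t.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise InvalidInputError("time must be nonnegative")
    q2_line = np.clip(fit.alpha1 - fit.beta1 * t_arr, fit.qr2, 1.0)
    q = np.sqrt(q2_line)
    q = np.where(t_arr <= fit.t0, 1.0, q)
    q = np.where(t_arr > fit.tr, fit.qr, q)
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(q)
    return q
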