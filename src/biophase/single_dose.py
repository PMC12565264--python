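"""Single-dose calibration of virus effectiveness.

The headline shortcut: across doses, end-of-experiment survival q_r and the
inverse lag duration 1/T0 fall on a common straight line.  Since an
untreated control pins one point on that line for free — if no control larva
dies within an observation window of T days, the lag is effectively the
whole window, so (1/T0, q_r) = (1/T, 1) — a single treated dose suffices to
draw the whole line:

    Q_r = slope · (1/T0) + intercept

Effectiveness Q_r at any other dose is then predicted from that dose's lag
duration alone, replacing a full serial-dilution design with one control and
one treated cohort.  Prediction errors Δq_r = q_r − Q_r against held-out
doses quantify how well the shortcut works.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .dose_response import ParamDoseRelation
from .errors import ClampingWarning, DegenerateCalibrationError, InvalidInputError, NoCrossingError

__all__ = [
    "CalibrationPoint",
    "CalibrationLine",
    "PredictionErrorRow",
    "control_point",
    "calibrate_two_point",
    "predict_effectiveness",
    "prediction_error_table",
    "logdose_for_lag",
]


@dataclass(frozen=True)
class CalibrationPoint:
    """One (1/T0, q_r) observation used to anchor the calibration line."""

    inv_t0: float
    qr: float
    dose: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.inv_t0 <= 0:
            raise InvalidInputError("inv_t0 must be positive")
        if not 0 <= self.qr <= 1:
            raise InvalidInputError("qr must lie in [0, 1]")


@dataclass(frozen=True)
class CalibrationLine:
    """The constraint line Q_r = slope·(1/T0) + intercept."""

    slope: float
    intercept: float
    source: tuple[CalibrationPoint, CalibrationPoint] | None = None

    def predict(self, inv_t0: float) -> float:
        return self.slope * inv_t0 + self.intercept


@dataclass(frozen=True)
class PredictionErrorRow:
    """Observed vs predicted effectiveness at one dose; delta = observed − predicted."""

    dose: float
    qr_observed: float
    qr_predicted: float
    delta: float
    excluded: bool = False


def control_point(observation_length: float) -> CalibrationPoint:
    """Calibration point contributed by a mortality-free control.

    When no control larva dies, the lag covers the whole observation window,
    so 1/T0 = 1/observation_length and q_r = 1.
    """
    if observation_length <= 0:
        raise InvalidInputError("observation_length must be positive")
    return CalibrationPoint(inv_t0=1.0 / observation_length, qr=1.0, dose=0.0, label="control")


def calibrate_two_point(control: CalibrationPoint, treated: CalibrationPoint) -> CalibrationLine:
    """Unique line through the control and one treated (1/T0, q_r) point."""
    dx = treated.inv_t0 - control.inv_t0
    if dx == 0:
        raise DegenerateCalibrationError("calibration points share the same 1/T0")
    slope = (treated.qr - control.qr) / dx
    intercept = control.qr - slope * control.inv_t0
    return CalibrationLine(slope=slope, intercept=intercept, source=(control, treated))


def predict_effectiveness(line: CalibrationLine, inv_t0: float, clamp: bool = True) -> float:
    """Predicted effectiveness Q_r at inverse lag duration ``inv_t0``.

    With ``clamp=True`` (default) the value is clamped to [0, 1] and a
    ClampingWarning is emitted when clamping occurred; ``clamp=False``
    returns the raw line value (used for Δq_r error arithmetic).
    """
    if inv_t0 <= 0:
        raise InvalidInputError("inv_t0 must be positive")
    raw = line.predict(inv_t0)
    if not clamp:
        return raw
    if raw < 0.0 or raw > 1.0:
        warnings.warn(
            f"predicted Q_r = {raw:.4g} outside [0, 1]; clamped", ClampingWarning, stacklevel=2
        )
        return min(1.0, max(0.0, raw))
    return raw


def prediction_error_table(rows, line: CalibrationLine, calibration_doses=()) -> list[PredictionErrorRow]:
    """Per-dose prediction errors Δq_r = q_r − Q_r (raw, unclamped predictions).

    ``rows`` is an iterable of (dose, qr_observed, inv_t0).  Doses listed in
    ``calibration_doses`` (and any dose matching a source point of the line)
    are marked excluded: they defined the line, so their error is trivially
    zero and they are left out of error summaries.
    """
    rows = list(rows)
    if not rows:
        raise InvalidInputError("rows must be nonempty")
    excluded_doses = set(float(d) for d in calibration_doses)
    if line.source is not None:
        excluded_doses.update(float(p.dose) for p in line.source)
    out = []
    for dose, qr_obs, inv_t0 in rows:
        pred = predict_effectiveness(line, inv_t0, clamp=False)
        out.append(
            PredictionErrorRow(
                dose=float(dose),
                qr_observed=float(qr_obs),
                qr_predicted=pred,
                delta=float(qr_obs) - pred,
                excluded=float(dose) in excluded_doses,
            )
        )
    return out


def logdose_for_lag(relation: ParamDoseRelation, t0: float) -> float:
    """Invert the lag–dose relation T0 = A1 − B1·ln(D + 1) for ln(D + 1).

    Used to translate a target lag duration (equivalently 1/T0) back into
    the dose that produces it.
    """
    if relation.target != "T0":
        raise InvalidInputError("relation must target 'T0'")
    if relation.b_coef == 0:
        raise NoCrossingError("zero slope; lag does not depend on dose")
    return (relation.a_coef - t0) / relation.b_coef
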