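"""Exception and warning types shared across the package."""


class BiophaseError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(BiophaseError, ValueError):
    """Malformed or out-of-contract input (lengths, ranges, signs)."""


class DegenerateDesignError(BiophaseError, ValueError):
    """Regression design has no variation in the predictor."""


class InsufficientDataError(BiophaseError, ValueError):
    """Too few points/doses/replicates to perform the requested fit."""


class NoMortalityError(BiophaseError, ValueError):
    """Every larva survived: the three-phase model is degenerate (q_r = 1)."""


class NoKillError(BiophaseError, ValueError):
    """Fitted decline rate is non-positive; a lethal time does not exist."""


class NoCrossingError(BiophaseError, ValueError):
    """A fitted line never reaches zero (slope magnitude is zero)."""


class DegenerateCalibrationError(BiophaseError, ValueError):
    """The two calibration points share the same 1/T0; no unique line exists."""


class ValidationError(BiophaseError, ValueError):
    """A dataset violates its structural invariants (with offending rows)."""


class ExtrapolationWarning(UserWarning):
    """A requested quantity lies outside the fitted range and was extrapolated."""


class ClampingWarning(UserWarning):
    """A prediction fell outside [0, 1] and was clamped."""
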