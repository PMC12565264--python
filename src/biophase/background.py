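"""Correction for dose-independent ("stochastic") background mortality.

Some rearing systems lose larvae to causes unrelated to the virus: in the
beet webworm assays roughly a fifth of control larvae died with no exposure
at all, and the loss was episodic — most control containers had some
mortality, one had none.  Treated-container mortality is then the additive
combination of the virus effect and this background.

The correction estimates each dose's squared survival by the average of the
two *smallest* replicate q² values, i.e. the replicates in which the
stochastic contribution was maximal.  Because the background is
dose-independent, pinning it at its maximal level at every dose removes its
replicate-to-replicate variability from the dose–effect slope, isolating the
"pure" virus susceptibility β2.  (Abbott-style subtraction of the mean
control mortality is deliberately not offered: the two-minima rule is the
estimator this pipeline is built around.)  With exactly two replicates the
rule degenerates to their plain mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dose_response import DoseEffectFit, fit_dose_effect
from .errors import InsufficientDataError, InvalidInputError

__all__ = [
    "ControlMortalitySummary",
    "summarize_control_mortality",
    "robust_q2",
    "fit_dose_effect_robust",
]


@dataclass(frozen=True)
class ControlMortalitySummary:
    """Replicate-level control mortality fractions and their arithmetic mean."""

    per_replicate: tuple[float, ...]
    mean_mortality: float


def summarize_control_mortality(mortalities) -> ControlMortalitySummary:
    """Summarise control (zero-dose) mortality across replicates."""
    vals = [float(v) for v in mortalities]
    if not vals:
        raise InvalidInputError("mortalities must be nonempty")
    if any(v < 0 or v > 1 for v in vals):
        raise InvalidInputError("mortality fractions must lie in [0, 1]")
    return ControlMortalitySummary(per_replicate=tuple(vals), mean_mortality=float(np.mean(vals)))


def robust_q2(replicate_q2) -> float:
    """Dose-level q² as the mean of the two smallest replicate q² values.

    This attributes the maximal plausible share of mortality to the
    dose-independent background, so the remaining dose-to-dose variation
    reflects the virus alone.
    """
    vals = sorted(float(v) for v in replicate_q2)
    if len(vals) < 2:
        raise InsufficientDataError("need at least 2 replicate q² values")
    if vals[0] < 0 or vals[-1] > 1:
        raise InvalidInputError("q² values must lie in [0, 1]")
    return 0.5 * (vals[0] + vals[1])


def fit_dose_effect_robust(doses, replicate_q2_per_dose) -> DoseEffectFit:
    """Background-corrected dose–effect fit.

    ``replicate_q2_per_dose`` holds, for each dose, the list of replicate
    squared survival fractions.  Each dose is summarised by the two-minima
    rule before the usual q² vs ln(D + 1) regression.
    """
    doses = list(doses)
    reps = list(replicate_q2_per_dose)
    if len(doses) != len(reps):
        raise InvalidInputError("doses and replicate_q2_per_dose must have equal length")
    q_end = [np.sqrt(robust_q2(r)) for r in reps]
    return fit_dose_effect(doses, q_end)
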