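"""Synthetic bioassay generator.

Individual larval death times are the primitive: each larva draws a death
time from the distribution implied by the three-phase cohort model, and the
observed dataset is the count of survivors at each observation time.  This
way the piecewise-linear q²(T) curve *emerges* from counts with genuine
binomial sampling noise, exactly as in a container assay, instead of being
imposed on aggregate fractions.

The death-time distribution at one dose: no deaths during the lag
(T <= T0), then F(t) = 1 − sqrt(α1 − β1·t) through the dying phase, with a
point mass q_r of survivors past Tr.  Continuity at the lag boundary fixes
α1 = 1 + β1·T0.  Dose-independent background mortality, when requested, is
an independent competing exponential risk whose rate is calibrated so that
the expected control mortality over the observation window equals the
requested fraction.

Default cohort sizes mirror droplet-feeding bioassay practice: 10 larvae
per container, 3–5 replicate containers per dose.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError
from .time_effect import SurvivalSeries

__all__ = [
    "DoseScenario",
    "SyntheticConfig",
    "death_time_cdf",
    "sample_death_times",
    "expected_survival_series",
    "generate_bioassay",
]


@dataclass(frozen=True)
class DoseScenario:
    """Generating truth for one dose: lag T0, decline rate β1, plateau q_r.

    ``alpha1`` is derived (= 1 + β1·T0, lag-boundary continuity) and
    ``tr`` is where the declining line meets q_r².  ``background_mortality``
    is the expected control-equivalent mortality over the observation
    window from causes unrelated to the dose.
    """

    dose: float
    t0: float
    beta1: float
    qr: float = 0.0
    background_mortality: float = 0.0

    def __post_init__(self) -> None:
        if self.dose < 0 or self.t0 < 0 or self.beta1 < 0:
            raise InvalidInputError("dose, t0 and beta1 must be nonnegative")
        if not 0 <= self.qr <= 1:
            raise InvalidInputError("qr must lie in [0, 1]")
        if not 0 <= self.background_mortality < 1:
            raise InvalidInputError("background_mortality must lie in [0, 1)")

    @property
    def alpha1(self) -> float:
        return 1.0 + self.beta1 * self.t0

    @property
    def tr(self) -> float:
        if self.beta1 == 0:
            return math.inf
        return (self.alpha1 - self.qr**2) / self.beta1

    def virus_survival(self, t) -> np.ndarray:
        """Dose-attributable survival q(t), ignoring background mortality."""
        t = np.asarray(t, dtype=float)
        q2 = np.clip(self.alpha1 - self.beta1 * t, self.qr**2, 1.0)
        return np.sqrt(q2)


@dataclass(frozen=True)
class SyntheticConfig:
    """Full multi-dose design: scenarios × replicates × observation times."""

    scenarios: tuple[DoseScenario, ...]
    observation_times: tuple[float, ...]
    n_per_replicate: int = 10
    n_replicates: int = 4
    seed: int = 0
    dose_units: str = "OBs/larva"

    def __post_init__(self) -> None:
        object.__setattr__(self, "scenarios", tuple(self.scenarios))
        object.__setattr__(
            self, "observation_times", tuple(float(t) for t in self.observation_times)
        )
        if not self.scenarios:
            raise InvalidInputError("at least one DoseScenario is required")
        t = np.asarray(self.observation_times)
        if t.size == 0 or np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise InvalidInputError("observation_times must be strictly increasing and >= 0")
        if self.n_per_replicate <= 0 or self.n_replicates <= 0:
            raise InvalidInputError("cohort sizes must be positive")

    @property
    def observation_length(self) -> float:
        return self.observation_times[-1]

    @classmethod
    def from_json(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = json.load(fh)
        scenarios = tuple(DoseScenario(**s) for s in raw.pop("scenarios"))
        return cls(scenarios=scenarios, **raw)


def _background_rate(scenario: DoseScenario, window: float) -> float:
    if scenario.background_mortality == 0:
        return 0.0
    if window is None or window <= 0:
        raise InvalidInputError("a positive observation window is required for background risk")
    return -math.log(1.0 - scenario.background_mortality) / window


def death_time_cdf(scenario: DoseScenario, t, observation_length: float | None = None):
    """CDF of an individual's death time under ``scenario``.

    F(t) = 1 − q_v(t)·exp(−λt) where q_v is the dose-attributable survival
    and λ the background competing-risk rate (0 when background mortality is
    0; otherwise ``observation_length`` is required for calibration).
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise InvalidInputError("time must be nonnegative")
    lam = _background_rate(scenario, observation_length)
    surv = scenario.virus_survival(t_arr) * np.exp(-lam * t_arr)
    out = 1.0 - surv
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(out)
    return out


def sample_death_times(
    scenario: DoseScenario,
    n: int,
    rng: np.random.Generator,
    observation_length: float | None = None,
) -> np.ndarray:
    """Draw ``n`` individual death times (inf = survived past everything).

    Virus deaths are sampled by exact inverse-CDF on the piecewise form:
    u < 1 − q_r maps to t = (α1 − (1 − u)²)/β1 in (T0, Tr]; the remaining
    mass survives.  Background deaths are an independent exponential and the
    realised death time is the minimum of the two.
    """
    if n <= 0:
        raise InvalidInputError("n must be positive")
    u = rng.random(n)
    t_virus = np.full(n, math.inf)
    if scenario.beta1 > 0:
        killed = u < 1.0 - scenario.qr
        t_virus[killed] = (scenario.alpha1 - (1.0 - u[killed]) ** 2) / scenario.beta1
    elif scenario.qr < 1:
        # zero decline rate but qr < 1 is contradictory; continuity forces qr = 1
        raise InvalidInputError("beta1 = 0 requires qr = 1")
    lam = _background_rate(scenario, observation_length)
    if lam > 0:
        t_bg = rng.exponential(1.0 / lam, size=n)
        return np.minimum(t_virus, t_bg)
    return t_virus


def expected_survival_series(
    scenario: DoseScenario,
    observation_times,
    n: float = 1.0,
    observation_length: float | None = None,
    dose_units: str = "OBs/larva",
) -> SurvivalSeries:
    """Noise-free series of *expected* alive counts (fractional counts allowed).

    Useful for exact generate-then-refit round trips: the cohort curve is the
    model itself, with no sampling noise.
    """
    t = np.asarray(observation_times, dtype=float)
    lam = _background_rate(scenario, observation_length)
    q = scenario.virus_survival(t) * np.exp(-lam * t)
    return SurvivalSeries(
        times=tuple(t.tolist()),
        alive=tuple((n * q).tolist()),
        n_initial=n,
        dose=scenario.dose,
        dose_units=dose_units,
    )


def generate_bioassay(config: SyntheticConfig):
    """Simulate the full design and tabulate alive counts per observation time.

    Returns a :class:`biophase.io.BioassayDataset`.  One root seed spawns an
    independent child stream per (scenario, replicate), so adding a scenario
    never perturbs the draws of the others.  Identical configs give
    bit-identical datasets.
    """
    from .io import BioassayDataset  # local import to avoid a cycle

    root = np.random.SeedSequence(config.seed)
    scenario_seeds = root.spawn(len(config.scenarios))
    times = np.asarray(config.observation_times)
    window = config.observation_length

    records = []
    for scenario, sseed in zip(config.scenarios, scenario_seeds):
        for rep, rseed in enumerate(sseed.spawn(config.n_replicates), start=1):
            rng = np.random.default_rng(rseed)
            deaths = sample_death_times(
                scenario, config.n_per_replicate, rng, observation_length=window
            )
            alive = (deaths[None, :] > times[:, None]).sum(axis=1)
            for t, a in zip(times, alive):
                records.append(
                    {
                        "dose": scenario.dose,
                        "dose_units": config.dose_units,
                        "replicate": f"r{rep}",
                        "time": float(t),
                        "alive": int(a),
                        "n_initial": config.n_per_replicate,
                    }
                )
    import pandas as pd

    df = pd.DataFrame.from_records(records)
    return BioassayDataset(df, metadata={"observation_length": window, "seed": config.seed})
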