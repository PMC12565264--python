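import math

import numpy as np
import pytest

from biophase import (
    DoseScenario,
    SurvivalSeries,
    SyntheticConfig,
    TimeEffectFit,
    expected_survival_series,
    fit_time_effect,
    generate_bioassay,
    lt100,
    predict_q,
    survival_fractions,
    time_at_q2,
)
from biophase.errors import (
    ExtrapolationWarning,
    InsufficientDataError,
    InvalidInputError,
    NoKillError,
    NoMortalityError,
)


class TestSurvivalSeries:
    def test_fraction_examples(self):
        s = SurvivalSeries(times=(1, 2, 3, 4), alive=(10, 10, 5, 0), n_initial=10)
        assert [q for _, q in survival_fractions(s)] == [1.0, 1.0, 0.5, 0.0]
        s2 = SurvivalSeries(times=(1,), alive=(40,), n_initial=40)
        assert survival_fractions(s2) == [(1.0, 1.0)]
        s3 = SurvivalSeries(times=(1, 2, 3), alive=(30, 24, 12), n_initial=40)
        assert [q for _, q in survival_fractions(s3)] == [0.75, 0.6, 0.3]

    def test_validation(self):
        with pytest.raises(InvalidInputError):
            SurvivalSeries(times=(1, 2), alive=(5, 6), n_initial=10)  # increasing alive
        with pytest.raises(InvalidInputError):
            SurvivalSeries(times=(2, 1), alive=(5, 4), n_initial=10)  # non-monotone time
        with pytest.raises(InvalidInputError):
            SurvivalSeries(times=(1,), alive=(5,), n_initial=0)
        with pytest.raises(InvalidInputError):
            SurvivalSeries(times=(1,), alive=(11,), n_initial=10)


class TestFitTimeEffect:
    def test_worked_example_roundtrip(self, worked_example_series):
        fit = fit_time_effect(worked_example_series)
        assert fit.alpha1 == pytest.approx(2.3056, abs=1e-9)
        assert fit.beta1 == pytest.approx(0.232, abs=1e-9)
        assert fit.r2_segment == pytest.approx(1.0, abs=1e-9)
        assert fit.qr == 0.0
        assert fit.t0 == pytest.approx(5.0)  # last observed day with q = 1

    def test_slow_kill_with_plateau_roundtrip(self):
        # slow assay: shallow decline, plateau reached around day 60
        beta1, alpha1 = 0.014, 1.044
        qr = math.sqrt(alpha1 - beta1 * 60.0)
        sc = DoseScenario(dose=0.0, t0=(alpha1 - 1) / beta1, beta1=beta1, qr=qr)
        series = expected_survival_series(sc, np.arange(5.0, 81.0, 5.0), n=80)
        fit = fit_time_effect(series)
        assert fit.alpha1 == pytest.approx(1.044, abs=1e-9)
        assert fit.beta1 == pytest.approx(0.014, abs=1e-9)
        assert fit.qr == pytest.approx(qr, abs=1e-9)
        assert fit.r2_segment == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize(
        "t0, beta1, qr",
        [(5.6276, 0.232, 0.0), (3.0, 0.15, 0.3), (0.5, 0.08, 0.55), (2.0, 0.4, 0.0)],
    )
    def test_noiseless_recovery_property(self, t0, beta1, qr):
        """Generate-then-refit on noise-free expected counts is exact."""
        sc = DoseScenario(dose=10.0, t0=t0, beta1=beta1, qr=qr)
        times = np.arange(0.5, 16.0, 0.5)
        series = expected_survival_series(sc, times, n=100)
        fit = fit_time_effect(series)
        assert fit.alpha1 == pytest.approx(sc.alpha1, abs=1e-8)
        assert fit.beta1 == pytest.approx(beta1, abs=1e-8)
        assert fit.qr == pytest.approx(qr, abs=1e-8)
        assert fit.r2_segment == pytest.approx(1.0, abs=1e-8)

    def test_no_mortality_raises(self):
        s = SurvivalSeries(times=(1, 2, 3, 4, 5), alive=(40,) * 5, n_initial=40)
        with pytest.raises(NoMortalityError):
            fit_time_effect(s)

    def test_too_few_times_raises(self):
        s = SurvivalSeries(times=(1, 2, 3), alive=(10, 8, 6), n_initial=10)
        with pytest.raises(InsufficientDataError):
            fit_time_effect(s)

    def test_stochastic_beta1_recovery(self):
        """Binomial counting noise at bioassay scale (40 larvae/dose):
        median relative error of the decline rate stays under 10%."""
        b1, t0 = 0.232, (2.3056 - 1.0) / 0.232
        errs = []
        for seed in range(30):
            cfg = SyntheticConfig(
                scenarios=[DoseScenario(dose=50.0, t0=t0, beta1=b1, qr=0.0)],
                observation_times=list(range(1, 16)),
                n_per_replicate=10,
                n_replicates=4,
                seed=seed,
            )
            ds = generate_bioassay(cfg)
            fit = fit_time_effect(ds.series_for_dose(50.0))
            errs.append(abs(fit.beta1 - b1) / b1)
        assert np.median(errs) < 0.10


class TestDerivedTimes:
    @pytest.mark.parametrize(
        "alpha1, beta1, expected, tol",
        [
            (2.3056, 0.232, 9.93, 0.01),   # worked-example lethal time
            (1.345, 0.173, 7.78, 0.01),    # slow-assay Tr = a/b
            (1.0, 1.0, 1.0, 1e-12),
        ],
    )
    def test_lt100(self, alpha1, beta1, expected, tol):
        fit = TimeEffectFit.from_line(alpha1, beta1)
        assert lt100(fit) == pytest.approx(expected, abs=tol)

    def test_lt100_requires_kill(self):
        fit = TimeEffectFit(
            alpha1=1.0, beta1=0.0, t0=0, tr=math.inf, qr=1.0,
            r2_segment=float("nan"), n_segment_points=0,
        )
        with pytest.raises(NoKillError):
            lt100(fit)

    @pytest.mark.parametrize(
        "alpha1, beta1, level, expected",
        [
            (1.7379, 0.089, 1.0, 8.291),      # lag end, fast assay
            (1.451, 0.066, 1.0, 6.833333),    # lag end, slower assay
            (1.0, 0.5, 1.0, 0.0),             # no lag
        ],
    )
    def test_time_at_q2(self, alpha1, beta1, level, expected):
        fit = TimeEffectFit.from_line(alpha1, beta1)
        assert time_at_q2(fit, level) == pytest.approx(expected, abs=5e-4)

    def test_time_at_q2_level_zero_is_lt100(self):
        fit = TimeEffectFit.from_line(1.8, 0.21)
        assert time_at_q2(fit, 0.0) == pytest.approx(lt100(fit))

    def test_out_of_range_level_warns(self):
        fit = TimeEffectFit.from_line(1.8, 0.21, qr=0.5)
        with pytest.warns(ExtrapolationWarning):
            time_at_q2(fit, 0.1)  # below the plateau level qr² = 0.25

    def test_lag_end_before_lt100(self):
        fit = TimeEffectFit.from_line(2.1, 0.3)
        assert time_at_q2(fit, 1.0) <= lt100(fit)


class TestPredictQ:
    def test_lag_phase(self):
        fit = TimeEffectFit.from_line(2.3056, 0.232)
        assert predict_q(fit, 0.0) == 1.0
        assert predict_q(fit, fit.t0) == 1.0

    def test_zero_at_lt100(self):
        fit = TimeEffectFit.from_line(2.3056, 0.232)
        assert predict_q(fit, lt100(fit)) == pytest.approx(0.0, abs=1e-12)

    def test_dying_phase_value(self):
        fit = TimeEffectFit.from_line(2.3056, 0.232)
        assert predict_q(fit, 7.0) == pytest.approx(math.sqrt(0.6816), rel=1e-12)

    def test_negative_time_rejected(self):
        fit = TimeEffectFit.from_line(2.0, 0.2)
        with pytest.raises(InvalidInputError):
            predict_q(fit, -1.0)

    @pytest.mark.parametrize("qr", [0.0, 0.3, 0.7])
    def test_non_increasing_and_bounded(self, qr):
        fit = TimeEffectFit.from_line(1.9, 0.17, qr=qr)
        t = np.linspace(0, 30, 400)
        q = predict_q(fit, t)
        assert np.all(np.diff(q) <= 1e-12)
        assert np.all((q >= qr - 1e-12) & (q <= 1.0 + 1e-12))
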