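# biophase

Phase-transition survival models for insect bioassays.

## The problem

Entomopathogenic viruses (nucleopolyhedroviruses, cypoviruses) are screened
as biological control agents in dose–response bioassays: cohorts of larvae
ingest a known dose, survivors are counted daily, and virulence is summarised
by lethal times (LT100) and effective doses. The standard probit/logit/Weibull
route needs many serial dilutions and ignores a robust qualitative feature of
the data: for days after exposure *nobody* dies (the lag phase), then the
cohort declines, then dying stops with some fraction of survivors.

`biophase` implements an alternative in which the surviving fraction *q* is
treated as the order parameter of a second-order phase transition. The
squared survival fraction is piecewise linear in exposure time *T* at a
fixed dose *D*:

    q²(T) = 1              T ≤ T₀        (lag phase)
          = α₁ − β₁·T      T₀ < T ≤ T_r  (dying phase)
          = q_r²           T > T_r       (plateau)

and, symmetrically, piecewise linear in log-dose at a fixed observation
time:

    q²(D) = 1                    D ≤ D₀
          = α₂ − β₂·ln(D + 1)    D₀ < D < D_r
          = q_r²                 D ≥ D_r   (overkill doses)

β₁ = −∂q²/∂T and β₂ = −∂q²/∂ln(1+D) are susceptibilities; LT100 = α₁/β₁ is
where the fitted line reaches q² = 0. Because everything is linear after the
change of variable, ordinary least squares provides coefficients *and*
inference statistics, and two cross-relations (LT100 = A − B·ln(D+1),
T₀ = A₁ − B₁·ln(D+1), q_r = A₂ − B₂·ln(D+1)) fall out of the same machinery.

The headline shortcut: across doses, (1/T₀, q_r) points lie on a common
line, and a mortality-free control observed for T days contributes the point
(1/T, 1) for free. A *single* treated dose therefore calibrates the line
Q_r = slope/T₀ + intercept, predicting effectiveness at every other dose
from its lag duration alone.

The package provides, for each piece of this pipeline, typed results with
full OLS inference (`LinearFitStats`), an exact breakpoint search for the
three-phase fit, a single-dose calibration module, a two-minima correction
for dose-independent background mortality, and an individual-level
death-time simulator for parameter-recovery studies.

## Worked example

Fit a fast baculovirus assay (40 larvae at 50 OBs/larva, counted daily):

```python
from biophase import DoseScenario, expected_survival_series, fit_time_effect, lt100

scenario = DoseScenario(dose=50.0, t0=(2.3056 - 1.0) / 0.232, beta1=0.232, qr=0.0)
series = expected_survival_series(scenario, range(1, 13), n=40)
fit = fit_time_effect(series)
print(fit.alpha1, fit.beta1, lt100(fit))
```

Running `python examples/fit_time_course.py` prints:

```
dying-phase line : q^2 = 2.3056 - 0.232 T  (R^2 = 1.000)
observed lag end : 5.0 d   fitted lag end: 5.63 d
plateau survival : q_r = 0.000
lethal time LT100: 9.94 d
```

Read: no larva died through day 5; from day 6 the squared survival fraction
fell by 0.232 per day; the line reaches zero at 9.94 days, the time by which
the whole cohort is dead (q_r = 0 — total kill, so LT100 is an observed,
not extrapolated, quantity).

The other capabilities each have a short narrative script under
`examples/`: `dose_response_curve.py` (dose–effect line, overkill boundary,
dose–time relation), `single_dose_calibration.py` (the one-experiment
shortcut and its per-dose errors), `simulate_bioassay.py` (individual-level
simulation and parameter recovery), `background_correction.py` (two-minima
control-mortality correction).

## Command line

A thin CLI wraps the same functions:

```sh
biophase simulate config.json --out assay.csv   # synthetic bioassay CSV
biophase fit-time assay.csv                     # per-dose three-phase fits
biophase fit-dose assay.csv --background-correct
biophase calibrate assay.csv --control-length 15 --calibration-dose 1e6
```

The bioassay CSV schema is long-format with columns
`dose,dose_units,replicate,time,alive,n_initial` and optional `# key = value`
metadata lines above the header.

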