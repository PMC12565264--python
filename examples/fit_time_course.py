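"""Fit the three-phase time-effect model to one dose's survival curve.

Builds a noise-free 40-larva cohort from the published dying-phase line
q² = 2.3056 − 0.232·T (a fast nucleopolyhedrovirus assay at 50 OBs/larva),
refits the model from the daily counts, and derives the lethal time.
"""

from biophase import DoseScenario, expected_survival_series, fit_time_effect, lt100, time_at_q2

scenario = DoseScenario(dose=50.0, t0=(2.3056 - 1.0) / 0.232, beta1=0.232, qr=0.0)
series = expected_survival_series(scenario, range(1, 13), n=40)

fit = fit_time_effect(series)
print(f"dying-phase line : q^2 = {fit.alpha1:.4f} - {fit.beta1:.3f} T  (R^2 = {fit.r2_segment:.3f})")
print(f"observed lag end : {fit.t0:.1f} d   fitted lag end: {time_at_q2(fit, 1.0):.2f} d")
print(f"plateau survival : q_r = {fit.qr:.3f}")
print(f"lethal time LT100: {lt100(fit):.2f} d")
# The cohort stops dying once the line reaches q^2 = 0: every larva is dead
# just before day 10, so LT100 ~ 9.94 d and q_r = 0 (total kill).
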