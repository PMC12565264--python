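"""Dose-effect fit: end-of-experiment survival against log-dose.

Five serial dilutions with graded survival give the line
q² = α2 − β2·ln(D+1); its boundaries are the largest harmless dose D0 and
the overkill threshold Dr where the line reaches q = 0.
"""

import numpy as np

from biophase import critical_log_dose, fit_dose_effect, fit_dose_time, log_dose

doses = [10.0, 100.0, 1e3, 1e4, 1e5]
q_end = [0.92, 0.83, 0.72, 0.55, 0.38]  # fraction alive at the end of the assay

fit = fit_dose_effect(doses, q_end)
print(f"dose-effect line : q^2 = {fit.alpha2:.3f} - {fit.beta2:.4f} ln(D+1)  "
      f"(R^2 = {fit.line_fit.r2:.3f})")
print(f"overkill boundary: ln(Dr+1) = {fit.ln_dr:.2f}  (Dr ~ {fit.dr:.3g})")
print(f"same boundary via critical_log_dose: {critical_log_dose(fit):.2f}")

# dose-time relation: lethal time shrinks with log-dose
lt100s = [14.2, 12.9, 11.5, 10.4, 8.9]
rel = fit_dose_time(doses, lt100s)
print(f"dose-time line   : LT100 = {rel.a_coef:.2f} - {rel.b_coef:.3f} ln(D+1)  "
      f"(slope p = {rel.stats.p_slope:.4f})")
print(f"predicted LT100 at D = 1e6: {rel.predict(1e6):.2f} d  (ln(D+1) = {log_dose(1e6):.2f})")
# Higher doses kill faster: ~0.45 d less per ln-dose unit here.
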