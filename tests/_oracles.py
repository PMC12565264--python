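"""Independent brute-force oracles used by the test suite.

Deliberately written from the explicit normal-equation sums, not via any
linear-algebra or statistics library, so they stay independent of the
implementation path they check.
"""

import math


def ols_oracle(x, y):
    """Closed-form simple regression: slope, intercept, SEs, R² from Σ formulas."""
    n = len(x)
    sx = sum(x)
    sy = sum(y)
    sxx = sum(v * v for v in x)
    sxy = sum(a * b for a, b in zip(x, y))
    denom = n * sxx - sx * sx
    slope = (n * sxy - sx * sy) / denom
    intercept = (sy - slope * sx) / n
    resid = [yi - (intercept + slope * xi) for xi, yi in zip(x, y)]
    rss = sum(r * r for r in resid)
    ybar = sy / n
    tss = sum((yi - ybar) ** 2 for yi in y)
    r2 = 1.0 - rss / tss if tss > 0 else math.nan
    sxx_c = sxx - sx * sx / n
    if n > 2:
        s2 = rss / (n - 2)
        se_slope = math.sqrt(s2 / sxx_c)
        se_intercept = math.sqrt(s2 * (1.0 / n + (sx / n) ** 2 / sxx_c))
    else:
        se_slope = math.nan
        se_intercept = math.nan
    return {
        "slope": slope,
        "intercept": intercept,
        "se_slope": se_slope,
        "se_intercept": se_intercept,
        "r2": r2,
        "rss": rss,
    }
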