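"""Independent brute-force statistical oracles used only by the tests.

These re-derive Welch's t-test and simple OLS from first principles: plain
sums for the statistics and a numerically integrated Student-t density
(math.gamma + quadrature) for the tail probabilities, so no formula is shared
with the package's scipy-backed implementations.
"""

import math

import numpy as np
from scipy.integrate import quad


def t_density(u: float, df: float) -> float:
    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
    return c * (1 + u * u / df) ** (-(df + 1) / 2)


def two_sided_t_pvalue(t: float, df: float) -> float:
    """2 * upper-tail mass beyond |t|, via quadrature of the density."""
    tail, _ = quad(t_density, abs(t), np.inf, args=(df,))
    return min(1.0, 2.0 * tail)


def welch_oracle(x, y):
    """Returns (t, satterthwaite_df, two_sided_p) from explicit sums."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    nx, ny = len(x), len(y)
    mx = sum(x) / nx
    my = sum(y) / ny
    vx = sum((v - mx) ** 2 for v in x) / (nx - 1)
    vy = sum((v - my) ** 2 for v in y) / (ny - 1)
    se2 = vx / nx + vy / ny
    t = (mx - my) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return t, df, two_sided_t_pvalue(t, df)


def ols_oracle(x, y):
    """Simple linear regression of y on x via explicit normal equations.

    Returns (slope, intercept, r2, adjusted_r2, slope_p).
    """
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxx = sum((v - mx) ** 2 for v in x)
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    syy = sum((v - my) ** 2 for v in y)
    slope = sxy / sxx
    intercept = my - slope * mx
    ss_res = sum((b - (intercept + slope * a)) ** 2 for a, b in zip(x, y))
    r2 = 1.0 - ss_res / syy if syy > 0 else 0.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    if ss_res == 0.0:
        return slope, intercept, r2, adj, 0.0
    se_slope = math.sqrt(ss_res / (n - 2) / sxx)
    t = slope / se_slope
    return slope, intercept, r2, adj, two_sided_t_pvalue(t, n - 2)
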