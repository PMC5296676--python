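"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the library code paths (and scipy.stats.linregress)
so they can serve as cross-checks: plain sum-formula normal equations and
textbook interval formulas.
"""

import math


def normal_equations_ols(x, y, alpha=0.05):
    """Straight-line least squares from the raw sum formulas."""
    from scipy.stats import t as t_dist

    n = len(x)
    sx = sum(x)
    sy = sum(y)
    sxy = sum(xi * yi for xi, yi in zip(x, y))
    sxx_raw = sum(xi * xi for xi in x)
    denom = n * sxx_raw - sx * sx
    slope = (n * sxy - sx * sy) / denom
    intercept = (sy - slope * sx) / n
    resid = [yi - (intercept + slope * xi) for xi, yi in zip(x, y)]
    sse = sum(r * r for r in resid)
    resid_sd = math.sqrt(sse / (n - 2))
    x_mean = sx / n
    sxx = sum((xi - x_mean) ** 2 for xi in x)
    se_slope = resid_sd / math.sqrt(sxx)
    se_intercept = resid_sd * math.sqrt(1.0 / n + x_mean**2 / sxx)
    t_crit = float(t_dist.ppf(1 - alpha / 2, n - 2))
    return {
        "slope": slope,
        "intercept": intercept,
        "resid_sd": resid_sd,
        "se_slope": se_slope,
        "se_intercept": se_intercept,
        "sxx": sxx,
        "x_mean": x_mean,
        "t_crit": t_crit,
    }


def sample_moments(values):
    """Biased-moment skewness and excess kurtosis from first principles."""
    n = len(values)
    mean = sum(values) / n
    m2 = sum((v - mean) ** 2 for v in values) / n
    m3 = sum((v - mean) ** 3 for v in values) / n
    m4 = sum((v - mean) ** 4 for v in values) / n
    return m3 / m2**1.5, m4 / m2**2 - 3.0
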