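"""Bundled reference tables.

Currently one dataset: published linear calibration regressions for daily
milk yields of US Holsteins estimated from single (AM or PM) milkings,
stratified by month in milk and milking session.  It illustrates the linear
error model at work on a real trait: the estimation procedure inflates the
phenotypic variance (K = var_obs / var_true > 1), and the stratified
regressions (alpha, beta, error variance) calibrate it back.
"""

from __future__ import annotations

import pandas as pd

# Columns: month in milk, session, true daily-yield variance (kg^2), variance
# of the estimated yields (kg^2), inflation ratio K, calibration intercept
# (kg), slope, and error variance (kg^2).
_DMY_CALIBRATION_ROWS = [
    # month, session, var_true, var_obs, K,  alpha,  beta,  error_variance
    (1, "morning", 111.2, 119.3, 1.07, 0.238, 0.979, 12.6),
    (1, "evening", 111.2, 125.8, 1.13, -0.133, 1.003, 13.9),
    (2, "morning", 99.8, 103.6, 1.04, 1.234, 0.961, 11.5),
    (2, "evening", 99.8, 113.2, 1.13, -0.499, 1.004, 12.5),
    (3, "morning", 82.6, 90.7, 1.10, 0.110, 0.986, 10.4),
    (3, "evening", 82.6, 90.0, 1.09, 0.640, 0.980, 10.6),
    (4, "morning", 69.0, 75.2, 1.09, 2.488, 0.936, 14.7),
    (4, "evening", 69.0, 89.7, 1.30, -1.843, 1.032, 16.2),
    (5, "morning", 62.8, 69.1, 1.10, 1.682, 0.955, 11.8),
    (5, "evening", 62.8, 77.7, 1.24, -1.242, 1.017, 12.7),
    (6, "morning", 54.0, 60.9, 1.13, 1.343, 0.963, 10.9),
    (6, "evening", 54.0, 67.8, 1.26, -1.359, 1.022, 11.5),
    (7, "morning", 55.3, 63.5, 1.15, 0.767, 0.970, 11.5),
    (7, "evening", 55.3, 67.4, 1.22, -0.396, 1.000, 12.1),
    (8, "morning", 54.9, 63.2, 1.15, 0.272, 0.986, 9.85),
    (8, "evening", 54.9, 63.6, 1.16, 0.003, 0.984, 10.3),
    (9, "morning", 52.8, 62.0, 1.17, -0.568, 1.018, 7.23),
    (9, "evening", 52.8, 56.9, 1.08, 0.720, 0.962, 8.04),
    (10, "morning", 59.0, 62.5, 1.06, 0.703, 0.965, 7.67),
    (10, "evening", 59.0, 69.0, 1.17, -0.515, 1.013, 8.52),
    (11, "morning", 62.4, 73.1, 1.17, -0.658, 1.020, 8.23),
    (11, "evening", 62.4, 65.9, 1.06, 0.659, 0.961, 8.22),
    (12, "morning", 67.3, 73.1, 1.09, 0.263, 0.978, 8.74),
    (12, "evening", 67.3, 75.6, 1.12, -0.015, 0.993, 9.25),
]


def holstein_dmy_calibration() -> pd.DataFrame:
    """Published daily-milk-yield calibration regressions (24 strata).

    Returns a DataFrame with columns ``month, session, var_true, var_obs, K,
    alpha, beta, error_variance``.  The rows satisfy (up to published
    rounding) the observed-variance identity of the linear error model,
    ``var_obs ~= beta**2 * var_true + error_variance``, and
    ``K = var_obs / var_true``.
    """
    return pd.DataFrame(
        _DMY_CALIBRATION_ROWS,
        columns=[
            "month",
            "session",
            "var_true",
            "var_obs",
            "K",
            "alpha",
            "beta",
            "error_variance",
        ],
    )
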