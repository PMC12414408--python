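"""Linear measurement-error calibration for continuous phenotypes.

The classical linear error model relates an error-prone measurement ``y*``
to the true phenotype ``y``:

    y* = alpha + beta * y + eps,    eps ~ N(0, sigma_eps2)

Fitted from a double sample (records measured both ways), the calibration
``(alpha, beta, sigma_eps2)`` back-adjusts quantities estimated on the
error-prone scale:

* measurements:          y_hat  = (y* - alpha) / beta
* random effects (BLUP): u_hat  = u*_hat / beta
* fixed effects:         b_hat  = (X'X)^-1 X'(X b*_hat - 1 alpha) / beta
* variance components:   sigma_u2 = sigma_u*2 / beta^2
                         sigma_e2 = (sigma_e*2 - sigma_eps2) / beta^2

The observed-scale variances satisfy sigma_u*2 = beta^2 sigma_u2 and
sigma_e*2 = beta^2 sigma_e2 + sigma_eps2, which the adjustments invert.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PairedSample:
    """Paired error-free / error-prone measurements, optionally stratified.

    ``group`` labels strata fitted separately (e.g. lactation month x
    AM/PM milking session); ``None`` pools all records.
    """

    y_true: np.ndarray
    y_obs: np.ndarray
    group: np.ndarray | None = None

    def __post_init__(self) -> None:
        yt = np.asarray(self.y_true, dtype=float)
        yo = np.asarray(self.y_obs, dtype=float)
        if yt.shape != yo.shape or yt.ndim != 1:
            raise ValueError("y_true and y_obs must be 1-D arrays of equal length")
        object.__setattr__(self, "y_true", yt)
        object.__setattr__(self, "y_obs", yo)
        if self.group is not None:
            g = np.asarray(self.group)
            if g.shape != yt.shape:
                raise ValueError("group must match the sample length")
            object.__setattr__(self, "group", g)

    @property
    def n(self) -> int:
        return self.y_true.size


@dataclass(frozen=True)
class CalibrationFit:
    """Least-squares fit of the linear error model within one stratum.

    ``var_true``/``var_obs`` are the sample variances of the paired values
    (when fitted from data), whose ratio K = var_obs/var_true measures the
    variance inflation of the error-prone instrument.
    """

    alpha: float
    beta: float
    error_variance: float
    n: int
    group: str | None = None
    var_true: float | None = None
    var_obs: float | None = None

    def __post_init__(self) -> None:
        if self.error_variance < 0:
            raise ValueError("error_variance must be >= 0")
        if not np.isfinite(self.beta):
            raise ValueError("beta must be finite")

    def require_invertible(self) -> None:
        if self.beta == 0.0:
            raise ZeroDivisionError("beta = 0: calibration is not invertible")


IDENTITY_FIT = CalibrationFit(alpha=0.0, beta=1.0, error_variance=0.0, n=0)


@dataclass(frozen=True)
class VarianceComponents:
    """Additive genetic, residual, and measurement-error variances."""

    sigma_u2: float
    sigma_e2: float
    sigma_eps2: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sigma_u2", "sigma_e2", "sigma_eps2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def heritability(self) -> float:
        return self.sigma_u2 / (self.sigma_u2 + self.sigma_e2)

    @property
    def residual_total(self) -> float:
        """Residual variance seen by a model ignoring measurement error."""
        return self.sigma_e2 + self.sigma_eps2


def _fit_one(y_true: np.ndarray, y_obs: np.ndarray, group=None) -> CalibrationFit:
    n = y_true.size
    if n < 3:
        raise ValueError(f"need >= 3 records per stratum, got {n}")
    if np.ptp(y_true) == 0.0:
        raise ValueError("y_true is constant: calibration regression is degenerate")
    X = np.column_stack([np.ones(n), y_true])
    coef, *_ = np.linalg.lstsq(X, y_obs, rcond=None)
    resid = y_obs - X @ coef
    # n - 2 denominator: unbiased residual variance for a 2-parameter line
    sigma_eps2 = float(resid @ resid / (n - 2))
    return CalibrationFit(
        alpha=float(coef[0]),
        beta=float(coef[1]),
        error_variance=sigma_eps2,
        n=n,
        group=None if group is None else str(group),
        var_true=float(np.var(y_true, ddof=1)),
        var_obs=float(np.var(y_obs, ddof=1)),
    )


def fit_calibration(sample: PairedSample) -> CalibrationFit | dict[str, CalibrationFit]:
    """Fit y_obs on y_true by least squares, one fit per stratum.

    Returns a single :class:`CalibrationFit` for an unstratified sample, or a
    dict keyed by stratum label.  The regression direction is observed on
    true (classical error model); strata are fitted independently.
    """
    if sample.group is None:
        return _fit_one(sample.y_true, sample.y_obs)
    fits: dict[str, CalibrationFit] = {}
    for g in pd.unique(sample.group):
        mask = sample.group == g
        fits[str(g)] = _fit_one(sample.y_true[mask], sample.y_obs[mask], group=g)
    return fits


def variance_ratio(var_obs: float, var_true: float) -> float:
    """Inflation ratio K = sigma_y*2 / sigma_y2 of observed to true variance."""
    if var_true <= 0:
        raise ValueError(f"var_true must be > 0, got {var_true}")
    return var_obs / var_true


def apply_calibration(y_obs: np.ndarray, fit: CalibrationFit) -> np.ndarray:
    """Back-transform error-prone measurements: (y* - alpha) / beta."""
    fit.require_invertible()
    return (np.asarray(y_obs, dtype=float) - fit.alpha) / fit.beta


def calibrate_effects(
    b_star: np.ndarray,
    u_star: np.ndarray,
    fit: CalibrationFit,
    X: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Back-adjust effect estimates obtained on the error-prone scale.

    ``u_hat = u*/beta``; ``b_hat = (X'X)^-1 X'(X b* - 1 alpha)/beta``.  When
    ``X`` is omitted (or one-hot with full rank) the fixed-effect projection
    reduces to ``(b* - alpha)/beta`` elementwise.
    """
    fit.require_invertible()
    b_star = np.asarray(b_star, dtype=float)
    u_star = np.asarray(u_star, dtype=float)
    u_hat = u_star / fit.beta
    if X is None:
        b_hat = (b_star - fit.alpha) / fit.beta
    else:
        X = np.asarray(X, dtype=float)
        ones = np.ones(X.shape[0])
        target = X @ b_star - ones * fit.alpha
        b_hat, *_ = np.linalg.lstsq(X, target, rcond=None)
        b_hat = b_hat / fit.beta
    return b_hat, u_hat


def calibrate_variances(
    sigma_u2_star: float, sigma_e2_star: float, fit: CalibrationFit
) -> VarianceComponents:
    """Back-adjust variance components estimated on the error-prone scale.

    ``sigma_u2 = sigma_u*2/beta^2``; ``sigma_e2 = (sigma_e*2 - sigma_eps2)/beta^2``.
    A residual smaller than the measurement-error variance clamps sigma_e2 to
    zero with a warning.
    """
    fit.require_invertible()
    if sigma_u2_star < 0 or sigma_e2_star < 0:
        raise ValueError("starred variance components must be >= 0")
    sigma_u2 = sigma_u2_star / fit.beta**2
    net = sigma_e2_star - fit.error_variance
    if net < 0:
        warnings.warn(
            f"observed residual variance {sigma_e2_star:.6g} is below the "
            f"measurement-error variance {fit.error_variance:.6g}; residual "
            "variance clamped to 0",
            stacklevel=2,
        )
        net = 0.0
    return VarianceComponents(
        sigma_u2=sigma_u2,
        sigma_e2=net / fit.beta**2,
        sigma_eps2=fit.error_variance,
    )


def read_paired_sample(path) -> PairedSample:
    """Read a paired-sample CSV with columns ``id,group,y_true,y_obs``.

    ``group`` is optional; extra columns are ignored.
    """
    df = pd.read_csv(path, comment="#")
    if not {"y_true", "y_obs"}.issubset(df.columns):
        raise ValueError(f"paired sample needs columns y_true,y_obs; got {list(df.columns)}")
    group = df["group"].to_numpy() if "group" in df.columns else None
    return PairedSample(
        y_true=df["y_true"].to_numpy(float),
        y_obs=df["y_obs"].to_numpy(float),
        group=group,
    )


def fits_to_frame(fits: dict[str, CalibrationFit] | CalibrationFit) -> pd.DataFrame:
    """Tabulate calibration fits (one row per stratum) for export.

    Columns follow the conventional calibration-table layout: stratum, the
    true and observed variances with their ratio K, the intercept and slope,
    and the error variance.
    """
    if isinstance(fits, CalibrationFit):
        fits = {fits.group or "all": fits}
    rows = [
        {
            "group": g,
            "n": f.n,
            "var_true": f.var_true,
            "var_obs": f.var_obs,
            "K": None if f.var_true in (None, 0) else f.var_obs / f.var_true,
            "alpha": f.alpha,
            "beta": f.beta,
            "error_variance": f.error_variance,
        }
        for g, f in fits.items()
    ]
    return pd.DataFrame(rows)
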