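"""Misclassification algebra for binary traits under double sampling.

A binary phenotype recorded with an error-prone instrument (an "unofficial
test") misclassifies some animals.  With a double-sampling design — an
internal validation subset scored by both the error-free and the error-prone
method — the 2x2 cross-classification yields:

* sensitivity  ``pi_1|1 = P(y* = 1 | y = 1)`` and
  specificity  ``pi_0|0 = P(y* = 0 | y = 0)`` (classical error direction);
* reclassification (predictive) probabilities
  ``lambda_1|1 = P(y = 1 | y* = 1)`` and ``lambda_0|0 = P(y = 0 | y* = 0)``
  (Berkson direction).

Either pair inverts the bias of the naive incidence estimate: the expected
observed incidence is ``E[q*] = q*sens + (1-q)*(1-spec)``, so

    q = (q* - (1 - spec)) / (sens + spec - 1)          (by error rates)
    q = q* (l11 + l00 - 1) + (1 - l00)                 (by reclassification)

Adjusted incidences are clamped to [0, 1]; an uninformative test
(``sens + spec = 1``) makes the first route non-identifiable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd


class NonIdentifiableError(ValueError):
    """Sensitivity + specificity = 1: the true incidence cannot be recovered."""


@dataclass(frozen=True)
class ValidationCounts:
    """2x2 counts from the internal validation set of a double sample.

    ``nXY`` is the number of animals with true status X and observed status Y.
    """

    n00: int
    n01: int
    n10: int
    n11: int

    def __post_init__(self) -> None:
        for name in ("n00", "n01", "n10", "n11"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    @property
    def total(self) -> int:
        return self.n00 + self.n01 + self.n10 + self.n11

    @property
    def validation_incidence(self) -> float:
        """True incidence in the validation set, (n10 + n11) / total."""
        return (self.n10 + self.n11) / self.total


@dataclass(frozen=True)
class ErrorRates:
    """Sensitivity pi_1|1 and specificity pi_0|0 of the error-prone test."""

    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @property
    def false_negative(self) -> float:
        """pi_0|1 = 1 - sensitivity."""
        return 1.0 - self.sensitivity

    @property
    def false_positive(self) -> float:
        """pi_1|0 = 1 - specificity."""
        return 1.0 - self.specificity


@dataclass(frozen=True)
class ReclassRates:
    """Predictive probabilities lambda_1|1 = P(y=1|y*=1), lambda_0|0 = P(y=0|y*=0)."""

    lambda11: float
    lambda00: float

    def __post_init__(self) -> None:
        for name in ("lambda11", "lambda00"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class IncidenceEstimate:
    """An incidence proportion with its provenance.

    ``delta`` is the shift q* - q between the observed and the (estimated)
    true incidence; ``clamped`` flags an adjustment that fell outside [0, 1]
    and was truncated.
    """

    q: float
    delta: float
    source: str  # observed | adjusted-by-misclass | adjusted-by-reclass
    clamped: bool = False


def rates_from_validation(c: ValidationCounts) -> ErrorRates:
    """Sensitivity and specificity from validation counts (row conditionals)."""
    if c.n11 + c.n10 == 0:
        raise ValueError("no true positives in validation set: sensitivity undefined")
    if c.n00 + c.n01 == 0:
        raise ValueError("no true negatives in validation set: specificity undefined")
    return ErrorRates(
        sensitivity=c.n11 / (c.n11 + c.n10),
        specificity=c.n00 / (c.n00 + c.n01),
    )


def reclass_from_validation(c: ValidationCounts) -> ReclassRates:
    """Reclassification probabilities from validation counts (column conditionals)."""
    if c.n11 + c.n01 == 0:
        raise ValueError("no observed positives in validation set: lambda11 undefined")
    if c.n00 + c.n10 == 0:
        raise ValueError("no observed negatives in validation set: lambda00 undefined")
    return ReclassRates(
        lambda11=c.n11 / (c.n11 + c.n01),
        lambda00=c.n00 / (c.n00 + c.n10),
    )


def reclass_from_rates(r: ErrorRates, q: float) -> ReclassRates:
    """Convert error rates to reclassification rates at true incidence ``q`` (Bayes)."""
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"incidence must be in [0, 1], got {q}")
    p_obs_pos = r.sensitivity * q + r.false_positive * (1.0 - q)
    p_obs_neg = r.false_negative * q + r.specificity * (1.0 - q)
    if p_obs_pos == 0.0:
        raise ZeroDivisionError("P(y*=1) = 0: lambda11 undefined")
    if p_obs_neg == 0.0:
        raise ZeroDivisionError("P(y*=0) = 0: lambda00 undefined")
    return ReclassRates(
        lambda11=r.sensitivity * q / p_obs_pos,
        lambda00=r.specificity * (1.0 - q) / p_obs_neg,
    )


def expected_observed_incidence(q: float, r: ErrorRates) -> float:
    """E[q*] = q*sens + (1-q)*(1-spec): marginal rate of observed positives."""
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"incidence must be in [0, 1], got {q}")
    return q * r.sensitivity + (1.0 - q) * r.false_positive


def naive_bias(q: float, r: ErrorRates) -> float:
    """Bias E[q*] - q of the naive incidence estimator."""
    return q * (r.sensitivity + r.specificity - 2.0) + r.false_positive


def variance_deviation(q: float, delta: float) -> float:
    """Var(y*) - Var(y) for Bernoulli phenotypes when q* = q + delta.

    Equals ``delta - 2 q delta - delta**2``, i.e. the shift in binomial
    variance caused by misclassification.
    """
    q_star = q + delta
    if not 0.0 <= q <= 1.0 or not 0.0 <= q_star <= 1.0:
        raise ValueError(f"q and q + delta must be in [0, 1]; got q={q}, delta={delta}")
    return delta - 2.0 * q * delta - delta**2


def _clamp01(x: float) -> tuple[float, bool]:
    if x < 0.0:
        return 0.0, True
    if x > 1.0:
        return 1.0, True
    return x, False


def adjust_incidence_by_rates(q_obs: float, r: ErrorRates) -> IncidenceEstimate:
    """Invert the naive-incidence bias using sensitivity and specificity.

    ``q = (q_obs - (1 - spec)) / (sens + spec - 1)``, clamped to [0, 1] with a
    warning.  Raises :class:`NonIdentifiableError` when ``sens + spec = 1``.
    """
    if not 0.0 <= q_obs <= 1.0:
        raise ValueError(f"observed incidence must be in [0, 1], got {q_obs}")
    denom = r.sensitivity + r.specificity - 1.0
    if denom == 0.0:
        raise NonIdentifiableError(
            "sensitivity + specificity = 1: observed incidence carries no "
            "information about the true incidence"
        )
    if abs(denom) < 0.05:
        warnings.warn(
            f"sensitivity + specificity - 1 = {denom:.4g}: adjustment is "
            "nearly non-identifiable and numerically unstable",
            stacklevel=2,
        )
    q, clamped = _clamp01((q_obs - r.false_positive) / denom)
    if clamped:
        warnings.warn(
            f"adjusted incidence fell outside [0, 1] and was clamped to {q}",
            stacklevel=2,
        )
    return IncidenceEstimate(
        q=q, delta=q_obs - q, source="adjusted-by-misclass", clamped=clamped
    )


def adjust_incidence_by_reclass(q_obs: float, l: ReclassRates) -> IncidenceEstimate:
    """Adjust the observed incidence with reclassification (predictive) rates.

    ``q = q_obs (l11 + l00 - 1) + (1 - l00)``, clamped to [0, 1].
    """
    if not 0.0 <= q_obs <= 1.0:
        raise ValueError(f"observed incidence must be in [0, 1], got {q_obs}")
    q, clamped = _clamp01(q_obs * (l.lambda11 + l.lambda00 - 1.0) + (1.0 - l.lambda00))
    if clamped:
        warnings.warn(
            f"adjusted incidence fell outside [0, 1] and was clamped to {q}",
            stacklevel=2,
        )
    return IncidenceEstimate(
        q=q, delta=q_obs - q, source="adjusted-by-reclass", clamped=clamped
    )


def read_counts(path) -> tuple[ValidationCounts, tuple[int, int] | None]:
    """Read a counts CSV with columns ``n00,n01,n10,n11`` (+ optional ``t0,t1``).

    ``t0``/``t1`` are observed-negative/-positive counts in the test-only set;
    returns them as a second element when present.
    """
    df = pd.read_csv(path, comment="#")
    required = {"n00", "n01", "n10", "n11"}
    if not required.issubset(df.columns):
        raise ValueError(f"counts file must have columns n00,n01,n10,n11; got {list(df.columns)}")
    row = df.iloc[0]
    counts = ValidationCounts(
        n00=int(row["n00"]), n01=int(row["n01"]), n10=int(row["n10"]), n11=int(row["n11"])
    )
    test = None
    if {"t0", "t1"}.issubset(df.columns):
        test = (int(row["t0"]), int(row["t1"]))
    return counts, test


def double_sampling_report(
    counts: ValidationCounts, test_counts: tuple[int, int] | None = None
) -> dict:
    """Full double-sampling calibration summary from a 2x2 validation table.

    Computes error and reclassification rates, the overall observed incidence
    (validation + test sets when test counts are given), and the adjusted
    incidence by both routes.  Numbers are reported at full precision;
    round for display.
    """
    rates = rates_from_validation(counts)
    reclass = reclass_from_validation(counts)
    n_obs_pos = counts.n01 + counts.n11
    n_total = counts.total
    if test_counts is not None:
        n_obs_pos += test_counts[1]
        n_total += test_counts[0] + test_counts[1]
    q_obs = n_obs_pos / n_total
    by_rates = adjust_incidence_by_rates(q_obs, rates)
    by_reclass = adjust_incidence_by_reclass(q_obs, reclass)
    return {
        "n_validation": counts.total,
        "n_total": n_total,
        "sensitivity": rates.sensitivity,
        "specificity": rates.specificity,
        "lambda11": reclass.lambda11,
        "lambda00": reclass.lambda00,
        "observed_incidence": q_obs,
        "validation_incidence": counts.validation_incidence,
        "adjusted_incidence_by_rates": by_rates.q,
        "adjusted_incidence_by_reclass": by_reclass.q,
        "clamped": by_rates.clamped or by_reclass.clamped,
    }
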