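"""Bayesian liability threshold animal model with asymmetric misclassification.

The observed binary status ``y*`` arises from a latent liability
``eta = x'b + z'u + e`` with residual variance fixed at 1: the true status is
``y = 1`` iff ``eta > tau``, where ``tau = Phi^-1(1 - q)`` for incidence
``q``.  Misclassification with sensitivity ``pi_1|1`` and specificity
``pi_0|0`` (allowed to differ) links ``y*`` to ``y``, giving per-record
likelihood contributions

    p(y* = 1) = pi_1|1 P1 + (1 - pi_0|0)(1 - P1)
    p(y* = 0) = (1 - pi_1|1) P1 + pi_0|0 (1 - P1)

with ``P1 = 1 - Phi(tau - x'b - z'u)``.  These two contributions sum to 1
for every record, and with a perfect instrument (rates = (1, 1)) the model
reduces to the standard threshold model.  With equal false-positive and
false-negative rates it coincides with the single-parameter
misclassification threshold model.

MCMC uses data augmentation: per record, the true status (hence the
misclassification indicator ``delta_i = [y_i != y*_i]``) is drawn from its
two-state posterior, then the liability from the correspondingly truncated
normal; ``b``, ``u`` and ``sigma_u2`` follow the same blocked conjugate
updates as the linear sampler.  Sensitivity and specificity can be fixed or
estimated with Beta priors (rejection-truncated to ``pi_1|1 + pi_0|0 > 1``
to prevent label switching).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .misclassification import ErrorRates, adjust_incidence_by_rates
from .mixed_model import ModelMatrices, _eigen_basis, _sample_variance
from .pedigree import RelationshipMatrix
from .results import PosteriorSummary, summarize_chain

PERFECT_RATES = ErrorRates(sensitivity=1.0, specificity=1.0)

_TINY = 1e-300


@dataclass(frozen=True)
class ThresholdConfig:
    """Settings for :func:`gibbs_threshold`.

    ``tau`` may be given directly, derived from ``incidence``, or left to the
    data (observed incidence, adjusted for the known error rates).  Set
    ``estimate_rates=True`` to sample sensitivity/specificity with
    ``Beta(*beta_prior)`` priors instead of fixing them.
    """

    tau: float | None = None
    incidence: float | None = None
    error_rates: ErrorRates = PERFECT_RATES
    estimate_rates: bool = False
    beta_prior: tuple[float, float] = (2.0, 1.0)
    iterations: int = 100_000
    burn_in: int = 20_000
    thin: int = 10
    seed: int = 0
    nu_u: float = 4.0
    prior_h2: float = 0.25
    # Fixed effects need a proper prior here: with a flat prior the probit
    # likelihood integrated over b grows like sigma_u^p, making the joint
    # posterior of (b, sigma_u2) improper and the chain drift without bound.
    sigma_b2: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("burn_in must satisfy 0 <= burn_in < iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.estimate_rates and min(self.beta_prior) <= 0:
            raise ValueError("Beta prior parameters must be > 0")
        if self.incidence is not None and not 0 < self.incidence < 1:
            raise ValueError("incidence must be in (0, 1)")
        if self.sigma_b2 <= 0:
            raise ValueError("sigma_b2 must be > 0")


@dataclass(frozen=True)
class LiabilityRecord:
    """One record's observed status and current linear predictor."""

    observed_status: int
    linear_predictor: float
    record_id: str = ""

    def __post_init__(self) -> None:
        if self.observed_status not in (0, 1):
            raise ValueError("observed_status must be 0 or 1")


@dataclass
class ChainState:
    """Mutable sampler state (residual variance is fixed at 1)."""

    b: np.ndarray
    u: np.ndarray
    eta: np.ndarray
    delta: np.ndarray
    sigma_u2: float
    pi11: float
    pi00: float


def threshold_from_incidence(q: float) -> float:
    """Liability threshold tau = Phi^-1(1 - q) for incidence q."""
    if not 0.0 < q < 1.0:
        raise ValueError(f"incidence must be strictly inside (0, 1), got {q}")
    return float(ndtri(1.0 - q))


def record_likelihood(rec: LiabilityRecord, tau: float, rates: ErrorRates) -> float:
    """Marginal probability of the observed status given the linear predictor.

    Normalized so that the two possible observed statuses sum to 1.
    """
    p1 = float(ndtr(rec.linear_predictor - tau))  # P(eta > tau)
    if rec.observed_status == 1:
        return rates.sensitivity * p1 + rates.false_positive * (1.0 - p1)
    return rates.false_negative * p1 + rates.specificity * (1.0 - p1)


def _sample_truth_and_liability(
    m: np.ndarray,
    y_star: np.ndarray,
    tau: float,
    rates: ErrorRates,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized draw of (true status, delta, liability) for all records.

    True status from its two-state posterior (prior from the liability side
    probabilities, likelihood from the misclassification rates), then the
    liability from N(m, 1) truncated to the side of tau the drawn status
    implies.  Tail draws use the one-sided inverse-CDF form, which stays
    accurate far from the threshold.
    """
    # clip away exact 0/1 so the two-state posterior stays defined in the
    # far tails even for degenerate (0 or 1) error rates
    p1 = np.clip(ndtr(m - tau), 1e-12, 1.0 - 1e-12)
    p_obs_if_1 = np.where(y_star == 1, rates.sensitivity, rates.false_negative)
    p_obs_if_0 = np.where(y_star == 1, rates.false_positive, rates.specificity)
    w1 = p_obs_if_1 * p1
    w0 = p_obs_if_0 * (1.0 - p1)
    prob_true1 = w1 / np.maximum(w1 + w0, _TINY)
    truth = rng.random(m.size) < prob_true1
    delta = truth != (y_star == 1)

    un = rng.random(m.size)
    eta = np.empty_like(m)
    upper = np.clip(ndtr(m[truth] - tau), _TINY, 1.0)  # P(Z > tau - m)
    eta[truth] = m[truth] - ndtri(np.clip(upper * un[truth], _TINY, 1.0))
    lower = np.clip(ndtr(tau - m[~truth]), _TINY, 1.0)  # P(Z <= tau - m)
    eta[~truth] = m[~truth] + ndtri(np.clip(lower * un[~truth], _TINY, 1.0))
    return truth, delta, eta


def sample_delta_and_liability(
    rec: LiabilityRecord,
    tau: float,
    rates: ErrorRates,
    rng: np.random.Generator,
) -> tuple[int, float]:
    """One record's data-augmentation step: draw (delta, eta)."""
    truth, delta, eta = _sample_truth_and_liability(
        np.array([rec.linear_predictor]),
        np.array([rec.observed_status]),
        tau,
        rates,
        rng,
    )
    return int(delta[0]), float(eta[0])


def resolve_tau(y_star: np.ndarray, config: ThresholdConfig) -> float:
    """Threshold used by the sampler.

    Explicit ``tau`` wins; otherwise ``Phi^-1(1 - q)`` with ``q`` the supplied
    incidence, or the observed incidence adjusted for the known error rates
    (no adjustment when rates are perfect or estimated).
    """
    if config.tau is not None:
        return config.tau
    if config.incidence is not None:
        return threshold_from_incidence(config.incidence)
    q_obs = float(np.mean(y_star))
    if config.estimate_rates or config.error_rates == PERFECT_RATES:
        return threshold_from_incidence(q_obs)
    return threshold_from_incidence(adjust_incidence_by_rates(q_obs, config.error_rates).q)


def _sample_rates(
    rng: np.random.Generator,
    truth: np.ndarray,
    y_star: np.ndarray,
    prior: tuple[float, float],
    current: tuple[float, float],
) -> tuple[float, float]:
    """Beta full conditionals for (sensitivity, specificity).

    Rejection-truncated to sensitivity + specificity > 1; falls back to the
    current values if 100 proposals all fail (pathological data).
    """
    a, b = prior
    n11 = int(np.sum(truth & (y_star == 1)))
    n10 = int(np.sum(truth & (y_star == 0)))
    n00 = int(np.sum(~truth & (y_star == 0)))
    n01 = int(np.sum(~truth & (y_star == 1)))
    for _ in range(100):
        pi11 = rng.beta(a + n11, b + n10)
        pi00 = rng.beta(a + n00, b + n01)
        if pi11 + pi00 > 1.0:
            return pi11, pi00
    return current


def gibbs_threshold(
    y_star: np.ndarray,
    mm: ModelMatrices,
    Ainv: RelationshipMatrix,
    config: ThresholdConfig,
) -> PosteriorSummary:
    """Gibbs sampler for the misclassification-aware threshold animal model.

    Returns liability-scale summaries: ``h2 = sigma_u2/(sigma_u2 + 1)``, the
    posterior incidence (mean imputed-true-positive fraction), the posterior
    misclassification fraction ``prop_delta``, and the current error rates
    (constant columns when the rates are fixed).  Posterior means of ``b``
    and ``u`` are in ``effects``.
    """
    y_star = np.asarray(y_star)
    if not np.all(np.isin(y_star, (0, 1))):
        raise ValueError("y_star must be a 0/1 status vector")
    if y_star.min() == y_star.max():
        raise ValueError("need at least one record of each observed class")
    y_star = y_star.astype(np.int64)
    if y_star.size != mm.n_records:
        raise ValueError("status length must match the design")

    tau = resolve_tau(y_star, config)
    rng = np.random.default_rng(config.seed)
    theta, W = _eigen_basis(mm, Ainv)
    n, q, p = y_star.size, len(mm.animal_ids), len(mm.level_labels)
    aidx, lidx = mm.animal_index, mm.level_index
    n_level = np.bincount(lidx, minlength=p).astype(float)
    if np.any(n_level == 0):
        raise ValueError("empty fixed-effect level")

    s_u = config.prior_h2 / (1.0 - config.prior_h2)  # prior scale, sigma_e2 = 1
    rates = config.error_rates
    pi11, pi00 = rates.sensitivity, rates.specificity

    b = np.zeros(p)
    u = np.zeros(q)
    sigma_u2 = s_u
    eta = np.where(y_star == 1, tau + 0.5, tau - 0.5).astype(float)

    rows = []
    u_sum = np.zeros(q)
    b_sum = np.zeros(p)
    n_kept = 0
    for it in range(config.iterations):
        m = b[lidx] + u[aidx]
        truth, delta, eta = _sample_truth_and_liability(
            m, y_star, tau, ErrorRates(pi11, pi00), rng
        )
        if config.estimate_rates:
            pi11, pi00 = _sample_rates(
                rng, truth, y_star, config.beta_prior, (pi11, pi00)
            )
        # conjugate location updates on the liabilities (residual variance 1)
        resid_b = np.bincount(lidx, weights=eta - u[aidx], minlength=p)
        prec_b = n_level + 1.0 / config.sigma_b2
        b_mean = resid_b / prec_b
        b = b_mean + rng.standard_normal(p) / np.sqrt(prec_b)
        r_u = np.bincount(aidx, weights=eta - b[lidx], minlength=q)
        prec = theta + 1.0 / sigma_u2
        v_mean = W.T @ r_u / prec
        v = v_mean + rng.standard_normal(q) / np.sqrt(prec)
        u = W @ v
        sigma_u2 = _sample_variance(rng, config.nu_u, s_u, float(v @ v), q)
        if not np.isfinite(sigma_u2):
            raise FloatingPointError(f"sigma_u2 diverged at iteration {it}")
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            rows.append(
                (
                    it,
                    sigma_u2,
                    sigma_u2 / (sigma_u2 + 1.0),
                    pi11,
                    pi00,
                    float(delta.mean()),
                    float(truth.mean()),
                )
            )
            # Rao-Blackwellized effect means: average the conditional means
            u_sum += W @ v_mean
            b_sum += b_mean
            n_kept += 1
    chain = pd.DataFrame(
        rows,
        columns=["iter", "sigma_u2", "h2", "pi11", "pi00", "prop_delta", "incidence"],
    ).set_index("iter")
    return summarize_chain(
        chain,
        seed=config.seed,
        iterations=config.iterations,
        burn_in=config.burn_in,
        thin=config.thin,
        scale="liability",
        effects={
            "u_mean": u_sum / n_kept,
            "b_mean": b_sum / n_kept,
            "animal_ids": list(mm.animal_ids),
            "level_labels": list(mm.level_labels),
            "tau": tau,
        },
    )


def heritability_summary(chain: pd.DataFrame, scale: str = "liability") -> pd.DataFrame:
    """Posterior mean/SD/95% interval of h2 from a retained chain.

    On the liability scale ``h2 = sigma_u2/(sigma_u2 + 1)``; on the observed
    scale the chain must carry ``sigma_e2``.
    """
    if len(chain) == 0:
        raise ValueError("empty chain")
    if scale == "liability":
        h2 = chain["sigma_u2"] / (chain["sigma_u2"] + 1.0)
    elif scale == "observed":
        h2 = chain["sigma_u2"] / (chain["sigma_u2"] + chain["sigma_e2"])
    else:
        raise ValueError(f"unknown scale {scale!r}")
    h2 = h2.to_numpy(float)
    lo, hi = np.percentile(h2, [2.5, 97.5])
    return pd.DataFrame(
        [
            {
                "parameter": f"h2_{scale}",
                "mean": h2.mean(),
                "sd": h2.std(ddof=1) if h2.size > 1 else 0.0,
                "q2.5": lo,
                "q97.5": hi,
            }
        ]
    ).set_index("parameter")
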