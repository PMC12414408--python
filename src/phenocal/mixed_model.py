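"""Henderson mixed-model machinery for the animal model.

The animal model is ``y = Xb + Zu + e`` with ``u ~ N(0, A sigma_u2)`` and
``e ~ N(0, I sigma_e2)``.  Additive, unbiased measurement error with
variance ``sigma_eps2`` simply inflates the residual: the observed response
satisfies ``y* ~ (Xb, ZGZ' + I(sigma_e2 + sigma_eps2))``, so BLUP under
measurement error is ordinary BLUP with the inflated residual variance
(:func:`blup_inflated`).  Under a fitted linear calibration the starred
system uses ``G* = A beta^2 sigma_u2`` and ``R* = I(beta^2 sigma_e2 +
sigma_eps2)``, and its solutions back-transform with
:func:`phenocal.calibration.calibrate_effects`.

:func:`gibbs_linear` is a blocked Gibbs sampler for the same linear model
(continuous records, or 0/1 records for observed-scale heritability of a
binary trait).  The additive-value block is drawn jointly: with ``W`` from
the one-time generalized eigendecomposition ``Z'Z W = A^-1 W diag(theta)``
(normalized so ``W' A^-1 W = I``), the full conditional of ``v = W^-1 u`` has
diagonal precision ``theta/sigma_e2 + 1/sigma_u2`` for any variance values,
so each sweep costs two matrix-vector products instead of a Cholesky.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, eigh

from .calibration import CalibrationFit, VarianceComponents
from .pedigree import PedigreeTable, RelationshipMatrix
from .results import PosteriorSummary, summarize_chain


@dataclass(frozen=True)
class ModelMatrices:
    """One-hot design matrices of the animal model.

    Each record carries exactly one fixed-effect level (row of ``X``) and one
    animal (row of ``Z``).
    """

    X: np.ndarray = field(repr=False)
    Z: np.ndarray = field(repr=False)
    record_ids: tuple[str, ...]
    animal_ids: tuple[str, ...]
    level_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        X, Z = np.asarray(self.X, float), np.asarray(self.Z, float)
        if X.shape[0] != Z.shape[0]:
            raise ValueError("X and Z must have the same number of rows")
        if Z.shape[1] != len(self.animal_ids) or X.shape[1] != len(self.level_labels):
            raise ValueError("column counts must match label vectors")
        for M, name in ((X, "X"), (Z, "Z")):
            if not (np.all((M == 0) | (M == 1)) and np.all(M.sum(axis=1) == 1)):
                raise ValueError(f"each row of {name} must have exactly one 1")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Z", Z)

    @property
    def n_records(self) -> int:
        return self.X.shape[0]

    @property
    def level_index(self) -> np.ndarray:
        return np.argmax(self.X, axis=1)

    @property
    def animal_index(self) -> np.ndarray:
        return np.argmax(self.Z, axis=1)


@dataclass(frozen=True)
class MMESolution:
    """Solutions of the mixed-model equations with a condition diagnostic."""

    b_hat: np.ndarray
    u_hat: np.ndarray
    coefficient_condition: float


@dataclass(frozen=True)
class ChainConfig:
    """Gibbs-chain settings and weakly informative variance priors.

    Variance components get scaled-inverse-chi-square priors with ``nu``
    degrees of freedom; the prior scales split the phenotypic variance
    according to ``prior_h2`` (override with explicit ``scale_u``/``scale_e``).
    """

    iterations: int = 100_000
    burn_in: int = 20_000
    thin: int = 10
    seed: int = 0
    nu: float = 4.0
    prior_h2: float = 0.25
    scale_u: float | None = None
    scale_e: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("burn_in must satisfy 0 <= burn_in < iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not 0 < self.prior_h2 < 1:
            raise ValueError("prior_h2 must be in (0, 1)")


def build_design(
    phenotypes: pd.DataFrame,
    ped: PedigreeTable,
    *,
    animals: list[str] | None = None,
) -> ModelMatrices:
    """Build one-hot X (from the ``level`` column) and Z (record -> animal).

    ``animals`` restricts Z's columns (default: every pedigree animal); each
    phenotyped animal must be in the pedigree.  ``phenotypes`` needs columns
    ``animal`` and ``level``.
    """
    if not {"animal", "level"}.issubset(phenotypes.columns):
        raise ValueError("phenotype table needs columns animal,level")
    ped_ids = set(ped.ids)
    rec_animals = [str(a) for a in phenotypes["animal"]]
    for a in rec_animals:
        if a not in ped_ids:
            raise ValueError(f"phenotyped animal {a!r} is not in the pedigree")
    levels = [str(l) for l in phenotypes["level"]]
    if any(l == "" for l in levels):
        raise ValueError("empty fixed-effect level")
    level_labels = tuple(sorted(set(levels)))
    if animals is None:
        animal_ids = tuple(ped.ids)
    else:
        missing = [a for a in rec_animals if a not in set(animals)]
        if missing:
            raise ValueError(f"phenotyped animal {missing[0]!r} not in animal subset")
        animal_ids = tuple(animals)
    lpos = {l: j for j, l in enumerate(level_labels)}
    apos = {a: j for j, a in enumerate(animal_ids)}
    n = len(rec_animals)
    X = np.zeros((n, len(level_labels)))
    Z = np.zeros((n, len(animal_ids)))
    X[np.arange(n), [lpos[l] for l in levels]] = 1.0
    Z[np.arange(n), [apos[a] for a in rec_animals]] = 1.0
    return ModelMatrices(
        X=X,
        Z=Z,
        record_ids=tuple(str(r) for r in phenotypes.get("id", phenotypes.index)),
        animal_ids=animal_ids,
        level_labels=level_labels,
    )


def _solve_mme(
    y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    Ainv: np.ndarray,
    ratio: float,
) -> MMESolution:
    """Solve Henderson's equations with variance ratio ``residual/genetic``."""
    p = X.shape[1]
    C = np.block(
        [
            [X.T @ X, X.T @ Z],
            [Z.T @ X, Z.T @ Z + Ainv * ratio],
        ]
    )
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    jitter = 0.0
    for attempt in range(2):
        try:
            fac = cho_factor(C + jitter * np.eye(C.shape[0]))
            break
        except np.linalg.LinAlgError:
            if attempt == 1:
                cond = float(np.linalg.cond(C))
                raise np.linalg.LinAlgError(
                    f"singular mixed-model coefficient matrix (condition {cond:.3g}); "
                    "check for unestimable fixed levels"
                )
            jitter = 1e-8 * np.trace(C) / C.shape[0]
    sol = cho_solve(fac, rhs)
    eigs = np.linalg.eigvalsh(C)
    cond = float(eigs[-1] / eigs[0]) if eigs[0] > 0 else float("inf")
    return MMESolution(b_hat=sol[:p], u_hat=sol[p:], coefficient_condition=cond)


def blup_inflated(
    y_obs: np.ndarray,
    mm: ModelMatrices,
    A: RelationshipMatrix,
    vc: VarianceComponents,
    fit: CalibrationFit | None = None,
) -> MMESolution:
    """BLUP of fixed and additive effects under measurement-error inflation.

    Without a calibration fit, solves the MME with residual variance
    ``sigma_e2 + sigma_eps2`` (additive, unbiased error).  With a fit, solves
    the starred system (``G* = A beta^2 sigma_u2``, ``R* = I(beta^2 sigma_e2
    + sigma_eps2)``); the returned solutions are then on the starred scale
    and should be back-adjusted with
    :func:`phenocal.calibration.calibrate_effects`.
    """
    y_obs = np.asarray(y_obs, dtype=float)
    if list(A.ids) != list(mm.animal_ids):
        A = A.submatrix(list(mm.animal_ids))
    if fit is None:
        sigma_r2 = vc.sigma_e2 + vc.sigma_eps2
        sigma_g2 = vc.sigma_u2
    else:
        fit.require_invertible()
        sigma_r2 = fit.beta**2 * vc.sigma_e2 + fit.error_variance
        sigma_g2 = fit.beta**2 * vc.sigma_u2
    if sigma_r2 <= 0:
        raise ValueError("total residual variance must be > 0")
    if sigma_g2 == 0.0:
        # no genetic variance: GLS on fixed effects, u = 0
        XtX = mm.X.T @ mm.X
        b = np.linalg.solve(XtX, mm.X.T @ y_obs)
        return MMESolution(
            b_hat=b,
            u_hat=np.zeros(len(mm.animal_ids)),
            coefficient_condition=float(np.linalg.cond(XtX)),
        )
    c, low = cho_factor(A.values)
    Ainv = cho_solve((c, low), np.eye(A.values.shape[0]))
    Ainv = 0.5 * (Ainv + Ainv.T)
    return _solve_mme(y_obs, mm.X, mm.Z, Ainv, ratio=sigma_r2 / sigma_g2)


def _eigen_basis(mm: ModelMatrices, Ainv: RelationshipMatrix):
    """Simultaneous diagonalization of Z'Z and A^-1 for fast u blocks."""
    if list(Ainv.ids) != list(mm.animal_ids):
        Ainv = Ainv.submatrix(list(mm.animal_ids))
    ZtZ = np.diag(np.bincount(mm.animal_index, minlength=len(mm.animal_ids)).astype(float))
    theta, W = eigh(ZtZ, Ainv.values)
    theta = np.clip(theta, 0.0, None)
    return theta, np.ascontiguousarray(W)


def _sample_variance(
    rng: np.random.Generator, nu0: float, s0: float, ss: float, n: int
) -> float:
    """Draw from the scaled-inverse-chi-square full conditional."""
    shape_df = nu0 + n
    return (nu0 * s0 + ss) / rng.chisquare(shape_df)


def gibbs_linear(
    y: np.ndarray,
    mm: ModelMatrices,
    Ainv: RelationshipMatrix,
    config: ChainConfig,
) -> PosteriorSummary:
    """Blocked Gibbs sampler for the linear animal model.

    Samples fixed effects (flat prior), the additive-value block jointly,
    and both variance components (scaled-inverse-chi-square priors).  Reports
    the heritability ``h2 = sigma_u2/(sigma_u2 + sigma_e2)`` on the scale of
    ``y`` — the observed scale when ``y`` is a 0/1 status vector.
    """
    y = np.asarray(y, dtype=float)
    if y.size != mm.n_records:
        raise ValueError("response length must match the design")
    rng = np.random.default_rng(config.seed)
    theta, W = _eigen_basis(mm, Ainv)
    n, q, p = y.size, len(mm.animal_ids), len(mm.level_labels)
    aidx, lidx = mm.animal_index, mm.level_index
    n_level = np.bincount(lidx, minlength=p).astype(float)
    if np.any(n_level == 0):
        raise ValueError("empty fixed-effect level")

    vary = float(np.var(y)) or 1.0
    s_u = config.scale_u if config.scale_u is not None else config.prior_h2 * vary
    s_e = config.scale_e if config.scale_e is not None else (1 - config.prior_h2) * vary
    nu = config.nu

    b = np.zeros(p)
    u = np.zeros(q)
    v = np.zeros(q)
    sigma_u2, sigma_e2 = s_u, s_e

    rows = []
    u_sum = np.zeros(q)
    b_sum = np.zeros(p)
    n_kept = 0
    for it in range(config.iterations):
        u_rec = u[aidx]
        # fixed-effect block (flat prior, X'X diagonal)
        resid_b = np.bincount(lidx, weights=y - u_rec, minlength=p)
        b_mean = resid_b / n_level
        b = b_mean + rng.standard_normal(p) * np.sqrt(sigma_e2 / n_level)
        # additive-value block in the eigenbasis: diagonal full conditional
        r_u = np.bincount(aidx, weights=y - b[lidx], minlength=q) / sigma_e2
        prec = theta / sigma_e2 + 1.0 / sigma_u2
        v_mean = W.T @ r_u / prec
        v = v_mean + rng.standard_normal(q) / np.sqrt(prec)
        u = W @ v
        # variances: u'A^-1 u = v'v in this basis
        sigma_u2 = _sample_variance(rng, nu, s_u, float(v @ v), q)
        e = y - b[lidx] - u[aidx]
        sigma_e2 = _sample_variance(rng, nu, s_e, float(e @ e), n)
        if not (np.isfinite(sigma_u2) and np.isfinite(sigma_e2)):
            raise FloatingPointError(
                f"variance draw diverged at iteration {it}: "
                f"sigma_u2={sigma_u2}, sigma_e2={sigma_e2}"
            )
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            rows.append(
                (it, sigma_u2, sigma_e2, sigma_u2 / (sigma_u2 + sigma_e2))
            )
            # Rao-Blackwellized effect means: average the conditional means
            u_sum += W @ v_mean
            b_sum += b_mean
            n_kept += 1
    chain = pd.DataFrame(rows, columns=["iter", "sigma_u2", "sigma_e2", "h2"]).set_index(
        "iter"
    )
    return summarize_chain(
        chain,
        seed=config.seed,
        iterations=config.iterations,
        burn_in=config.burn_in,
        thin=config.thin,
        scale="observed",
        effects={
            "u_mean": u_sum / n_kept,
            "b_mean": b_sum / n_kept,
            "animal_ids": list(mm.animal_ids),
            "level_labels": list(mm.level_labels),
        },
    )
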