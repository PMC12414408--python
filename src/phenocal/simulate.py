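"""Synthetic-data generators for pedigreed binary and continuous traits.

The default configuration emulates a dairy-cattle study design: 125 unrelated
sires and 477 unrelated dams produce 643 phenotyped cows; a latent liability
is the sum of a 10-level fixed effect (level values standard normal), an
additive genetic value with covariance ``A sigma_u2`` where ``sigma_u2 =
h2/(1 - h2)`` and ``h2 = 0.4``, and a unit-variance residual.  Thresholding
the liability at its empirical 80th quantile yields a binary trait with
incidence 129/643 = 20.06%.  Misclassification is injected by independent
Bernoulli flips with false-positive rate ``pi_1|0`` and false-negative rate
``pi_0|1`` (equal-rate scenario: both 0.15; unequal: 0.2 and 0.1).

Additive values are generated by the pedigree recursion (founders ~
N(0, sigma_u2); offspring = parent average + Mendelian-sampling deviate),
which realizes the covariance ``A sigma_u2`` exactly without factorizing A.

All generators are pure functions of (configuration, rng): the same seed
reproduces every output bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calibration import PairedSample
from .misclassification import ErrorRates, ValidationCounts
from .pedigree import PedigreeTable, inbreeding, pedigree_from_arrays


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the trait simulator."""

    n_sires: int = 125
    n_dams: int = 477
    n_offspring: int = 643
    h2: float = 0.4
    sigma_e2: float = 1.0
    n_fixed_levels: int = 10
    incidence_quantile: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.h2 < 1:
            raise ValueError("h2 must be in (0, 1)")
        if not 0 < self.incidence_quantile < 1:
            raise ValueError("incidence_quantile must be in (0, 1)")
        if min(self.n_sires, self.n_dams, self.n_offspring, self.n_fixed_levels) < 1:
            raise ValueError("counts must be positive")

    @property
    def sigma_u2(self) -> float:
        """Additive variance implied by the target heritability."""
        return self.h2 / (1.0 - self.h2) * self.sigma_e2


@dataclass(frozen=True)
class SimulatedTrait:
    """A simulated pedigreed trait.

    ``u_all`` is aligned with ``pedigree.ids``; all record-level vectors
    (``latent``, ``e``, ``fixed_level`` …) are aligned with ``animal_ids``
    (the phenotyped cohort).  ``latent = fixed_value + u + e`` elementwise.
    After :func:`dichotomize`, ``tau`` and ``y_true`` are set; after
    :func:`inject_misclassification`, ``y_obs``.
    """

    pedigree: PedigreeTable
    animal_ids: tuple[str, ...]
    u_all: np.ndarray = field(repr=False)
    latent: np.ndarray = field(repr=False)
    e: np.ndarray = field(repr=False)
    fixed_level: np.ndarray = field(repr=False)
    fixed_values: np.ndarray = field(repr=False)
    tau: float | None = None
    y_true: np.ndarray | None = None
    y_obs: np.ndarray | None = None

    @property
    def u(self) -> np.ndarray:
        """Additive values of the phenotyped cohort."""
        pos = {a: i for i, a in enumerate(self.pedigree.ids)}
        return self.u_all[[pos[a] for a in self.animal_ids]]

    @property
    def incidence(self) -> float:
        if self.y_true is None:
            raise ValueError("trait has not been dichotomized")
        return float(np.mean(self.y_true))

    @property
    def observed_incidence(self) -> float:
        if self.y_obs is None:
            raise ValueError("no misclassification has been injected")
        return float(np.mean(self.y_obs))

    def phenotype_frame(self) -> pd.DataFrame:
        """Phenotype table (``animal,level`` plus whatever statuses exist)."""
        df = pd.DataFrame(
            {"animal": list(self.animal_ids), "level": self.fixed_level.astype(int)}
        )
        df["latent"] = self.latent
        if self.y_true is not None:
            df["status_true"] = self.y_true.astype(int)
        if self.y_obs is not None:
            df["status"] = self.y_obs.astype(int)
        return df


def simulate_pedigree(cfg: SimConfig, rng: np.random.Generator) -> PedigreeTable:
    """Half-sib family pedigree: unrelated founders, random sire/dam per cow."""
    sires = [f"S{i + 1:04d}" for i in range(cfg.n_sires)]
    dams = [f"D{i + 1:04d}" for i in range(cfg.n_dams)]
    cows = [f"C{i + 1:04d}" for i in range(cfg.n_offspring)]
    sire_of = rng.integers(0, cfg.n_sires, size=cfg.n_offspring)
    dam_of = rng.integers(0, cfg.n_dams, size=cfg.n_offspring)
    animals = sires + dams + cows
    sire_col = ["0"] * (cfg.n_sires + cfg.n_dams) + [sires[i] for i in sire_of]
    dam_col = ["0"] * (cfg.n_sires + cfg.n_dams) + [dams[i] for i in dam_of]
    return pedigree_from_arrays(animals, sire_col, dam_col)


def simulate_breeding_values(
    ped: PedigreeTable, sigma_u2: float, rng: np.random.Generator
) -> np.ndarray:
    """Additive values with covariance ``A sigma_u2`` via the pedigree recursion.

    Founders draw N(0, sigma_u2); an offspring is the parent average plus a
    Mendelian-sampling deviate with variance ``sigma_u2 (0.5 - 0.25 (F_s +
    F_d))`` (per-parent terms ``0.25 (1 - F)`` when only one parent is known).
    """
    par = ped.parent_indices()
    f = inbreeding(ped)
    z = rng.standard_normal(ped.n)
    u = np.zeros(ped.n)
    for i in range(ped.n):
        s, d = par[i]
        mean = 0.0
        ms_var = 1.0
        for p in (s, d):
            if p >= 0:
                mean += 0.5 * u[p]
                ms_var -= 0.25 * (1.0 + f[p])
        u[i] = mean + z[i] * np.sqrt(ms_var * sigma_u2)
    return u


def simulate_latent(
    ped: PedigreeTable,
    cfg: SimConfig,
    rng: np.random.Generator,
    phenotyped: list[str] | None = None,
) -> SimulatedTrait:
    """Latent liability = fixed effect + additive value + residual.

    The phenotyped cohort defaults to all non-parents (the offspring
    generation).  Fixed-effect level values are standard normal; levels are
    assigned uniformly at random.
    """
    if phenotyped is None:
        parents = {p for _, s, d in ped.records for p in (s, d) if p}
        phenotyped = [a for a in ped.ids if a not in parents]
    n = len(phenotyped)
    if n == 0:
        raise ValueError("no phenotyped animals")
    u_all = simulate_breeding_values(ped, cfg.sigma_u2, rng)
    fixed_values = rng.standard_normal(cfg.n_fixed_levels)
    fixed_level = rng.integers(0, cfg.n_fixed_levels, size=n)
    e = rng.standard_normal(n) * np.sqrt(cfg.sigma_e2)
    pos = {a: i for i, a in enumerate(ped.ids)}
    u_pheno = u_all[[pos[a] for a in phenotyped]]
    latent = fixed_values[fixed_level] + u_pheno + e
    return SimulatedTrait(
        pedigree=ped,
        animal_ids=tuple(phenotyped),
        u_all=u_all,
        latent=latent,
        e=e,
        fixed_level=fixed_level,
        fixed_values=fixed_values,
    )


def simulate_trait(cfg: SimConfig, rng: np.random.Generator | None = None) -> SimulatedTrait:
    """Pedigree + latent liability in one call (pedigree and trait share rng)."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    ped = simulate_pedigree(cfg, rng)
    cows = [f"C{i + 1:04d}" for i in range(cfg.n_offspring)]
    return simulate_latent(ped, cfg, rng, phenotyped=cows)


def dichotomize(trait: SimulatedTrait, quantile: float) -> SimulatedTrait:
    """Threshold the latent liability at its empirical ``quantile``.

    The threshold is the ascending-rank ``floor(quantile * n)`` value and
    positives are strictly greater, so exactly ``n - floor(quantile * n)``
    records are positive (643 records at the 0.8 quantile give 129 positives,
    incidence 20.06%).  Ties at the threshold raise an error.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    latent = trait.latent
    n = latent.size
    k = int(np.floor(quantile * n))
    if k < 1 or k >= n:
        raise ValueError(f"quantile {quantile} leaves no records on one side")
    tau = float(np.sort(latent)[k - 1])
    y = latent > tau
    if int(y.sum()) != n - k:
        raise ValueError("ties at the threshold: dichotomization is ambiguous")
    return replace(trait, tau=tau, y_true=y)


def inject_misclassification(
    y_true: np.ndarray | SimulatedTrait,
    rates: tuple[float, float],
    rng: np.random.Generator,
):
    """Flip statuses independently: 0 -> 1 w.p. ``pi_1|0``, 1 -> 0 w.p. ``pi_0|1``.

    ``rates = (false_positive, false_negative)``.  Accepts a status vector
    (returns the corrupted vector) or a dichotomized :class:`SimulatedTrait`
    (returns a copy with ``y_obs`` set).
    """
    fp, fn = rates
    if not (0.0 <= fp <= 1.0 and 0.0 <= fn <= 1.0):
        raise ValueError("rates must be in [0, 1]")
    if isinstance(y_true, SimulatedTrait):
        if y_true.y_true is None:
            raise ValueError("dichotomize the trait before injecting misclassification")
        y_obs = inject_misclassification(y_true.y_true, rates, rng)
        return replace(y_true, y_obs=y_obs)
    y = np.asarray(y_true).astype(bool)
    flip = np.where(y, rng.random(y.size) < fn, rng.random(y.size) < fp)
    return y ^ flip


def simulate_paired_continuous(
    n: int,
    alpha: float,
    beta: float,
    sigma_eps2: float,
    rng: np.random.Generator,
    mean: float = 0.0,
    variance: float = 1.0,
) -> PairedSample:
    """Paired true / error-prone values under the linear error model."""
    if n < 3:
        raise ValueError("need n >= 3")
    if sigma_eps2 < 0 or variance <= 0:
        raise ValueError("variances must be positive")
    y = mean + rng.standard_normal(n) * np.sqrt(variance)
    y_obs = alpha + beta * y + rng.standard_normal(n) * np.sqrt(sigma_eps2)
    return PairedSample(y_true=y, y_obs=y_obs)


def simulate_double_sampling(
    n_validation: int,
    n_test: int,
    q: float,
    rates: ErrorRates,
    rng: np.random.Generator,
) -> tuple[ValidationCounts, tuple[int, int]]:
    """Double-sampling draw: a cross-tabulated validation set plus a test set.

    True statuses are Bernoulli(q); observed statuses pass through the error
    rates.  Returns the validation 2x2 counts and the test set's observed
    (negative, positive) counts.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must be in [0, 1]")
    y_val = rng.random(n_validation) < q
    y_obs_val = inject_misclassification(
        y_val, (rates.false_positive, rates.false_negative), rng
    )
    counts = ValidationCounts(
        n00=int(np.sum(~y_val & ~y_obs_val)),
        n01=int(np.sum(~y_val & y_obs_val)),
        n10=int(np.sum(y_val & ~y_obs_val)),
        n11=int(np.sum(y_val & y_obs_val)),
    )
    y_test = rng.random(n_test) < q
    y_obs_test = inject_misclassification(
        y_test, (rates.false_positive, rates.false_negative), rng
    )
    t1 = int(np.sum(y_obs_test))
    return counts, (n_test - t1, t1)
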