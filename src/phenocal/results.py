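"""Posterior summaries for the MCMC samplers."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def _ess(x: np.ndarray) -> float:
    """Effective sample size of one chain (bulk ESS)."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            import arviz

            return float(arviz.ess(np.asarray(x)[None, :]))
    except Exception:  # pragma: no cover - diagnostic only
        return float("nan")


def _split_rhat(x: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for a single chain."""
    x = np.asarray(x, dtype=float)
    half = x.size // 2
    if half < 4:
        return float("nan")
    chains = np.stack([x[:half], x[half : 2 * half]])
    m, n = chains.shape
    means = chains.mean(axis=1)
    w = chains.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w == 0:
        return float("nan")
    return float(np.sqrt((n - 1) / n + b / (w * n)))


@dataclass
class PosteriorSummary:
    """Retained MCMC samples plus their summary statistics.

    ``chain`` has one row per retained draw; ``summary`` one row per scalar
    parameter with posterior mean, SD, central 95% interval, ESS and a
    split-chain Rhat.  ``effects`` optionally carries posterior means of the
    fixed-effect and additive-value vectors.
    """

    chain: pd.DataFrame
    summary: pd.DataFrame
    seed: int
    iterations: int
    burn_in: int
    thin: int
    scale: str = "observed"  # observed | liability
    effects: dict = field(default_factory=dict)

    @property
    def retained(self) -> int:
        return len(self.chain)

    def mean(self, parameter: str) -> float:
        return float(self.summary.loc[parameter, "mean"])

    def interval(self, parameter: str) -> tuple[float, float]:
        row = self.summary.loc[parameter]
        return float(row["q2.5"]), float(row["q97.5"])

    @property
    def heritability(self) -> float:
        return self.mean("h2")


def summarize_chain(
    chain: pd.DataFrame,
    *,
    seed: int,
    iterations: int,
    burn_in: int,
    thin: int,
    scale: str,
    effects: dict | None = None,
) -> PosteriorSummary:
    rows = []
    for col in chain.columns:
        x = chain[col].to_numpy(float)
        lo, hi = np.percentile(x, [2.5, 97.5])
        rows.append(
            {
                "parameter": col,
                "mean": x.mean(),
                "sd": x.std(ddof=1) if x.size > 1 else 0.0,
                "q2.5": lo,
                "q97.5": hi,
                "ess": _ess(x),
                "rhat": _split_rhat(x),
            }
        )
    summary = pd.DataFrame(rows).set_index("parameter")
    return PosteriorSummary(
        chain=chain,
        summary=summary,
        seed=seed,
        iterations=iterations,
        burn_in=burn_in,
        thin=thin,
        scale=scale,
        effects=effects or {},
    )
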