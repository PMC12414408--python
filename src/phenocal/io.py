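"""Readers, writers, and run-configuration handling shared by the CLI.

Every artifact written here embeds the seed and a hash of the configuration
that produced it (CSV header comment or JSON field), so a stochastic output
can be reproduced exactly from the pair.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from dataclasses import asdict, dataclass, fields

import numpy as np
import pandas as pd
import yaml

from .pedigree import RelationshipMatrix
from .results import PosteriorSummary

CHAIN_DEFAULTS = {"iterations": 100_000, "burn_in": 20_000, "thin": 10}


class ConfigError(ValueError):
    """Raised for unknown keys or inconsistent run-configuration values."""


@dataclass(frozen=True)
class RunConfig:
    """Validated run settings for the model-fitting subcommands."""

    iterations: int = CHAIN_DEFAULTS["iterations"]
    burn_in: int = CHAIN_DEFAULTS["burn_in"]
    thin: int = CHAIN_DEFAULTS["thin"]
    seed: int = 0
    sensitivity: float = 1.0
    specificity: float = 1.0
    estimate_rates: bool = False
    tau: float | None = None
    incidence: float | None = None
    prior_h2: float = 0.25
    nu: float = 4.0

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ConfigError(
                f"burn_in ({self.burn_in}) must be smaller than iterations "
                f"({self.iterations})"
            )
        if self.thin < 1:
            raise ConfigError("thin must be >= 1")
        for name in ("sensitivity", "specificity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")

    def hash(self) -> str:
        return config_hash(asdict(self))


def read_config(path) -> RunConfig:
    """Read a YAML run configuration; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    allowed = {f.name: f for f in fields(RunConfig)}
    unknown = sorted(set(raw) - set(allowed))
    if unknown:
        raise ConfigError(f"unknown config keys: {', '.join(unknown)}")
    for key in ("iterations", "burn_in", "thin", "seed"):
        if key in raw and not isinstance(raw[key], int):
            raise ConfigError(f"{key} must be an integer, got {raw[key]!r}")
    return RunConfig(**raw)


def config_hash(obj) -> str:
    """Short stable hash of any JSON-serializable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _atomic_write(path, writer) -> None:
    path = os.fspath(path)
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=os.path.dirname(path) or ".", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            writer(fh)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_frame(df: pd.DataFrame, path, *, seed=None, cfg_hash=None, index=False) -> None:
    """CSV with a provenance header comment."""

    def _writer(fh):
        fh.write(f"# seed={seed} config={cfg_hash}\n")
        df.to_csv(fh, index=index)

    _atomic_write(path, _writer)


def write_matrix(mat: RelationshipMatrix, path) -> None:
    """Relationship matrix as row-major CSV with an id header row/column."""
    _atomic_write(path, lambda fh: mat.to_frame().to_csv(fh, index_label="id"))


def write_chain(summary: PosteriorSummary, path) -> None:
    """Retained samples, one row per draw, with seed/settings in the header."""

    def _writer(fh):
        fh.write(
            f"# seed={summary.seed} iterations={summary.iterations} "
            f"burn_in={summary.burn_in} thin={summary.thin} scale={summary.scale}\n"
        )
        summary.chain.to_csv(fh, index=True)

    _atomic_write(path, _writer)


def write_summary_json(summary: PosteriorSummary, path, extra: dict | None = None) -> None:
    payload = {
        "seed": summary.seed,
        "iterations": summary.iterations,
        "burn_in": summary.burn_in,
        "thin": summary.thin,
        "retained": summary.retained,
        "scale": summary.scale,
        "parameters": {
            name: {k: _jsonify(v) for k, v in row.items()}
            for name, row in summary.summary.to_dict(orient="index").items()
        },
    }
    if extra:
        payload.update(extra)
    _atomic_write(path, lambda fh: json.dump(payload, fh, indent=2, default=_jsonify))


def write_json(obj: dict, path) -> None:
    _atomic_write(path, lambda fh: json.dump(obj, fh, indent=2, default=_jsonify))


def _jsonify(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, np.ndarray):
        return v.tolist()
    return v


def read_phenotypes(path) -> pd.DataFrame:
    """Phenotype CSV: ``animal,level,value`` (continuous) or ``animal,level,status``."""
    df = pd.read_csv(path, comment="#")
    if "animal" not in df.columns or "level" not in df.columns:
        raise ValueError("phenotype file needs columns animal,level")
    if "value" not in df.columns and "status" not in df.columns:
        raise ValueError("phenotype file needs a value or status column")
    df["animal"] = df["animal"].astype(str)
    return df
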