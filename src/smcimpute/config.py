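"""Run configuration: YAML schema, validation, and hashing.

Every run is driven by a single config file; unknown keys are rejected so
that typos fail loudly before any computation starts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .conditional import Priors

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    pass


_TOP_KEYS = {"data", "variables", "models", "controls", "priors", "output",
             "seed", "verbosity", "pool", "simulate"}
_DATA_KEYS = {"path", "cluster_col"}
_CONTROL_KEYS = {"burn_in", "n_between", "m", "adapt_every", "accept_band",
                 "indep_prob"}
_PRIOR_KEYS = {"var_shape", "var_rate", "t_scale", "t_df_extra"}
_OUTPUT_KEYS = {"imputations", "diagnostics", "split", "pooled", "metrics",
                "estimates"}
_MODEL_KEYS = {"sequence", "order"}
_POOL_KEYS = {"stacked_path", "formula", "cluster_col", "imp_col", "df_com"}
_SIM_KEYS = {"study", "n", "J", "icc", "lambda1", "w", "replications",
             "strategies", "burn_in", "n_between", "m"}


def _check_keys(section: dict, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")


@dataclass
class RunConfig:
    data_path: str | None = None
    cluster_col: str = "cluster"
    levels: dict = field(default_factory=dict)
    sequence: list = field(default_factory=list)   # formulas, outcome last
    order: str = "given"
    controls: dict = field(default_factory=dict)
    priors: Priors = field(default_factory=Priors)
    output: dict = field(default_factory=dict)
    seed: int | None = None
    verbosity: str = "info"
    pool: dict = field(default_factory=dict)
    simulate: dict = field(default_factory=dict)
    raw: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def load_config(path) -> RunConfig:
    """Load and schema-validate a YAML run configuration."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys(raw, _TOP_KEYS, "config root")

    cfg = RunConfig(raw=raw)
    data = raw.get("data", {}) or {}
    _check_keys(data, _DATA_KEYS, "data")
    cfg.data_path = data.get("path")
    cfg.cluster_col = data.get("cluster_col", "cluster")

    levels = raw.get("variables", {}) or {}
    for k, v in levels.items():
        if v not in (1, 2):
            raise ConfigError(f"variable {k!r} has invalid level {v!r}")
    cfg.levels = dict(levels)

    models = raw.get("models", {}) or {}
    _check_keys(models, _MODEL_KEYS, "models")
    cfg.sequence = list(models.get("sequence", []))
    cfg.order = models.get("order", "given")
    if cfg.order not in ("given", "auto"):
        raise ConfigError("models.order must be 'given' or 'auto'")

    controls = raw.get("controls", {}) or {}
    _check_keys(controls, _CONTROL_KEYS, "controls")
    cfg.controls = dict(controls)

    priors = raw.get("priors", {}) or {}
    _check_keys(priors, _PRIOR_KEYS, "priors")
    cfg.priors = Priors(**priors)

    output = raw.get("output", {}) or {}
    _check_keys(output, _OUTPUT_KEYS, "output")
    cfg.output = dict(output)

    cfg.seed = raw.get("seed")
    cfg.verbosity = raw.get("verbosity", "info")

    pool = raw.get("pool", {}) or {}
    _check_keys(pool, _POOL_KEYS, "pool")
    cfg.pool = dict(pool)

    sim = raw.get("simulate", {}) or {}
    _check_keys(sim, _SIM_KEYS, "simulate")
    cfg.simulate = dict(sim)
    return cfg
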