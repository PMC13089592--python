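"""Pipeline configuration: YAML-backed, strictly validated.

Unknown fields are rejected by name so a typo in a scenario file fails loudly
rather than silently falling back to a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .design import ExperimentDesign
from .sapflow import BaselineConfig


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class McmcConfig:
    n_iter: int = 50_000
    burn_in: int = 40_000
    n_chains: int = 3

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ConfigError("mcmc burn_in must be below n_iter")
        if self.n_chains < 2:
            raise ConfigError("mcmc needs at least two chains")


ALL_STAGES = ("simulate", "phenology", "dendro", "sapflow", "bootstrap", "report")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a reproducible run needs: scenario, stage toggles, module
    settings, the master seed and an exclusion list of tree ids."""

    out_dir: str = "run"
    seed: int = 42
    stages: tuple[str, ...] = ALL_STAGES
    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    baseline: BaselineConfig = field(default_factory=BaselineConfig)
    bootstrap_n_iter: int = 1000
    fit_onset: bool = True  # pass the scenario's growth-onset day to the fit
    exclude_trees: tuple[str, ...] = ()
    input_dir: str | None = None  # read CSVs from here instead of simulating

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise ConfigError(f"unknown stages {unknown}; valid: {list(ALL_STAGES)}")

    def to_payload(self) -> dict:
        """JSON-serialisable view used for hashing; filesystem locations are
        excluded so identical analyses hash identically wherever they run."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)
        payload.pop("input_dir", None)
        return payload


def _build(cls, data: dict, path: str):
    known = {f.name: f for f in fields(cls)}
    unknown = [k for k in data if k not in known]
    if unknown:
        raise ConfigError(f"unknown field(s) {unknown} in {path or cls.__name__}")
    kwargs = {}
    for k, v in data.items():
        if k == "design" and isinstance(v, dict):
            kwargs[k] = _build(ExperimentDesign, _tupleize(v), f"{path}.{k}")
        elif k == "mcmc" and isinstance(v, dict):
            kwargs[k] = _build(McmcConfig, v, f"{path}.{k}")
        elif k == "baseline" and isinstance(v, dict):
            kwargs[k] = _build(BaselineConfig, v, f"{path}.{k}")
        elif isinstance(v, list):
            kwargs[k] = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        else:
            kwargs[k] = v
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as err:
        raise ConfigError(f"invalid configuration at {path or cls.__name__}: {err}") from err


def _tupleize(d: dict) -> dict:
    return {k: tuple(tuple(x) if isinstance(x, list) else x for x in v) if isinstance(v, list) else v for k, v in d.items()}


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from YAML, applying keyword overrides
    (e.g. ``seed=...``, ``out_dir=...``) on top."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"configuration root in {path} must be a mapping")
    data.update({k: v for k, v in overrides.items() if v is not None})
    cfg = _build(PipelineConfig, data, "")
    # the master seed drives the scenario too
    if "design" not in data or "rng_seed" not in (data.get("design") or {}):
        cfg = dataclasses.replace(cfg, design=cfg.design.with_seed(cfg.seed))
    return cfg
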