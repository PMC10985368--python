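"""Run configuration: loading, validation and canonical serialisation.

A run configuration is a flat YAML mapping mirroring the model's parameter
symbols (``delta``, ``c``, ``S``, ``theta``, ``beta``, ``sigma``, ``gamma``,
``phi``, ``X``) plus experiment plumbing (``experiment``, ``scenario``,
``mode``, ``reps``, ``generations``, ``seed``, ``out``) and optional
explicit environment bounds (``U``, ``L``, ``R``).  Omitted keys take the
model defaults; unknown keys and out-of-range values are rejected.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional

import yaml

from .core import SCENARIOS, EnvironmentConfig, SimulationParams

__all__ = ["RunConfig", "load_config", "dump_config", "config_hash"]

EXPERIMENTS = ("single-run", "ecological", "sensitivity", "mechanistic", "evolutionary")

#: key -> (attribute on SimulationParams, validation range shown in errors)
_PARAM_KEYS = {
    "delta": "breeding season length in days (>= 1, and > beta)",
    "c": "selection coefficient (> 0; default 0.2)",
    "S": "infected survival benefit (0-0.5)",
    "theta": "male dispersal parameter (0.05-5)",
    "beta": "lifetime matings per female in male excess (> 0, < delta)",
    "sigma": "brood size (>= 1)",
    "gamma": "vertical transmission probability (0-1; sampled range 0.5-1)",
    "phi": "mutation probability (0-1; default 0.01)",
    "X": "juvenile competition parameter (> 0; default 500)",
    "init_size": "initial adult count (>= 2)",
    "init_prevalence": "initial fraction of females infected (0-1)",
    "init_phenotype_mode": "uniform | matched",
}
_RUN_KEYS = ("experiment", "scenario", "mode", "reps", "generations", "seed", "out")
_ENV_KEYS = ("U", "L", "R")


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration for one CLI invocation."""

    experiment: str = "single-run"
    params: SimulationParams = field(default_factory=SimulationParams)
    scenario: str = "constant"
    mode: str = "cyclical"
    env: Optional[EnvironmentConfig] = None  # explicit U/L/R override
    n_reps: int = 100
    base_seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"experiment must be one of {EXPERIMENTS}, got {self.experiment!r}"
            )
        if self.env is None and self.scenario not in SCENARIOS:
            raise ValueError(
                f"scenario must be one of {sorted(SCENARIOS)}, got {self.scenario!r}"
            )
        if self.mode not in ("cyclical", "stochastic", "constant"):
            raise ValueError(f"invalid environment mode {self.mode!r}")
        if self.n_reps < 1:
            raise ValueError("reps must be >= 1")
        if self.base_seed < 0:
            raise ValueError("seed must be >= 0")

    def environment(self) -> EnvironmentConfig:
        """The resolved environment process for this run."""
        if self.env is not None:
            return self.env
        return EnvironmentConfig.from_scenario(self.scenario, mode=self.mode)


def _coerce(key: str, value: Any) -> Any:
    if key in ("delta", "sigma", "init_size", "reps", "generations", "seed"):
        return int(value)
    if key in ("experiment", "scenario", "mode", "out", "init_phenotype_mode"):
        return str(value)
    return float(value)


def load_config(
    source: str | Path | Mapping[str, Any] | None = None,
    overrides: Mapping[str, Any] | None = None,
) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file/mapping plus overrides.

    ``source`` may be a path to a YAML file, an already-parsed mapping, or
    None (all defaults).  ``overrides`` (e.g. CLI flags) take precedence over
    the file.  Unknown keys raise; range violations raise with the permitted
    range in the message.
    """
    data: dict[str, Any] = {}
    if source is not None:
        if isinstance(source, Mapping):
            data.update(source)
        else:
            path = Path(source)
            try:
                loaded = yaml.safe_load(path.read_text())
            except yaml.YAMLError as exc:
                raise ValueError(f"malformed config file {path}: {exc}") from exc
            if loaded is None:
                loaded = {}
            if not isinstance(loaded, dict):
                raise ValueError(f"config file {path} must be a mapping")
            data.update(loaded)
    for k, v in (overrides or {}).items():
        if v is not None:
            data[k] = v

    allowed = set(_PARAM_KEYS) | set(_RUN_KEYS) | set(_ENV_KEYS)
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(
            f"unknown configuration keys: {sorted(unknown)}; allowed keys are {sorted(allowed)}"
        )

    param_kwargs = {}
    for key in _PARAM_KEYS:
        if key in data:
            param_kwargs[key] = _coerce(key, data[key])
    if "generations" in data:
        param_kwargs["n_generations"] = _coerce("generations", data["generations"])
    try:
        params = SimulationParams(**param_kwargs)
    except ValueError as exc:
        bad = next((k for k in param_kwargs if k in str(exc)), None)
        hint = f" ({_PARAM_KEYS[bad]})" if bad in _PARAM_KEYS else ""
        raise ValueError(f"invalid parameter value: {exc}{hint}") from exc

    env = None
    if any(k in data for k in ("U", "L")):
        env = EnvironmentConfig(
            mode=str(data.get("mode", "cyclical")),
            U=float(data["U"]),
            L=float(data.get("L", 1.0 - float(data["U"]))),
            R=float(data.get("R", 10.0)),
        )
    return RunConfig(
        experiment=str(data.get("experiment", "single-run")),
        params=params,
        scenario=str(data.get("scenario", "constant")),
        mode=str(data.get("mode", "cyclical")),
        env=env,
        n_reps=int(data.get("reps", 100)),
        base_seed=int(data.get("seed", 0)),
        out_dir=str(data.get("out", "results")),
    )


def dump_config(cfg: RunConfig) -> str:
    """Canonical YAML form: flat mapping, sorted keys; load(dump(x)) == x."""
    p = cfg.params
    data: dict[str, Any] = {
        "experiment": cfg.experiment,
        "scenario": cfg.scenario,
        "mode": cfg.mode,
        "reps": cfg.n_reps,
        "seed": cfg.base_seed,
        "out": cfg.out_dir,
        "generations": p.n_generations,
        "delta": p.delta,
        "c": p.c,
        "S": p.S,
        "theta": p.theta,
        "beta": p.beta,
        "sigma": p.sigma,
        "gamma": p.gamma,
        "phi": p.phi,
        "X": p.X,
        "init_size": p.init_size,
        "init_prevalence": p.init_prevalence,
        "init_phenotype_mode": p.init_phenotype_mode,
    }
    if cfg.env is not None:
        data.update({"U": cfg.env.U, "L": cfg.env.L, "R": cfg.env.R})
    return yaml.safe_dump(data, sort_keys=True, default_flow_style=False)


def config_hash(cfg: RunConfig) -> str:
    """Short stable digest of the canonical config, for output provenance."""
    return hashlib.sha256(dump_config(cfg).encode()).hexdigest()[:12]
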