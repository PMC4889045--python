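"""Run configuration: validation, defaults, and provenance echo.

A run is fully described by a YAML (or JSON) mapping with blocks::

    model:   {type: two-stage, ks: ..., kdm: ..., kdp: ...}
             or a declarative mass-action block {species: [...], reactions: [...]}
             or {path: network.yaml}
    input:   {generator: circadian|ou|lognormal-ou|modulated-circadian|
              sum-of-ou|constant, ...params, dt: ..., seed: ...}
             or {csv: trajectory.csv}
    method:  extrande | sia | mn-integral | direct-integral
    T:       horizon in hours

plus method-specific fields (``L``/``bound_strategy``/``safety_factor`` for
extrande, ``integration_step`` for the integral methods), ``seed``,
``output_dir`` and optional ``output_dt``/``record_events``.  Unknown keys are
a hard error (no silent typo-tolerance); missing required keys raise a named
error.  The fully-resolved configuration is echoed to the output directory so
a run is reproducible from its artifacts alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import yaml

from .exceptions import ConfigError

__all__ = ["RunConfig", "load_config", "save_config"]

_METHODS = ("extrande", "sia", "mn-integral", "direct-integral")
_TOP_KEYS = {
    "model",
    "input",
    "method",
    "T",
    "seed",
    "output_dir",
    "output_dt",
    "record_events",
    "L",
    "bound_strategy",
    "safety_factor",
    "integration_step",
    "x0",
    "interpolation",
}
_REQUIRED = ("model", "input", "method", "T")


@dataclasses.dataclass
class RunConfig:
    """Validated, defaults-filled run description."""

    model: dict
    input: dict
    method: str
    T: float
    seed: int = 0
    output_dir: str = "extrande-run"
    output_dt: float | None = None
    record_events: bool = True
    L: float | str | None = "auto"
    bound_strategy: str = "window-max"
    safety_factor: float = 1.0
    integration_step: float | None = None
    x0: list | None = None
    interpolation: str = "previous"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        missing = [k for k in _REQUIRED if k not in raw]
        if missing:
            raise ConfigError(f"missing required configuration keys: {missing}")
        cfg = cls(**{k: raw[k] for k in raw})
        cfg.validate()
        return cfg

    def validate(self):
        if self.method not in _METHODS:
            raise ConfigError(f"method must be one of {_METHODS}, got {self.method!r}")
        if self.T <= 0:
            raise ConfigError(f"T must be > 0, got {self.T}")
        if self.method in ("mn-integral", "direct-integral"):
            if self.integration_step is None:
                raise ConfigError(
                    f"method {self.method!r} requires the field 'integration_step'"
                )
            if self.integration_step <= 0:
                raise ConfigError("integration_step must be > 0")
        if not isinstance(self.model, dict):
            raise ConfigError("'model' must be a mapping")
        if not isinstance(self.input, dict):
            raise ConfigError("'input' must be a mapping")
        if self.L not in (None, "auto") and (
            not isinstance(self.L, (int, float)) or self.L <= 0
        ):
            raise ConfigError("L must be a positive number, 'auto' or null")

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path} does not contain a mapping")
    return RunConfig.from_dict(raw)


def save_config(cfg: RunConfig, path):
    """Write the fully-resolved configuration (YAML)."""
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
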