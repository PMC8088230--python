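"""Run configuration: a flat key-value YAML file mapped onto the
synthetic-cohort hyperparameters plus run-level settings."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .observer import ObserverConfig

_OBSERVER_KEYS = {f.name for f in dataclasses.fields(ObserverConfig)}
_RUN_KEYS = {"seed", "out_dir", "trajectories"}


@dataclass(frozen=True)
class RunConfig:
    """Everything needed for a reproducible end-to-end run.

    ``seed`` may be omitted at load time but is mandatory for any
    stochastic step; ``trajectories`` is either ``"paper"`` (the
    built-in experimental set) or a path to a trajectory CSV.
    """

    observer: ObserverConfig = field(default_factory=ObserverConfig)
    seed: int | None = None
    out_dir: str = "parattc_report"
    trajectories: str = "paper"

    def require_seed(self) -> int:
        if self.seed is None:
            raise ConfigError("seed is required for data generation")
        return int(self.seed)

    def to_flat_dict(self) -> dict:
        flat = dataclasses.asdict(self.observer)
        flat.update(seed=self.seed, out_dir=self.out_dir, trajectories=self.trajectories)
        return flat


def config_from_dict(raw: dict) -> RunConfig:
    """Build a validated RunConfig from a flat mapping; unknown keys are
    rejected, missing keys take their defaults."""
    unknown = set(raw) - _OBSERVER_KEYS - _RUN_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    try:
        observer = ObserverConfig(**{k: v for k, v in raw.items() if k in _OBSERVER_KEYS})
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
    return RunConfig(
        observer=observer,
        seed=raw.get("seed"),
        out_dir=raw.get("out_dir", "parattc_report"),
        trajectories=raw.get("trajectories", "paper"),
    )


def load_config(path: str | Path) -> RunConfig:
    """Load a flat YAML config file.  An empty file yields all defaults."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a flat key: value mapping")
    return config_from_dict(raw)


def write_config(config: RunConfig, path: str | Path) -> None:
    """Echo a config verbatim (flat YAML), for self-describing output."""
    Path(path).write_text(yaml.safe_dump(config.to_flat_dict(), sort_keys=True))
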