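"""Run configuration: defaults, YAML overlay, and provenance serialization."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import yaml

from .model import (
    DEFAULT_CONTRAST_GRID,
    DEFAULT_LEVEL_PROBS,
    DEFAULT_P_SWITCH_GRID,
)


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved settings for a command-line run.

    Precedence: built-in defaults < YAML config file < command-line flags.
    The resolved config is serialized next to every output for provenance.
    """

    level_probs: tuple[float, ...] = DEFAULT_LEVEL_PROBS
    p_switch: float = 0.01
    contrast: float = 1.0
    initial_prior: float = 0.5
    repeats: int = 4
    p_switch_grid: tuple[float, ...] = DEFAULT_P_SWITCH_GRID
    contrast_grid: tuple[float, ...] = DEFAULT_CONTRAST_GRID
    gen_buffer: float | None = None
    gen_max_attempts: int = 10_000
    fit_restarts: int = 5
    variability_floor: float = 1.0
    noise_sd: float = 5.0
    seed: int | None = None

    @classmethod
    def load(cls, path: str | Path | None = None, **overrides) -> "RunConfig":
        """Build a config from defaults, an optional YAML file, and overrides."""
        values: dict = {}
        if path is not None:
            raw = yaml.safe_load(Path(path).read_text()) or {}
            if not isinstance(raw, dict):
                raise ValueError(f"config file {path} must hold a mapping")
            unknown = set(raw) - set(cls.__dataclass_fields__)
            if unknown:
                raise ValueError(f"unknown config keys: {sorted(unknown)}")
            values.update(raw)
        values.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("level_probs", "p_switch_grid", "contrast_grid"):
            if key in values:
                values[key] = tuple(values[key])
        return cls(**values)

    def dump(self, path: str | Path) -> None:
        data = asdict(self)
        for key in ("level_probs", "p_switch_grid", "contrast_grid"):
            data[key] = list(data[key])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    def with_overrides(self, **overrides) -> "RunConfig":
        return replace(self, **{k: v for k, v in overrides.items() if v is not None})
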