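"""Run configuration: a flat schema shared by the CLI and config files.

A run is described by a single flat mapping (YAML on disk) mirroring
:class:`RunConfig`; command-line flags override file values.  Validation
reuses the constraints of the underlying domain types, so a config rejects
exactly the inputs the library would reject — before any computation starts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .experiments import CATEGORIES
from .model import PSAWeights
from .protocols import Protocol

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    category: str = "best_responder"
    alpha: float = 1.0 / 3.0
    beta: float = 1.0 / 3.0
    protocol: str = "at"
    horizon: float = 10000.0
    rtol: float = 1e-8
    atol: float = 1e-12
    lower_frac: float = 0.5
    upper_frac: float = 1.0
    step: float = 0.05
    n: int = 50
    seed: int = 0
    init_fraction: float = 0.1
    sample_dt: float = 1.0
    outdir: str = "psadapt-out"

    def validate(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"category must be one of {CATEGORIES}, got {self.category!r}"
            )
        PSAWeights(self.alpha, self.beta)  # raises InvalidWeightsError
        Protocol(self.protocol)  # raises ValueError
        if self.horizon <= 0:
            raise ValueError(f"horizon must be > 0, got {self.horizon}")
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("solver tolerances must be > 0")
        if not (0 < self.lower_frac < self.upper_frac <= 10):
            raise ValueError(
                "need 0 < lower_frac < upper_frac (fractions of baseline PSA)"
            )
        if not (0 < self.step <= 0.5):
            raise ValueError(f"step must be in (0, 0.5], got {self.step}")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if not (0 < self.init_fraction <= 1):
            raise ValueError(f"init_fraction must be in (0, 1], got {self.init_fraction}")
        if self.sample_dt <= 0:
            raise ValueError(f"sample_dt must be > 0, got {self.sample_dt}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def load_config(path: str | Path | None, overrides: dict) -> RunConfig:
    """Config from an optional YAML file with CLI overrides applied on top."""
    cfg = RunConfig.from_file(path) if path else RunConfig()
    for key, value in overrides.items():
        if value is not None:
            setattr(cfg, key, value)
    cfg.validate()
    return cfg
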