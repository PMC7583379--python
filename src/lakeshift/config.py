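"""Run configuration: a validated YAML mapping driving a simulation."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "save_config"]

_DATE_KEYS = ("warmup_start", "calibration_start", "validation_start", "end")


@dataclass(frozen=True)
class RunConfig:
    """Paths, grid, simulation windows, and numerics of one run."""

    hypsograph: str
    meteorology: str
    inflow: str
    observations: str | None = None
    parameters: str | None = None
    output_dir: str = "output"
    n_layers: int = 16
    zoom: float = 0.035
    dt: float = 0.25
    seed: int = 42
    warmup_start: str = "1990-01-01"
    calibration_start: str = "1993-01-01"
    validation_start: str = "2000-01-01"
    end: str = "2007-01-01"

    def __post_init__(self):
        dates = [getattr(self, k) for k in _DATE_KEYS]
        if sorted(dates) != dates or len(set(dates)) != len(dates):
            raise ValueError(
                "simulation windows must be strictly ordered: "
                "warmup_start < calibration_start < validation_start < end")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if not 0 < self.dt <= 1:
            raise ValueError("dt must be in (0, 1] days")

    def validate_paths(self, base: Path | None = None) -> None:
        base = base or Path(".")
        for key in ("hypsograph", "meteorology", "inflow", "observations", "parameters"):
            val = getattr(self, key)
            if val is not None and not (base / val).exists():
                raise FileNotFoundError(f"config key {key!r}: file not found: {val}")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def load_config(path, *, check_paths: bool = True) -> RunConfig:
    """Load and validate a YAML run configuration (unknown keys rejected)."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ValueError("configuration file must contain a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    required = {"hypsograph", "meteorology", "inflow"}
    missing = required - set(raw)
    if missing:
        raise ValueError(f"missing required configuration keys: {sorted(missing)}")
    cfg = RunConfig(**raw)
    if check_paths:
        cfg.validate_paths(path.parent)
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
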