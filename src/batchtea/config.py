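"""Pipeline configuration: a small validated YAML schema.

Unknown keys are rejected, defaults are filled, and bound overrides are
validated against the variable registry at load time.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .variables import VARIABLES, Variable

__all__ = ["PipelineConfig", "load_config", "save_config", "config_hash"]


@dataclass(frozen=True)
class PipelineConfig:
    n: int = 5_000
    seed: int = 0
    marr: float = 0.30
    irr_range: tuple[float, float] = (0.01, 0.50)
    upc_window: tuple[float, float] = (140.0, 240.0)
    train_fraction: float = 0.8
    cv_folds: int = 5
    search_iterations: int = 30
    heatmap_resolution: int = 100
    out_dir: str = "results"
    bounds_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be at least 1")
        if not 0.0 <= self.marr <= 1.0:
            raise ValueError("marr must be in [0, 1]")
        lo, hi = self.irr_range
        if not lo < hi:
            raise ValueError("irr_range: low must be < high")
        lo, hi = self.upc_window
        if not lo < hi:
            raise ValueError("upc_window: low must be < high")
        for name, spec in self.bounds_overrides.items():
            known = {v.name for v in VARIABLES}
            if name not in known:
                raise ValueError(f"bounds override for unknown variable {name!r}")
            if not spec["lower"] < spec["upper"]:
                raise ValueError(f"bounds override for {name!r}: lower must be < upper")

    def variables(self) -> tuple[Variable, ...]:
        """The variable registry with any bound overrides applied."""
        out = []
        for v in VARIABLES:
            if v.name in self.bounds_overrides:
                spec = self.bounds_overrides[v.name]
                v = Variable(v.name, v.kind, v.units,
                             spec.get("baseline", v.baseline),
                             spec["lower"], spec["upper"])
            out.append(v)
        return tuple(out)


_FIELDS = {f.name for f in dataclasses.fields(PipelineConfig)}
_TUPLE_FIELDS = {"irr_range", "upc_window"}


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML config; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config at {path} must be a mapping")
    unknown = set(raw) - _FIELDS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in _TUPLE_FIELDS & set(raw):
        raw[key] = tuple(raw[key])
    return PipelineConfig(**raw)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    data = dataclasses.asdict(config)
    for key in _TUPLE_FIELDS:
        data[key] = list(data[key])
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def config_hash(config: PipelineConfig) -> str:
    data = dataclasses.asdict(config)
    for key in _TUPLE_FIELDS:
        data[key] = list(data[key])
    blob = yaml.safe_dump(data, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
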