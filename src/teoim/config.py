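"""YAML run configuration with strict validation.

Unknown keys are fatal (silent default substitution would invalidate the
round-trip guarantees the pipeline tests rely on). Missing keys take the
documented dataclass defaults. ``dump_config(load_config(p))`` is the
normalized form of ``p``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from . import dielectric
from .dielectric import SOLUTES, PermittivitySpec
from .errors import ConfigError, TeoimError
from .forward_sim import NoiseConfig, SceneConfig
from .grid import GridSpec
from .reconstruct import ReconstructionConfig

DEFAULT_GRID = GridSpec(nx=128, ny=128, pitch_mm=0.1)


def default_roi(grid: GridSpec) -> tuple[float, float, float, float]:
    """Rectangle over the tube region: centered, 8 mm x 3 mm (clipped to grid)."""
    cx, cy = grid.center_mm()
    hx = min(4.0, grid.nx * grid.pitch_mm / 4)
    hy = min(1.5, grid.ny * grid.pitch_mm / 4)
    return (cx - hx, cy - hy, cx + hx, cy + hy)


@dataclass
class RunConfig:
    grid: GridSpec = field(default_factory=lambda: DEFAULT_GRID)
    scene: SceneConfig = field(default_factory=SceneConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    reconstruction: ReconstructionConfig = field(default_factory=ReconstructionConfig)
    dielectric: dict = field(
        default_factory=lambda: {s: dielectric.default_spec(s) for s in SOLUTES}
    )
    roi: tuple | None = None
    output_dir: str = "out"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.roi is None:
            self.roi = default_roi(self.grid)
        self.roi = tuple(float(v) for v in self.roi)
        x0, y0, x1, y1 = self.roi
        xs, ys = self.grid.x_mm(), self.grid.y_mm()
        if not (x0 < x1 and y0 < y1):
            raise ConfigError(f"roi: degenerate rectangle {self.roi}")
        if x1 <= xs[0] or x0 > xs[-1] or y1 <= ys[0] or y0 > ys[-1]:
            raise ConfigError(f"roi: rectangle {self.roi} lies outside the grid")


def _build(cls, data, path: str):
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping, got {type(data).__name__}")
    allowed = {f.name for f in fields(cls)}
    for key in data:
        if key not in allowed:
            raise ConfigError(f"unknown key '{path}.{key}'")
    try:
        return cls(**data)
    except TeoimError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def _build_dielectric(data, path: str) -> dict:
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping of solute overrides")
    specs = {s: dielectric.default_spec(s) for s in SOLUTES}
    for solute, overrides in data.items():
        if solute not in SOLUTES:
            raise ConfigError(f"unknown key '{path}.{solute}'")
        overrides = overrides or {}
        allowed = {f.name for f in fields(PermittivitySpec)} - {"solute"}
        for key in overrides:
            if key not in allowed:
                raise ConfigError(f"unknown key '{path}.{solute}.{key}'")
        try:
            specs[solute] = dataclasses.replace(specs[solute], **overrides)
        except TeoimError as exc:
            raise ConfigError(f"{path}.{solute}: {exc}") from exc
    return specs


_SECTIONS = {
    "grid": lambda d: _build(GridSpec, d, "grid"),
    "scene": lambda d: _build(SceneConfig, d, "scene"),
    "noise": lambda d: _build(NoiseConfig, d, "noise"),
    "reconstruction": lambda d: _build(ReconstructionConfig, d, "reconstruction"),
    "dielectric": lambda d: _build_dielectric(d, "dielectric"),
}


def config_from_mapping(data: dict | None) -> RunConfig:
    data = data or {}
    if not isinstance(data, dict):
        raise ConfigError("top level: expected a mapping")
    kwargs = {}
    for key, value in data.items():
        if key in _SECTIONS:
            kwargs[key] = _SECTIONS[key](value)
        elif key in ("roi", "output_dir", "log_level"):
            kwargs[key] = value
        else:
            raise ConfigError(f"unknown key '{key}'")
    try:
        return RunConfig(**kwargs)
    except TeoimError as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path) -> RunConfig:
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: YAML parse error: {exc}") from exc
    return config_from_mapping(data)


def to_dict(cfg: RunConfig) -> dict:
    """Normalized plain-dict form (stable for serialization round trips)."""

    def as_dict(obj):
        return {f.name: getattr(obj, f.name) for f in fields(obj)}

    return {
        "grid": as_dict(cfg.grid),
        "scene": as_dict(cfg.scene),
        "noise": as_dict(cfg.noise),
        "reconstruction": as_dict(cfg.reconstruction),
        "dielectric": {
            s: {k: v for k, v in as_dict(spec).items() if k != "solute"}
            for s, spec in sorted(cfg.dielectric.items())
        },
        "roi": list(cfg.roi),
        "output_dir": cfg.output_dir,
        "log_level": cfg.log_level,
    }


def dump_config(cfg: RunConfig, path=None) -> str:
    text = yaml.safe_dump(to_dict(cfg), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text
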