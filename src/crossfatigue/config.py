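"""YAML run configuration: validation, defaults, provenance echo.

A run config mirrors the library's spec dataclasses section by section::

    sim:    {n_channels: 17, fs: 128, duration: 64, shift: 1.0, ...}
    model:  {backbone_depth: tiny, use_attention: true, ...}
    train:  {epochs: 30, batch: 32, alpha: 0.3, ...}
    losses: {alpha: 0.3, kernel: rbf_median}
    paths:  {out_dir: runs/demo}
    log_level: INFO

Missing sections/keys fall back to the library defaults; unknown keys warn
but do not fail (forward compatibility); type and range violations are
collected and reported together.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .eegsim import SynthConfig
from .losses import LossConfig
from .model import ModelSpec
from .training import TrainSpec

__all__ = ["ConfigError", "RunConfig", "validate_config"]


class ConfigError(ValueError):
    """Raised with an exhaustive list of configuration violations."""


@dataclass
class RunConfig:
    sim: SynthConfig = field(default_factory=SynthConfig)
    model: ModelSpec = field(default_factory=ModelSpec)
    train: TrainSpec = field(default_factory=TrainSpec)
    losses: LossConfig = field(default_factory=LossConfig)
    paths: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def provenance(self) -> dict:
        """Resolved config as a JSON-ready dict (the run header)."""
        out = {}
        for name in ("sim", "model", "train", "losses"):
            section = dataclasses.asdict(getattr(self, name))
            for k, v in section.items():
                if isinstance(v, frozenset):
                    section[k] = sorted(v)
            out[name] = section
        out["paths"] = dict(self.paths)
        out["log_level"] = self.log_level
        return out


_SECTIONS = {
    "sim": SynthConfig,
    "model": ModelSpec,
    "train": TrainSpec,
    "losses": LossConfig,
}


def _build_section(name: str, cls, raw: dict, errors: list[str]):
    known = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in raw.items():
        if key not in known:
            warnings.warn(f"config: unknown key {name}.{key} ignored", stacklevel=3)
            continue
        if key == "ablation" and isinstance(value, list):
            value = frozenset(value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        errors.append(f"{name}: {exc}")
        return cls()


def validate_config(config_path: str | Path | None,
                    overrides: dict | None = None) -> RunConfig:
    """Load + validate a YAML config; an empty/missing file yields defaults."""
    raw: dict = {}
    if config_path is not None:
        text = Path(config_path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"top level of {config_path} must be a mapping")
        raw = loaded
    if overrides:
        for section, vals in overrides.items():
            if isinstance(vals, dict):
                base = raw.setdefault(section, {})
                for k, v in vals.items():
                    base.setdefault(k, v)
            else:
                raw.setdefault(section, vals)

    errors: list[str] = []
    sections = {}
    for name, cls in _SECTIONS.items():
        sec_raw = raw.pop(name, {}) or {}
        if not isinstance(sec_raw, dict):
            errors.append(f"{name}: must be a mapping")
            sec_raw = {}
        sections[name] = _build_section(name, cls, sec_raw, errors)
    paths = raw.pop("paths", {}) or {}
    log_level = raw.pop("log_level", "INFO")
    for leftover in raw:
        warnings.warn(f"config: unknown section {leftover!r} ignored", stacklevel=2)
    if errors:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(errors))
    return RunConfig(paths=paths, log_level=str(log_level), **sections)


def write_provenance(cfg: RunConfig, out_dir: str | Path, seed: int | None = None) -> Path:
    """Write the resolved config + seed to ``run_config.json`` in out_dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = cfg.provenance()
    if seed is not None:
        payload["seed"] = seed
    from . import __version__

    payload["version"] = __version__
    path = out_dir / "run_config.json"
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path
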