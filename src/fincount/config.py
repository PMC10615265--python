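"""Structured YAML configuration for the command-line tools.

A run config file mirrors the library dataclasses field-for-field:

.. code-block:: yaml

    seed: 1
    geometry:  {electrode_width: 0.020}
    detector:  {mode: re, threshold_ratio: 3.0}
    scenario:
      n_pass: 40
      n_dwell: 40
      noise: {gaussian_sd: 0.005}
    solver:    {h: 0.005, sigma_water: 0.05}

All sections are optional; omitted fields take the library defaults.
Unknown keys raise, so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .detector import DetectorConfig
from .field import TankGeometry
from .synth import NoiseModel, ScenarioConfig


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SolverConfig:
    h: float = 0.005
    sigma_water: float = 0.05
    v_drive: float = 1.0
    ratios: tuple[float, ...] = (20 / 240, 0.125, 0.5, 1.0)

    def __post_init__(self) -> None:
        if self.h <= 0 or self.sigma_water <= 0 or self.v_drive <= 0:
            raise ConfigError("solver parameters must be positive")


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    geometry: TankGeometry = field(default_factory=TankGeometry)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    solver: SolverConfig = field(default_factory=SolverConfig)


def _build(cls, data: dict[str, Any], where: str):
    if not isinstance(data, dict):
        raise ConfigError(f"section {where!r} must be a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown keys in {where!r}: {sorted(unknown)}")
    kwargs = dict(data)
    for f in dataclasses.fields(cls):
        if f.name in kwargs:
            v = kwargs[f.name]
            if f.name == "noise" and isinstance(v, dict):
                kwargs[f.name] = _build(NoiseModel, v, f"{where}.noise")
            elif isinstance(v, list):
                kwargs[f.name] = tuple(v)
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {where!r} section: {exc}") from exc


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML run config (None gives all defaults)."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    known = {"seed", "geometry", "detector", "scenario", "solver"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        raise ConfigError("seed must be an integer")
    scenario_raw = dict(raw.get("scenario", {}))
    scenario_raw.setdefault("seed", seed)
    return RunConfig(
        seed=seed,
        geometry=_build(TankGeometry, raw.get("geometry", {}), "geometry"),
        detector=_build(DetectorConfig, raw.get("detector", {}), "detector"),
        scenario=_build(ScenarioConfig, scenario_raw, "scenario"),
        solver=_build(SolverConfig, raw.get("solver", {}), "solver"),
    )


def _jsonify(value: Any) -> Any:
    if isinstance(value, dict):
        return {k: _jsonify(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_jsonify(v) for v in value]
    return value


def config_echo(config: RunConfig) -> dict[str, Any]:
    """JSON-round-trippable dict of every numeric setting, for metadata."""
    return _jsonify({
        "seed": config.seed,
        "geometry": dataclasses.asdict(config.geometry),
        "detector": dataclasses.asdict(config.detector),
        "scenario": dataclasses.asdict(config.scenario),
        "solver": dataclasses.asdict(config.solver),
    })
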