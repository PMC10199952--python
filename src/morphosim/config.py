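"""Simulation configuration: nested dataclass sections with strict YAML
(de)serialization — unknown keys are rejected, round trips are lossless."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .coupling import CouplingConfig
from .mechanics import MechParams, MorseParams, SpringParams
from .meshgen import MeshParams
from .signaling import ChemParams

__all__ = ["TissueConfig", "OutputConfig", "SimConfig",
           "load_config", "save_config", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class TissueConfig:
    """Initial-tissue fixture parameters."""

    n_cells: int = 100
    nodes_per_cell_membrane: int = 16
    internal_nodes_per_cell: int = 8
    cell_radius: float = 1.0
    relax_steps: int = 300


@dataclass(frozen=True)
class OutputConfig:
    outdir: str = "out"
    save_nodes: bool = False


@dataclass
class SimConfig:
    """Top-level configuration with sections mirroring the submodels."""

    seed: int = 0
    mechanics: MechParams = field(default_factory=MechParams)
    mesh: MeshParams = field(default_factory=MeshParams)
    signaling: ChemParams = field(default_factory=ChemParams)
    coupling: CouplingConfig = field(default_factory=CouplingConfig)
    tissue: TissueConfig = field(default_factory=TissueConfig)
    output: OutputConfig = field(default_factory=OutputConfig)


_NESTED = {"ii": MorseParams, "mi": MorseParams, "adh": MorseParams,
           "mmd": MorseParams, "mms": SpringParams}


def _build(cls, data, path=""):
    if not isinstance(data, dict):
        raise ConfigError(f"section {path or cls.__name__} must be a mapping")
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown keys in {path or cls.__name__}: "
                          f"{sorted(unknown)}")
    kwargs = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        sub = _NESTED.get(f.name)
        if sub is None and dataclasses.is_dataclass(f.type) is False:
            # nested sections of SimConfig
            tmap = {"mechanics": MechParams, "mesh": MeshParams,
                    "signaling": ChemParams, "coupling": CouplingConfig,
                    "tissue": TissueConfig, "output": OutputConfig}
            sub = tmap.get(f.name)
        if sub is not None and isinstance(v, dict):
            v = _build(sub, v, f"{path}.{f.name}" if path else f.name)
        kwargs[f.name] = v
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"invalid {path or cls.__name__}: {e}") from e


def config_from_dict(data: dict) -> SimConfig:
    return _build(SimConfig, data)


def config_to_dict(cfg: SimConfig) -> dict:
    return dataclasses.asdict(cfg)


def load_config(path) -> SimConfig:
    """Load and validate a YAML configuration file."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    return config_from_dict(raw)


def save_config(cfg: SimConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))
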