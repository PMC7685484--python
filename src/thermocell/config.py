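"""Structured run configuration: YAML in, validated dataclasses out.

One file describes a whole run — plant calibration, PID gains, setpoint
program, movie and pipeline parameters, seed — so device simulations and
movie/quantification runs are reproducible from a single artifact.  Unknown
keys are rejected rather than ignored: a typo in a parameter name should be
an error, not a silently applied default.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .control import DEFAULT_SAMPLE_INTERVAL_S, PIDGains, SetpointProgram, parse_waveform
from .plant import PlantParams
from .simcell import GrowthModel, MovieConfig

__version__ = "0.1.0"


class ConfigError(ValueError):
    """Malformed or unknown configuration content."""


def _build(cls, data: dict, section: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in section '{section}'; "
            f"known keys: {sorted(known)}"
        )
    # YAML gives lists; dataclasses want the tuples they were declared with
    coerced = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if isinstance(v, list):
            v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        coerced[f.name] = v
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid section '{section}': {exc}") from exc


@dataclass(frozen=True)
class PipelineParams:
    """Quantification-pipeline knobs exposed in the config file."""

    smoothing_window: int = 5
    bin_window_min: float = 2.5
    division_window_min: float = 5.0
    max_displacement_px: float = 10.0
    register: bool = True


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a simulation/quantification run."""

    seed: int = 0
    plant: PlantParams = field(default_factory=PlantParams)
    gains: PIDGains = field(default_factory=PIDGains)
    program: str = "hold:37:70m"
    sample_interval_s: float = DEFAULT_SAMPLE_INTERVAL_S
    initial_temp_c: float | None = None
    calibration_file: str | None = None
    movie: MovieConfig = field(default_factory=MovieConfig)
    growth: GrowthModel = field(default_factory=GrowthModel)
    pipeline: PipelineParams = field(default_factory=PipelineParams)
    n_cells: int = 16
    phenotype: str = "wildtype"

    def setpoint_program(self) -> SetpointProgram:
        return parse_waveform(self.program, self.sample_interval_s)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


_SECTIONS = {
    "plant": PlantParams,
    "gains": PIDGains,
    "movie": MovieConfig,
    "growth": GrowthModel,
    "pipeline": PipelineParams,
}
_SCALARS = {
    "seed",
    "program",
    "sample_interval_s",
    "initial_temp_c",
    "calibration_file",
    "n_cells",
    "phenotype",
}


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return RunConfig()
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    unknown = set(raw) - set(_SECTIONS) - _SCALARS
    if unknown:
        raise ConfigError(
            f"{path}: unknown top-level key(s) {sorted(unknown)}"
        )
    kwargs: dict = {k: raw[k] for k in _SCALARS if k in raw}
    for name, cls in _SECTIONS.items():
        if name in raw:
            if not isinstance(raw[name], dict):
                raise ConfigError(f"{path}: section '{name}' must be a mapping")
            kwargs[name] = _build(cls, raw[name], name)
    cfg = RunConfig(**kwargs)
    # fail fast on a bad waveform too
    cfg.setpoint_program()
    return cfg


def write_provenance(out_dir: str | Path, config: RunConfig, command: str) -> Path:
    """Drop a machine-readable record of what produced this directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    record = {
        "command": command,
        "config_hash": config.hash(),
        "seed": config.seed,
        "version": __version__,
    }
    path = out / "provenance.json"
    path.write_text(json.dumps(record, indent=2) + "\n")
    return path
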