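"""Run configuration: a single YAML-serializable bundle of all parameters.

An empty file (or missing section) falls back to the published defaults;
unknown sections or keys are rejected so typos fail loudly.  Every
output file written by the CLI embeds the configuration hash for
provenance.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .adex import FEF_PRESET, SC_PRESET, AdExParams
from .connectivity import MexicanHatParams, SynapseParams
from .input_drive import InputParams
from .map_geometry import MapConstants
from .network import SimulationConfig
from .tuning import MapParameterTable

__all__ = ["RunConfig", "SimSettings", "load_config", "save_config", "config_hash"]


@dataclass(frozen=True)
class SimSettings:
    """Integration and trial settings."""

    dt: float = 0.01
    horizon: float = 300.0
    lateral_enabled: bool = True
    spike_guard: int = 200
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.horizon <= 0:
            raise ValueError("dt and horizon must be positive")


@dataclass(frozen=True)
class TuningSettings:
    """Neuron-tuning settings: tau_q map endpoints and the count target."""

    tau_rostral: float = 80.0
    tau_caudal: float = 10.0
    target_spikes: int = 20


_SECTIONS = {
    "map": MapConstants,
    "input": InputParams,
    "fef": AdExParams,
    "sc": AdExParams,
    "synapse": SynapseParams,
    "hat": MexicanHatParams,
    "simulation": SimSettings,
    "tuning": TuningSettings,
}


@dataclass(frozen=True)
class RunConfig:
    """Merged parameter sets for every stage of the pipeline."""

    map: MapConstants = field(default_factory=MapConstants)
    input: InputParams = field(default_factory=InputParams)
    fef: AdExParams = FEF_PRESET
    sc: AdExParams = SC_PRESET
    synapse: SynapseParams = field(default_factory=SynapseParams)
    hat: MexicanHatParams = field(default_factory=MexicanHatParams)
    simulation: SimSettings = field(default_factory=SimSettings)
    tuning: TuningSettings = field(default_factory=TuningSettings)

    def to_dict(self) -> dict:
        return {name: asdict(getattr(self, name)) for name in _SECTIONS}

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        unknown = set(data) - set(_SECTIONS)
        if unknown:
            raise ValueError(f"unknown configuration section(s): {sorted(unknown)}")
        kwargs = {}
        for name, section_cls in _SECTIONS.items():
            section = dict(data.get(name) or {})
            valid = {f.name for f in fields(section_cls)}
            bad = set(section) - valid
            if bad:
                raise ValueError(f"unknown key(s) in [{name}]: {sorted(bad)}")
            defaults = asdict(getattr(cls(), name))
            defaults.update(section)
            kwargs[name] = section_cls(**defaults)
        kwargs["hat"].validate_hat_shape()
        return cls(**kwargs)

    def simulation_config(
        self, target_amplitude: float, table: MapParameterTable
    ) -> SimulationConfig:
        """Assemble a trial configuration from this bundle and a tuned table."""
        return SimulationConfig(
            target_amplitude=target_amplitude,
            tau_q=table.tau_q,
            w_ff=table.w_ff,
            dt=self.simulation.dt,
            horizon=self.simulation.horizon,
            lateral_enabled=self.simulation.lateral_enabled,
            map_constants=self.map,
            input_params=self.input,
            fef_params=self.fef,
            sc_params=self.sc,
            synapse_params=self.synapse,
            hat_params=self.hat,
            spike_guard=self.simulation.spike_guard,
            rng_seed=self.simulation.seed,
        )


def load_config(path: str | Path | None = None) -> RunConfig:
    """Read a YAML configuration; ``None`` or an empty file give defaults."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ValueError(f"malformed configuration file {path}: {exc}") from exc
    if data is None:
        return RunConfig()
    if not isinstance(data, dict):
        raise ValueError(f"configuration root must be a mapping, got {type(data)}")
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def config_hash(config: RunConfig) -> str:
    """Short provenance hash of the canonical serialized configuration."""
    canonical = yaml.safe_dump(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]
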