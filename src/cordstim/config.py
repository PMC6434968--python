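"""Experiment configuration: one YAML-serializable record of every knob.

An :class:`ExperimentConfig` pins the discretization, conductivities, pulse
timing and sweep layout of a full run, and hashes to a stable identifier so
outputs can be traced back to the exact configuration that produced them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import yaml


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ExperimentConfig:
    # discretization
    mesh_resolution_mm: float = 0.35
    map_spacing_mm: float = 0.1
    axon_dt_ms: float = 1e-3
    # conductivities (S/m)
    sigma_white_radial: float = 0.083
    sigma_white_longitudinal: float = 0.6
    sigma_gray: float = 0.23
    sigma_csf: float = 1.7
    sigma_shell: float = 0.04
    # pulse
    stim_duration_ms: float = 0.2
    recovery_ratio: float = 0.25
    # sweeps
    depth_trials: int = 9
    lateral_trials: int = 7
    max_total_mA: float = 20.0
    # replication
    seed: int = 0
    n_replicates: int = 2

    def __post_init__(self):
        for name in ("mesh_resolution_mm", "map_spacing_mm", "axon_dt_ms",
                     "stim_duration_ms", "max_total_mA"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be positive")
        if self.depth_trials < 2 or self.lateral_trials < 2:
            raise ConfigError("sweeps need at least 2 trials")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")

    def conductivity_map(self):
        from .geometry import ConductivityMap
        return ConductivityMap(
            sigma_white_radial=self.sigma_white_radial,
            sigma_white_longitudinal=self.sigma_white_longitudinal,
            sigma_gray=self.sigma_gray, sigma_csf=self.sigma_csf,
            sigma_extradural=self.sigma_shell)

    @property
    def digest(self) -> str:
        """Stable short hash of the full configuration."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def with_overrides(self, **kw) -> "ExperimentConfig":
        return replace(self, **kw)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
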