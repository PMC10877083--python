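"""Run configuration and manifests.

A :class:`RunConfig` collects every knob of a pipeline run; it loads from and
saves to YAML, and every simulation output directory gets a manifest carrying
the full parameter set, the seed and a hash of the configuration so reruns
are auditable.  Units throughout: nm, kBT, degrees, mol/L, seconds.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .cg_model import Nanoparticle

__all__ = ["RunConfig", "write_manifest"]


@dataclass
class RunConfig:
    """Parameters of one corona-prediction run."""

    radius_nm: float = 80.0
    surface_label: str = "Al100"
    zeta_potential_mV: float = -5.0
    debye_length_nm: float = 0.78
    temperature_K: float = 300.0
    hamaker_constant_J: float = 0.0
    grid_spacing_deg: float = 5.0
    mode: str = "hard_sphere"  # or "displacement"
    acceleration: bool = False
    sim_time_s: float | None = None
    max_events: int | None = None
    burn_in_fraction: float = 0.5
    seed: int | None = None
    pmf_dir: str | None = None
    structure_paths: list = field(default_factory=list)
    output_dir: str = "."

    def __post_init__(self) -> None:
        if self.mode not in ("hard_sphere", "displacement"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def validate_for_simulation(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory for simulation runs")
        if self.sim_time_s is None and self.max_events is None:
            raise ValueError("sim_time_s or max_events must be set")
        for p in self.structure_paths:
            if not Path(p).exists():
                raise FileNotFoundError(p)
        if self.pmf_dir is not None and not Path(self.pmf_dir).is_dir():
            raise FileNotFoundError(self.pmf_dir)

    def nanoparticle(self) -> Nanoparticle:
        return Nanoparticle(
            radius=self.radius_nm,
            surface_label=self.surface_label,
            zeta_potential=self.zeta_potential_mV,
            debye_length=self.debye_length_nm,
            temperature=self.temperature_K,
            hamaker_constant=self.hamaker_constant_J,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def digest(self) -> str:
        """Stable hash of the full configuration."""
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(path, config: RunConfig, extra: dict | None = None) -> None:
    """Write the auditable run manifest (all parameters + seed + config hash)."""
    manifest = {
        "config": asdict(config),
        "config_hash": config.digest(),
        "seed": config.seed,
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(yaml.safe_dump(manifest, sort_keys=True))
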