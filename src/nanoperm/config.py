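"""Run configuration: a flat YAML-backed record of every tunable.

Defaults mirror the constrained-simulation protocol where one exists
(0.2 nm window spacing, 60% equilibration discard, 310 K) and package
design defaults elsewhere; each key carries a provenance tag
("protocol" vs "default") in the echoed resolved configuration so a
run directory documents exactly what produced it.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "PROVENANCE"]

PROVENANCE = {
    "temperature": "protocol",
    "z_max": "protocol",
    "window_spacing": "protocol",
    "discard_fraction": "protocol",
    "pull_rate_nm_per_ps": "protocol",
    "preset": "default",
    "tau": "default",
    "dt": "default",
    "n_steps": "default",
    "bounds_mode": "default",
    "bilayer_thickness": "default",
    "acf_cutoff_tau_factor": "default",
    "n_boot": "default",
    "seed": "default",
}


@dataclass
class RunConfig:
    """All tunables of an end-to-end synthetic run."""

    temperature: float = 310.0          # K
    z_max: float = 8.0                  # nm, initial particle placement
    window_spacing: float = 0.2         # nm
    discard_fraction: float = 0.6       # 120 ns of 200 ns discarded
    pull_rate_nm_per_ps: float = 0.002  # recorded metadata only
    preset: str = "3nm"
    tau: float = 1.0                    # ps, OU correlation time
    dt: float = 0.1                     # ps, force sampling interval
    n_steps: int = 200_000              # force samples per window
    bounds_mode: str = "full"           # "full" or "bilayer"
    bilayer_thickness: float = 6.0      # nm, used when bounds_mode="bilayer"
    acf_cutoff_tau_factor: float = 10.0
    n_boot: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "temperature",
            "z_max",
            "window_spacing",
            "tau",
            "dt",
            "bilayer_thickness",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.discard_fraction < 1:
            raise ValueError("discard_fraction must lie in [0, 1)")
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        if self.bounds_mode not in ("full", "bilayer"):
            raise ValueError("bounds_mode must be 'full' or 'bilayer'")

    def dump_resolved(self, path) -> None:
        """Echo the fully resolved configuration with provenance tags."""
        data = {
            k: {"value": v, "provenance": PROVENANCE.get(k, "default")}
            for k, v in asdict(self).items()
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def load_config(path=None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus overrides."""
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a mapping")
        for key in loaded:
            if key not in RunConfig.__dataclass_fields__:
                raise ValueError(f"{path}: unknown config key {key!r}")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)
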