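"""Run configuration: YAML schema, validation and builders.

A run config names a mixture (preset or custom YAML spec), the initial
condition (slab for direct coexistence, homogeneous fluid for nucleation),
the thermodynamic state (T*), and the integration schedule.  Every CLI run
serializes the resolved config plus seed and code version into a manifest
sufficient to reproduce it bit-exactly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .coexistence import init_direct_coexistence, init_homogeneous
from .engine import Schedule, State, Thermostat
from .model import MIXTURE_PRESETS, MixtureSpec, build_mixture, load_mixture
from .potential import ForceField, PotentialParams

__all__ = ["RunConfig", "load_config", "write_manifest"]


@dataclass
class RunConfig:
    """Validated parameters of a simulation run."""

    mixture: str = "valency_driven"          # preset name or path to a mixture YAML
    counts: int | dict | None = None
    init: str = "slab"                        # slab | homogeneous
    density: float = 0.3                      # slab density or homogeneous density
    aspect: tuple = (1.0, 1.0, 4.0)
    slab_fraction: float = 1.0 / 3.0
    temperature: float = 0.09
    thermostat: str | None = "langevin"
    thermostat_coupling: float = 0.1
    dt: float = 0.001
    n_steps: int = 10000
    snapshot_stride: int = 200
    seed: int = 0
    potential: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.init not in ("slab", "homogeneous"):
            raise ValueError("init must be 'slab' or 'homogeneous'")
        if self.temperature <= 0 or self.dt <= 0 or self.n_steps <= 0:
            raise ValueError("temperature, dt and n_steps must be positive")
        if self.snapshot_stride <= 0:
            raise ValueError("snapshot_stride must be positive")
        if self.thermostat not in (None, "langevin", "velocity_rescale"):
            raise ValueError(f"unknown thermostat {self.thermostat!r}")
        if self.density < 0:
            raise ValueError("density must be non-negative")
        self.aspect = tuple(float(a) for a in self.aspect)
        unknown = set(self.potential) - set(PotentialParams.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown potential parameters: {sorted(unknown)}")

    # -- builders -----------------------------------------------------------

    def make_mixture(self) -> MixtureSpec:
        if self.mixture in MIXTURE_PRESETS:
            return build_mixture(self.mixture, self.counts)
        return load_mixture(self.mixture)

    def make_forcefield(self, mixture: MixtureSpec | None = None) -> ForceField:
        return ForceField(mixture or self.make_mixture(), PotentialParams(**self.potential))

    def make_state(self, mixture: MixtureSpec | None = None, seed: int | None = None) -> State:
        mixture = mixture or self.make_mixture()
        seed = self.seed if seed is None else seed
        if self.init == "slab":
            return init_direct_coexistence(
                mixture, self.density, self.aspect, self.slab_fraction,
                seed=seed, temperature=self.temperature,
            )
        return init_homogeneous(
            mixture, self.density, seed=seed, temperature=self.temperature
        )

    def make_schedule(self, seed: int | None = None) -> Schedule:
        thermo = None
        if self.thermostat is not None:
            thermo = Thermostat(self.thermostat, self.temperature, self.thermostat_coupling)
        return Schedule(
            dt=self.dt,
            n_steps=self.n_steps,
            snapshot_stride=self.snapshot_stride,
            seed=self.seed if seed is None else seed,
            thermostat=thermo,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["aspect"] = list(self.aspect)
        return d


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "aspect" in data:
        data["aspect"] = tuple(data["aspect"])
    return RunConfig(**data)


def write_manifest(config: RunConfig, seed: int, out_dir) -> Path:
    out = Path(out_dir) / "manifest.yaml"
    payload = {"config": config.to_dict(), "seed": seed, "version": __version__}
    with open(out, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
    return out
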