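"""YAML-backed configuration for the severity pipeline.

One flat document with five blocks — ``rheology``, ``waveforms``,
``geometry``, ``grid``, ``solver``, ``pipeline`` — each mapping onto the
corresponding domain dataclass.  Unknown keys are rejected so typos fail
loudly.  All defaults reproduce the package's standard desk-scale study
conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .geometry import StenosedVesselSpec
from .rheology import BloodProperties, CarreauYasudaParams, NewtonianParams
from .solver import SolverConfig
from .waveforms import WaveformSpec

__all__ = ["PipelineOptions", "Config", "default_config", "load_config"]

DEFAULT_SEVERITIES = (0.0, 0.25, 0.35, 0.50, 0.65)


@dataclass(frozen=True)
class PipelineOptions:
    """Cross-severity sweep options."""

    severities: tuple = DEFAULT_SEVERITIES
    rrt_epsilon: float = 1e-3
    decay_fraction: float = 0.15
    downstream_diameters: float = 1.0   # downstream probe offset, in diameters
    write_vtk: bool = False

    def __post_init__(self) -> None:
        sev = tuple(float(s) for s in self.severities)
        if any(b <= a for a, b in zip(sev, sev[1:])):
            raise ValueError("severities must be strictly increasing")
        object.__setattr__(self, "severities", sev)
        if self.rrt_epsilon <= 0.0:
            raise ValueError("rrt_epsilon must be > 0")
        if not (0.0 < self.decay_fraction < 1.0):
            raise ValueError("decay_fraction must be in (0, 1)")


@dataclass(frozen=True)
class GridOptions:
    n_axial: int = 96
    n_radial: int = 24
    growth_rate: float = 1.2


@dataclass
class Config:
    """Full pipeline configuration."""

    rheology: dict = field(default_factory=dict)
    waveforms: dict = field(default_factory=dict)
    geometry: dict = field(default_factory=dict)
    grid: dict = field(default_factory=dict)
    solver: dict = field(default_factory=dict)
    pipeline: dict = field(default_factory=dict)

    # ---- constructors ---------------------------------------------------
    @classmethod
    def from_dict(cls, data: dict) -> "Config":
        known = {"rheology", "waveforms", "geometry", "grid", "solver", "pipeline"}
        extra = set(data) - known
        if extra:
            raise ValueError(f"unknown config blocks: {sorted(extra)}")
        cfg = cls(**{k: dict(data.get(k, {})) for k in known})
        # validate eagerly
        cfg.blood_properties()
        cfg.waveform_spec()
        cfg.vessel_spec(0.0)
        cfg.grid_options()
        cfg.solver_config()
        cfg.pipeline_options()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "Config":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return {
            "rheology": dict(self.rheology),
            "waveforms": dict(self.waveforms),
            "geometry": dict(self.geometry),
            "grid": dict(self.grid),
            "solver": dict(self.solver),
            "pipeline": dict(self.pipeline),
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    # ---- typed views -----------------------------------------------------
    def blood_properties(self) -> BloodProperties:
        r = dict(self.rheology)
        density = float(r.pop("density", 1060.0))
        if r.pop("newtonian", False):
            mu = float(r.pop("mu", 0.0035))
            if r:
                raise ValueError(f"unknown rheology keys: {sorted(r)}")
            return BloodProperties(density=density, rheology=NewtonianParams(mu=mu))
        params = CarreauYasudaParams(**{k: float(v) for k, v in r.items()})
        return BloodProperties(density=density, rheology=params)

    def waveform_spec(self) -> WaveformSpec:
        return WaveformSpec(**{k: float(v) for k, v in self.waveforms.items()})

    def vessel_spec(self, severity: float) -> StenosedVesselSpec:
        g = dict(self.geometry)
        mm = 1e-3
        return StenosedVesselSpec(
            inlet_radius=float(g.get("radius_mm", 1.5)) * mm,
            length=float(g.get("length_mm", 30.0)) * mm,
            stenosis_center=float(g.get("stenosis_center_mm", 15.0)) * mm,
            stenosis_length=float(g.get("stenosis_length_mm", 4.0)) * mm,
            severity=float(severity),
        )

    def grid_options(self) -> GridOptions:
        return GridOptions(
            n_axial=int(self.grid.get("n_axial", 96)),
            n_radial=int(self.grid.get("n_radial", 24)),
            growth_rate=float(self.grid.get("growth_rate", 1.2)),
        )

    def solver_config(self) -> SolverConfig:
        s = {k: (int(v) if k in ("n_cycles", "max_inner_iterations",
                                 "steady_max_steps", "n_wss_samples") else float(v))
             for k, v in self.solver.items()}
        return SolverConfig(**s)

    def pipeline_options(self) -> PipelineOptions:
        p = dict(self.pipeline)
        if "severities" in p:
            p["severities"] = tuple(float(s) for s in p["severities"])
        return PipelineOptions(**p)


def default_config() -> Config:
    """The standard desk-scale study configuration."""
    return Config.from_dict({})


def load_config(path=None) -> Config:
    """Load a YAML config, or the defaults when path is None."""
    return default_config() if path is None else Config.from_yaml(path)
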