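"""Run configuration: schema, defaults, YAML round trip.

The default configuration reproduces the reference scenario: the
idealized quarter-eye with the reference tissue constants (anisotropic
cornea/limbus with C10 = 0.05 MPa, k1 = 0.010 MPa, k2 = 100; neo-Hookean
sclera C10 = 0.8 MPa; linear-elastic internals), humors pressurized to
15 mmHg and then closed, and a 120 m/s Gaussian air pulse applied 11 mm
from the apex between 40 and 60 ms after 30 ms of inflation and 10 ms of
rest.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .airjet import JetConfig
from .errors import ConfigError
from .eye_model import EyeGeometryConfig
from .fem_engine import SolverConfig
from .materials import HGOParams, LinearElasticParams, NeoHookeanParams


@dataclass(frozen=True)
class Schedule:
    """Simulation timeline (ms)."""

    inflate_end: float = 30.0        # inflow-controlled pressurization
    rest_end: float = 40.0           # quiescent hold, cavities closed
    puff_end: float = 60.0           # air pulse window
    record_end: float = 68.0         # extra recovery recorded after the puff
    target_iop_mmhg: float = 15.0

    def __post_init__(self):
        # recording may stop before the pulse window closes (batch runs
        # that only need the highest-concavity instant)
        if not (0 < self.inflate_end <= self.rest_end < self.puff_end
                and self.rest_end < self.record_end):
            raise ConfigError("schedule phases out of order")


@dataclass(frozen=True)
class Resolution:
    """Mesh/time discretization preset."""

    surface: str = "ultra"           # ultra | coarse | medium
    n_thickness: int = 3
    dt: float = 0.25                 # ms, matches the instrument frame rate

    def __post_init__(self):
        if not 2 <= self.n_thickness <= 8:
            raise ConfigError("n_thickness must lie in [2, 8]")


@dataclass
class RunConfig:
    geometry: EyeGeometryConfig = field(default_factory=EyeGeometryConfig)
    materials: dict = None
    solver: SolverConfig = field(default_factory=SolverConfig)
    jet: JetConfig = field(default_factory=JetConfig)
    schedule: Schedule = field(default_factory=Schedule)
    resolution: Resolution = field(default_factory=Resolution)
    corvis_sampling: bool = False    # resample output to 140 frames / 33 ms

    def __post_init__(self):
        if self.materials is None:
            self.materials = default_materials()
        missing = {"cornea", "limbus", "sclera"} - set(self.materials)
        if missing:
            raise ConfigError(f"missing material blocks: {sorted(missing)}")


def default_materials():
    """Material parameter blocks of the reference eye, keyed by part."""
    return {
        "cornea": HGOParams(),
        "limbus": HGOParams(),
        "sclera": NeoHookeanParams(),
        "lens_nucleus": LinearElasticParams(E=0.0003),
        "lens_cortex": LinearElasticParams(E=0.35),
        "zonule": LinearElasticParams(E=0.35),
        "vitreous_membrane": LinearElasticParams(E=0.35),
    }


def default_config() -> RunConfig:
    return RunConfig()


# ---------------------------------------------------------------------------
# YAML (de)serialization
# ---------------------------------------------------------------------------

_MATERIAL_MODELS = {
    "hgo": HGOParams,
    "neo_hookean": NeoHookeanParams,
    "linear_elastic": LinearElasticParams,
}
_MODEL_NAMES = {v: k for k, v in _MATERIAL_MODELS.items()}


def _material_to_dict(p):
    d = dataclasses.asdict(p)
    d["model"] = _MODEL_NAMES[type(p)]
    return d


def _material_from_dict(d):
    d = dict(d)
    try:
        cls = _MATERIAL_MODELS[d.pop("model")]
    except KeyError as exc:
        raise ConfigError(f"unknown or missing material model: {exc}")
    try:
        return cls(**d)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"bad material block: {exc}")


def to_dict(cfg: RunConfig) -> dict:
    return {
        "geometry": dataclasses.asdict(cfg.geometry),
        "materials": {k: _material_to_dict(v)
                      for k, v in cfg.materials.items()},
        "solver": dataclasses.asdict(cfg.solver),
        "jet": dataclasses.asdict(cfg.jet),
        "schedule": dataclasses.asdict(cfg.schedule),
        "resolution": dataclasses.asdict(cfg.resolution),
        "corvis_sampling": cfg.corvis_sampling,
    }


def from_dict(data: dict) -> RunConfig:
    data = dict(data or {})
    known = {"geometry", "materials", "solver", "jet", "schedule",
             "resolution", "corvis_sampling"}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")

    def build(cls, block):
        try:
            return cls(**(block or {}))
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"bad {cls.__name__} block: {exc}")

    mats = data.get("materials")
    materials = None if mats is None else \
        {k: _material_from_dict(v) for k, v in mats.items()}
    return RunConfig(
        geometry=build(EyeGeometryConfig, data.get("geometry")),
        materials=materials,
        solver=build(SolverConfig, data.get("solver")),
        jet=build(JetConfig, data.get("jet")),
        schedule=build(Schedule, data.get("schedule")),
        resolution=build(Resolution, data.get("resolution")),
        corvis_sampling=bool(data.get("corvis_sampling", False)),
    )


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return from_dict(data)


def save_config(cfg: RunConfig, path):
    with open(path, "w") as fh:
        yaml.safe_dump(to_dict(cfg), fh, sort_keys=False)
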