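"""Configuration objects for the attractor networks, view store, map and world.

The shipped defaults are the reference parameter set of the conjunctive
space-by-movement model: a 51 x 25 head-direction-by-rotation ring and a
15^2 x 7^2 grid-by-translation torus, with uniform inhibition J0 = -60,
interaction strength 50 and a 10 ms membrane time constant.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "HDConfig",
    "GridConfig",
    "ViewConfig",
    "MapConfig",
    "WorldConfig",
    "RunConfig",
    "load_config",
]


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class HDConfig:
    """Parameters of the head-direction-by-rotation ring attractor.

    The network lives on a (theta, nu) lattice: theta in [0, 2*pi) is the
    internal head direction (periodic), nu in [-L_r, L_r] the rotation
    coordinate (non-periodic).  A unit at rotation coordinate nu drives the
    activity bump around the ring at the angular velocity tan(nu)/tau.
    """

    n_theta: int = 51          # units along the direction axis
    n_nu: int = 25             # units along the rotation axis
    J0: float = -60.0          # uniform inhibition (< 0)
    J1: float = 50.0           # interaction strength (> 0)
    lambda_v: float = 0.8      # spread of velocity tuning in the weights
    L_r: float = 0.0095        # half-range of the rotation axis
    tau: float = 0.01          # membrane time constant [s]
    I_r: float = 50.0          # amplitude of the rotational velocity input
    epsilon: float = 0.8       # strength of velocity tuning, in [0, 1]
    sigma_r: float = 0.012     # width of the rotational velocity tuning
    I_d: float = 60.0          # amplitude of the view-cell calibration current
    sigma_d: float = 2.19      # width of the view-cell current [rad]
    dt: float = 0.001          # integration step [s]

    def __post_init__(self) -> None:
        if self.n_theta < 3 or self.n_nu < 3:
            raise ConfigError("n_theta and n_nu must both be >= 3")
        if self.L_r <= 0 or self.tau <= 0 or self.dt <= 0:
            raise ConfigError("L_r, tau and dt must be positive")
        if self.dt > self.tau:
            raise ConfigError("dt must not exceed tau (explicit Euler stability)")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ConfigError("epsilon must lie in [0, 1]")

    @property
    def n_units(self) -> int:
        return self.n_theta * self.n_nu


@dataclass
class GridConfig:
    """Parameters of the grid-by-translation torus attractor.

    Units carry four coordinates (theta_x, theta_y, nu_x, nu_y): spatial
    phases on the periodic torus and translation-velocity coordinates on
    the non-periodic [-L_t, L_t] axes.  The integer k sets the number of
    activity bumps per spatial axis; S [m] is the physical distance mapped
    onto one torus period, i.e. the spacing of the grid firing pattern.
    """

    n_theta: int = 15          # units per spatial axis
    n_nu: int = 7              # units per velocity axis
    J0: float = -60.0
    Jk: float = 50.0
    k: int = 2                 # bumps per spatial axis
    lambda_v: float = 0.8
    L_t: float = 0.3           # half-range of the velocity axes
    S: float = 30.0            # metres per grid period
    tau: float = 0.01
    I_t: float = 60.0          # amplitude of the translational velocity input
    epsilon: float = 0.8
    sigma_t: float = 0.1       # width of the translational velocity tuning
    I_p: float = 200.0         # amplitude of the view-cell calibration current
    C: float = 0.5             # baseline constant of the view-cell current
    I_maint: float = 5.0       # weak self-anchored pattern-maintenance current
    dt: float = 0.001

    def __post_init__(self) -> None:
        if self.k < 1 or int(self.k) != self.k:
            raise ConfigError("k must be a positive integer")
        if self.n_theta < 4 * self.k:
            raise ConfigError("n_theta must be >= 4*k to resolve k bumps per axis")
        if self.n_nu < 3:
            raise ConfigError("n_nu must be >= 3")
        if self.S <= 0 or self.L_t <= 0:
            raise ConfigError("S and L_t must be positive")
        if self.L_t <= 0 or self.tau <= 0 or self.dt <= 0:
            raise ConfigError("L_t, tau and dt must be positive")
        if self.dt > self.tau:
            raise ConfigError("dt must not exceed tau (explicit Euler stability)")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ConfigError("epsilon must lie in [0, 1]")

    @property
    def n_units(self) -> int:
        return self.n_theta**2 * self.n_nu**2


@dataclass
class ViewConfig:
    """Local-view-cell store settings."""

    match_threshold: float = 0.85   # similarity cutoff for reusing a template
    descriptor_range: float = 1.0   # dynamic range used to normalise distances
    refractory_frames: int = 50     # frames before a reactivation counts as familiar

    def __post_init__(self) -> None:
        if not 0.0 < self.match_threshold < 1.0:
            raise ConfigError("match_threshold must lie in (0, 1)")
        if self.descriptor_range <= 0:
            raise ConfigError("descriptor_range must be positive")


@dataclass
class MapConfig:
    """Experience-map settings."""

    creation_threshold: float = 5.0   # metres between consecutive vertices
    relax_rate: float = 0.25          # alpha of the relaxation update
    relax_iters: int = 20             # sweeps per loop closure

    def __post_init__(self) -> None:
        if not 0.0 < self.relax_rate <= 0.5:
            raise ConfigError("relax_rate must lie in (0, 0.5]")
        if self.creation_threshold <= 0:
            raise ConfigError("creation_threshold must be positive")


@dataclass
class WorldConfig:
    """Synthetic-world settings: trajectory kind plus scene-descriptor field."""

    kind: str = "line"
    params: dict[str, Any] = field(default_factory=dict)
    dt: float = 0.1                 # frame interval [s] (10 frames/s input rate)
    cell_size: float = 5.0          # spatial granularity of scenes [m]
    descriptor_length: int = 64
    noise_sd: float = 0.02          # additive descriptor noise scale

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.cell_size <= 0:
            raise ConfigError("dt and cell_size must be positive")
        if self.descriptor_length < 1:
            raise ConfigError("descriptor_length must be >= 1")


@dataclass
class RunConfig:
    """Full pipeline configuration; a run is reproducible from (config, seed)."""

    hd: HDConfig = field(default_factory=HDConfig)
    grid: GridConfig = field(default_factory=GridConfig)
    view: ViewConfig = field(default_factory=ViewConfig)
    map: MapConfig = field(default_factory=MapConfig)
    world: WorldConfig = field(default_factory=WorldConfig)
    io: dict[str, Any] = field(default_factory=dict)
    seed: int = 0
    settle_steps: int = 500    # relaxation steps at zero velocity before a run

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        kwargs: dict[str, Any] = dict(d)
        for name, sub in (
            ("hd", HDConfig),
            ("grid", GridConfig),
            ("view", ViewConfig),
            ("map", MapConfig),
            ("world", WorldConfig),
        ):
            if name in kwargs and isinstance(kwargs[name], dict):
                kwargs[name] = sub(**kwargs[name])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def load_config(path: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML or JSON file."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    return RunConfig.from_dict(data or {})
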