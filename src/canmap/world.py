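"""Synthetic world: ground-truth trajectories, noisy velocity observations,
and position-locked scene descriptors.

The generator emulates the input streams of a vehicle-mounted forward
camera pipeline: a 10 frames/s stream of angular velocity and running
speed (with optional observation noise) plus an abstract scene descriptor
per frame.  Descriptors are deterministic pseudo-random vectors keyed by
the spatial cell and heading octant of the true pose, so revisiting a place
in the same direction reproduces (up to noise) the descriptor seen before
— the property the local-view store needs for loop closure.  No images are
rendered; the image-to-descriptor step of a real system is out of scope.

Trajectories are built from piecewise-constant (speed, omega) control
segments and integrated exactly (arc formulas) at the frame interval, so
the stored pose is the exact integral of the true velocities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TrajectorySample",
    "SceneField",
    "generate_trajectory",
    "generate_scene_descriptor",
    "write_trajectory_csv",
    "read_trajectory_csv",
]

#: columns of a trajectory frame table
COLUMNS = [
    "t",
    "x",
    "y",
    "heading",
    "omega_true",
    "omega_obs",
    "speed_true",
    "speed_obs",
]


@dataclass
class TrajectorySample:
    t: float
    x: float
    y: float
    heading: float
    omega_true: float
    omega_obs: float
    speed_true: float
    speed_obs: float


@dataclass
class SceneField:
    """Deterministic scene-descriptor field.

    Identical (spatial cell, heading octant) pairs map to identical
    noiseless descriptors; descriptors of different cells are independent
    uniform vectors, so their expected similarity sits at the random
    baseline (~2/3 for the absolute-difference similarity on [0, 1]).
    """

    cell_size: float = 5.0
    descriptor_length: int = 64
    noise_sd: float = 0.02
    seed: int = 0


def _segments_for(kind: str, params: dict) -> list[tuple[float, float, float]]:
    """Return (duration, speed, omega) control segments for a trajectory kind."""
    p = dict(params)
    if kind == "line":
        length = float(p.get("length", 100.0))
        speed = float(p.get("speed", 10.0))
        return [(length / speed, speed, 0.0)]
    if kind == "circle":
        r = float(p.get("radius", 20.0))
        speed = float(p.get("speed", 5.0))
        n_turns = float(p.get("n_turns", 1.0))
        return [(2.0 * np.pi * r * n_turns / speed, speed, speed / r)]
    if kind == "figure_eight":
        r = float(p.get("radius", 20.0))
        speed = float(p.get("speed", 5.0))
        lap = 2.0 * np.pi * r / speed
        return [(lap, speed, speed / r), (lap, speed, -speed / r)]
    if kind == "l_path":
        leg = float(p.get("leg", 100.0))
        speed = float(p.get("speed", 10.0))
        omega = float(p.get("omega_turn", 0.5))
        turn = (np.pi / 2.0) / omega
        return [
            (leg / speed, speed, 0.0),
            (turn, speed, omega),
            (leg / speed, speed, 0.0),
        ]
    if kind == "street_grid":
        block = float(p.get("block", 40.0))
        speed = float(p.get("speed", 5.0))
        omega = float(p.get("omega_turn", 0.5))
        n_loops = int(p.get("n_loops", 3))
        turn_time = (np.pi / 2.0) / omega
        radius = speed / omega
        straight = block - 2.0 * radius
        if straight <= 0:
            raise ValueError("block too small for the turn radius speed/omega_turn")
        lap = [(straight / speed, speed, 0.0), (turn_time, speed, omega)] * 4
        return lap * n_loops
    raise ValueError(f"unknown trajectory kind: {kind!r}")


def generate_trajectory(
    kind: str,
    params: dict | None = None,
    seed: int = 0,
    dt: float = 0.1,
) -> pd.DataFrame:
    """Simulate a trajectory of the given kind at fixed frame interval dt.

    Supported kinds: ``line``, ``circle``, ``figure_eight``, ``l_path`` and
    ``street_grid`` (laps around a square block with rounded corners, so
    every lap revisits the previous one — the loop-closure workload).
    Observation noise: multiplicative Gaussian on speed
    (``speed_noise_frac``), additive Gaussian on omega (``omega_noise_sd``),
    both seeded and zero by default.  Columns: t, x, y, heading,
    omega_true, omega_obs, speed_true, speed_obs.
    """
    params = params or {}
    rng = np.random.default_rng(seed)
    speed_noise = float(params.get("speed_noise_frac", 0.0))
    omega_noise = float(params.get("omega_noise_sd", 0.0))
    x0 = float(params.get("x0", 0.0))
    y0 = float(params.get("y0", 0.0))
    h0 = float(params.get("heading0", 0.0))

    segments = _segments_for(kind, params)
    # quantize segment boundaries to whole frames; rescale the controls so
    # each segment keeps its exact turn angle and arc length (laps close)
    frames: list[tuple[float, float]] = []
    for duration, speed, omega in segments:
        n = max(1, round(duration / dt))
        scale = duration / (n * dt)
        frames.extend([(speed * scale, omega * scale)] * n)

    rows = np.empty((len(frames), len(COLUMNS)))
    x, y, h = x0, y0, h0
    for i, (speed, omega) in enumerate(frames):
        s_obs = speed * (1.0 + speed_noise * rng.standard_normal())
        w_obs = omega + omega_noise * rng.standard_normal()
        rows[i] = (i * dt, x, y, h, omega, w_obs, speed, s_obs)
        # exact arc update for constant (speed, omega) over dt
        if abs(omega) < 1e-12:
            x += speed * dt * np.cos(h)
            y += speed * dt * np.sin(h)
        else:
            h2 = h + omega * dt
            r = speed / omega
            x += r * (np.sin(h2) - np.sin(h))
            y += -r * (np.cos(h2) - np.cos(h))
            h = h2
    return pd.DataFrame(rows, columns=COLUMNS)


def _cell_key(field: SceneField, pose) -> tuple[int, int, int]:
    x, y, heading = float(pose[0]), float(pose[1]), float(pose[2])
    cx = int(np.floor(x / field.cell_size))
    cy = int(np.floor(y / field.cell_size))
    octant = int(np.floor(((heading % (2.0 * np.pi)) / (np.pi / 4.0)) + 0.5)) % 8
    return cx, cy, octant


def generate_scene_descriptor(
    field: SceneField,
    pose,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Descriptor for the true pose (x, y, heading).

    Deterministic uniform [0, 1] vector keyed by (spatial cell, heading
    octant); an optional ``rng`` adds seeded Gaussian noise of scale
    ``noise_sd`` (clipped back to [0, 1]).  Reversing the heading on the
    same spot changes the octant and hence the descriptor, as for a
    forward-facing camera.
    """
    cx, cy, octant = _cell_key(field, pose)
    offset = 2**20  # map possibly-negative cell indices to SeedSequence ints
    key_rng = np.random.default_rng(
        np.random.SeedSequence([field.seed, cx + offset, cy + offset, octant])
    )
    d = key_rng.uniform(0.0, 1.0, field.descriptor_length)
    if rng is not None and field.noise_sd > 0:
        d = np.clip(d + rng.normal(0.0, field.noise_sd, d.shape), 0.0, 1.0)
    return d


def write_trajectory_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_trajectory_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory CSV missing columns: {sorted(missing)}")
    return df[COLUMNS]
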