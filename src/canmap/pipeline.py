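"""Closed-loop mapping pipeline.

Per frame: the ring attractor integrates the observed angular velocity and
its decoded heading converts the observed running speed into a
translational velocity vector; the torus attractor integrates that vector;
the decoded, unwrapped torus phase yields the position estimate; the scene
descriptor is matched against the local-view store; when a stored view
reappears after an absence its calibration currents are injected (pattern
completion) and a loop-closure link is added to the experience map, which
is then relaxed.  Between calibrations the torus pattern is supported by
the weak predictive maintenance current.

A run is reproducible bit-for-bit from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import h5py
import numpy as np
import pandas as pd

from . import grid as grid_mod
from . import hd as hd_mod
from . import views as views_mod
from . import world as world_mod
from .config import RunConfig
from .expmap import ExperienceGraph, close_loop, maybe_create_vertex

__all__ = ["RunLog", "run_mapping", "vertex_errors"]

FRAME_COLUMNS = [
    "t",
    "x_true",
    "y_true",
    "heading_true",
    "psi",
    "phi",
    "theta_x_hat",
    "theta_y_hat",
    "x_hat",
    "y_hat",
    "view_id",
    "view_is_new",
    "calibrating",
    "vertex_id",
    "closure",
]


@dataclass
class RunLog:
    """Per-frame decodings plus map events and run summary."""

    frames: pd.DataFrame
    events: list[dict[str, Any]] = field(default_factory=list)
    summary: dict[str, Any] = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.frames.to_csv(path, index=False)


def _wrap_pi(a: float) -> float:
    return float(np.angle(np.exp(1j * a)))


def run_mapping(
    config: RunConfig,
    trajectory: pd.DataFrame | None = None,
) -> tuple[ExperienceGraph, RunLog]:
    """Run the full velocity -> HD -> grid -> views -> map loop.

    ``trajectory`` defaults to the synthetic stream described by
    ``config.world``; a recorded stream with the same schema can be passed
    instead.  Any module error aborts with the frame index.
    """
    hd_cfg, grid_cfg = config.hd, config.grid
    axes = grid_mod.ProjectionAxes.square_torus()
    hd_kernel = hd_mod.build_hd_weight_kernel(hd_cfg)
    grid_kernel = grid_mod.build_grid_weight_kernel(grid_cfg)

    hd_state = hd_mod.settle(hd_cfg, hd_kernel, seed=config.seed, n_steps=config.settle_steps)
    grid_state = grid_mod.settle(
        grid_cfg, grid_kernel, seed=config.seed, n_steps=config.settle_steps, axes=axes
    )
    psi0 = hd_mod.decode_heading(hd_state, hd_cfg).psi
    grid_dec = grid_mod.decode_grid_phases(grid_state, axes, grid_cfg)
    tracker = grid_mod.PositionTracker(grid_cfg)
    tracker.begin(grid_dec)
    origin = np.array(tracker.position)

    if trajectory is None:
        trajectory = world_mod.generate_trajectory(
            config.world.kind, config.world.params, seed=config.seed, dt=config.world.dt
        )
    scene = world_mod.SceneField(
        cell_size=config.world.cell_size,
        descriptor_length=config.world.descriptor_length,
        noise_sd=config.world.noise_sd,
        seed=config.seed,
    )
    noise_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    store = views_mod.ViewStore.from_config(config.view)
    graph = ExperienceGraph(
        creation_threshold=config.map.creation_threshold,
        relax_rate=config.map.relax_rate,
        relax_iters=config.map.relax_iters,
    )

    h0 = float(trajectory["heading"].iloc[0])
    start_xy = trajectory[["x", "y"]].iloc[0].to_numpy(dtype=float)
    substeps = max(1, round(config.world.dt / hd_cfg.dt))
    gsubsteps = max(1, round(config.world.dt / grid_cfg.dt))
    refractory = config.view.refractory_frames

    snapshot_path = config.io.get("snapshot_path")
    snapshot_every = int(config.io.get("snapshot_every", 50))
    snap_file = h5py.File(snapshot_path, "w") if snapshot_path else None

    pending_hd_view: np.ndarray | float = 0.0
    pending_grid_view: np.ndarray | None = None
    calibrating_id: int | None = None
    events: list[dict[str, Any]] = []
    rows: list[list] = []
    n_closures = 0

    try:
        for i, row in enumerate(trajectory.itertuples(index=False)):
            # (1) ring attractor: angular velocity in, heading out
            hd_ext = hd_mod.angular_velocity_input(row.omega_obs, hd_cfg)
            for _ in range(substeps):
                hd_state = hd_mod.hd_step(
                    hd_state, hd_ext, pending_hd_view, hd_cfg, hd_kernel
                )
            hd_dec = hd_mod.decode_heading(hd_state, hd_cfg)
            psi_world = h0 + _wrap_pi(hd_dec.psi - psi0)

            # (2) torus attractor: translational velocity in, position out
            v_vec = grid_mod.heading_speed_to_velocity(max(row.speed_obs, 0.0), psi_world)
            grid_ext = grid_mod.translational_velocity_input(v_vec, grid_cfg)
            if pending_grid_view is not None:
                grid_view = pending_grid_view
            else:
                grid_view = grid_mod.maintenance_current(
                    grid_dec, grid_cfg, axes, config.world.dt
                )
            for _ in range(gsubsteps):
                grid_state = grid_mod.grid_step(
                    grid_state, grid_ext, grid_view, grid_cfg, grid_kernel
                )
            grid_dec = grid_mod.decode_grid_phases(
                grid_state, axes, grid_cfg, floor=1e-30
            )
            tracker.update(grid_dec)
            pos = np.array(tracker.position) - origin + start_xy

            # (3) local view: match the scene, decide on calibration
            descriptor = world_mod.generate_scene_descriptor(
                scene, (row.x, row.y, row.heading), rng=noise_rng
            )
            cell, is_new = views_mod.match_or_create(
                descriptor, store, hd_dec.psi, (grid_dec.theta_x_hat, grid_dec.theta_y_hat)
            )
            reactivated = (
                not is_new
                and cell.last_active_frame >= 0
                and (i - cell.last_active_frame) > refractory
            )
            closure_started = False
            if calibrating_id == cell.id:
                pass  # keep injecting while the same familiar view stays matched
            elif reactivated:
                calibrating_id = cell.id
                closure_started = True
            else:
                calibrating_id = None
            cell.last_active_frame = i

            # (4) experience map
            vertex, _ = maybe_create_vertex(graph, pos, cell)
            if vertex is not None:
                if cell.vertex_id is None:
                    cell.vertex_id = vertex.id
                events.append(
                    {
                        "type": "vertex",
                        "frame": i,
                        "id": vertex.id,
                        "true": (float(row.x), float(row.y)),
                        "decoded": (float(pos[0]), float(pos[1])),
                    }
                )
            if (
                closure_started
                and cell.vertex_id is not None
                and cell.vertex_id != graph.current_id
            ):
                cur = graph.current
                e_before = graph.energy()
                link = close_loop(
                    graph, cur.id, cell.vertex_id, pos - cur.position
                )
                if link is not None:
                    n_closures += 1
                    events.append(
                        {
                            "type": "closure",
                            "frame": i,
                            "from": cur.id,
                            "to": cell.vertex_id,
                            "energy_before": e_before,
                            "energy_after": graph.energy(),
                        }
                    )

            # (5) currents for the next frame
            if calibrating_id is not None:
                pending_hd_view = views_mod.hd_view_current(cell, hd_cfg)
                pending_grid_view = views_mod.grid_view_current(cell, axes, grid_cfg)
            else:
                pending_hd_view = 0.0
                pending_grid_view = None

            rows.append(
                [
                    row.t,
                    row.x,
                    row.y,
                    row.heading,
                    hd_dec.psi,
                    hd_dec.phi,
                    grid_dec.theta_x_hat,
                    grid_dec.theta_y_hat,
                    pos[0],
                    pos[1],
                    cell.id,
                    bool(is_new),
                    calibrating_id is not None,
                    -1 if graph.current_id is None else graph.current_id,
                    closure_started,
                ]
            )

            if snap_file is not None and i % snapshot_every == 0:
                g = snap_file.create_group(f"frame_{i:06d}")
                g["hd_rates"] = hd_state.rates
                g["grid_rates"] = grid_state.rates
                g["map_positions"] = np.array(
                    [v.position for v in graph.vertices.values()]
                    or np.zeros((0, 2))
                )
                g.attrs["t"] = row.t
    except Exception as err:
        raise RuntimeError(f"pipeline aborted at frame {len(rows)}: {err}") from err
    finally:
        if snap_file is not None:
            snap_file.close()

    frames = pd.DataFrame(rows, columns=FRAME_COLUMNS)
    true_end = trajectory[["x", "y"]].iloc[-1].to_numpy(dtype=float)
    est_end = frames[["x_hat", "y_hat"]].iloc[-1].to_numpy(dtype=float)
    path_length = float(
        (trajectory["speed_true"] * config.world.dt).sum()
    )
    summary = {
        "n_frames": len(frames),
        "n_vertices": len(graph),
        "n_views": len(store.cells),
        "n_closures": n_closures,
        "path_length": path_length,
        "final_position_error": float(np.hypot(*(est_end - true_end))),
        "final_energy": graph.energy(),
    }
    return graph, RunLog(frames=frames, events=events, summary=summary)


def vertex_errors(graph: ExperienceGraph, log: RunLog) -> tuple[float, float]:
    """Mean vertex position error vs ground truth, before and after relaxation.

    'Before' uses each vertex's decoded position at creation; 'after' uses
    its current (relaxed) position.  Both are compared against the true
    pose at the creation frame.
    """
    pre, post = [], []
    for ev in log.events:
        if ev["type"] != "vertex":
            continue
        true = np.asarray(ev["true"])
        pre.append(float(np.hypot(*(np.asarray(ev["decoded"]) - true))))
        post.append(
            float(np.hypot(*(graph.vertices[ev["id"]].position - true)))
        )
    if not pre:
        return 0.0, 0.0
    return float(np.mean(pre)), float(np.mean(post))
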