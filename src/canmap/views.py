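"""Local-view cells: scene-template store and calibration currents.

A local-view cell binds a scene descriptor (an abstract fixed-length vector;
the image-to-descriptor step is a pluggable adapter) to the bump phases
(psi, theta_x, theta_y) decoded when the scene was first observed.  When a
stored view is recognised again, the cell injects currents into both
attractor networks, pulling their bumps back to the anchored phases —
pattern completion as the calibration mechanism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import grid as grid_mod
from . import hd as hd_mod
from .config import GridConfig, HDConfig, ViewConfig

__all__ = [
    "LocalViewCell",
    "ViewStore",
    "match_or_create",
    "hd_view_current",
    "grid_view_current",
]


@dataclass
class LocalViewCell:
    """A stored scene descriptor bound to anchor phases (immutable after creation)."""

    id: int
    template: np.ndarray
    anchor_psi: float
    anchor_theta: tuple[float, float]
    activation: float = 0.0        # current match score in [0, 1]
    last_active_frame: int = -1    # pipeline bookkeeping
    vertex_id: int | None = None   # associated experience-map vertex


@dataclass
class ViewStore:
    """Ordered collection of local-view cells with a similarity cutoff.

    Similarity between descriptors is 1 minus the mean absolute difference
    normalised by the descriptor range; at most one cell (the best match)
    is active per frame.
    """

    match_threshold: float = 0.85
    descriptor_range: float = 1.0
    cells: list[LocalViewCell] = field(default_factory=list)

    @classmethod
    def from_config(cls, config: ViewConfig) -> "ViewStore":
        return cls(
            match_threshold=config.match_threshold,
            descriptor_range=config.descriptor_range,
        )

    def similarity(self, a: np.ndarray, b: np.ndarray) -> float:
        d = float(np.mean(np.abs(np.asarray(a, float) - np.asarray(b, float))))
        return float(np.clip(1.0 - d / self.descriptor_range, 0.0, 1.0))

    # -- persistence --------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        data = {
            "match_threshold": self.match_threshold,
            "descriptor_range": self.descriptor_range,
            "cells": [
                {
                    "id": c.id,
                    "template": np.asarray(c.template).tolist(),
                    "anchor_psi": c.anchor_psi,
                    "anchor_theta": list(c.anchor_theta),
                }
                for c in self.cells
            ],
        }
        Path(path).write_text(json.dumps(data))

    @classmethod
    def from_json(cls, path: str | Path) -> "ViewStore":
        data = json.loads(Path(path).read_text())
        store = cls(
            match_threshold=data["match_threshold"],
            descriptor_range=data["descriptor_range"],
        )
        for c in data["cells"]:
            store.cells.append(
                LocalViewCell(
                    id=c["id"],
                    template=np.asarray(c["template"], dtype=float),
                    anchor_psi=c["anchor_psi"],
                    anchor_theta=tuple(c["anchor_theta"]),
                )
            )
        return store


def match_or_create(
    descriptor: np.ndarray,
    store: ViewStore,
    current_psi: float,
    current_theta: tuple[float, float],
) -> tuple[LocalViewCell, bool]:
    """Return the best-matching stored cell, or create one anchored here.

    If the best similarity reaches the store threshold the matching cell is
    returned active with its stored anchors; otherwise a new cell is created
    with anchors at the current decoded phases.
    """
    descriptor = np.asarray(descriptor, dtype=float)
    if descriptor.size == 0:
        raise ValueError("empty scene descriptor")
    best: LocalViewCell | None = None
    best_sim = -1.0
    for cell in store.cells:
        s = store.similarity(descriptor, cell.template)
        if s > best_sim:
            best, best_sim = cell, s
    if best is not None and best_sim >= store.match_threshold:
        best.activation = best_sim
        return best, False
    cell = LocalViewCell(
        id=len(store.cells),
        template=descriptor.copy(),
        anchor_psi=float(current_psi),
        anchor_theta=(float(current_theta[0]), float(current_theta[1])),
        activation=1.0,
    )
    store.cells.append(cell)
    return cell, True


def hd_view_current(cell: LocalViewCell, config: HDConfig) -> np.ndarray:
    """Gaussian current pulling the ring bump toward the cell's anchor heading.

    I(theta) = I_d * exp(-||theta - psi||^2 / (2 sigma_d^2)) with the
    circular distance; constant across the rotation axis (shape
    (n_theta, 1)).
    """
    th = hd_mod.theta_coords(config)
    d = np.mod(th - cell.anchor_psi + np.pi, 2.0 * np.pi) - np.pi
    return (config.I_d * np.exp(-(d**2) / (2.0 * config.sigma_d**2)))[:, None]


def grid_view_current(
    cell: LocalViewCell,
    axes: grid_mod.ProjectionAxes,
    config: GridConfig,
) -> np.ndarray:
    """Triad current imprinting the cell's anchor phase on the torus.

    I(theta) = I_p * [(1/3) sum_j cos(k (theta - anchor).e_j / l_j) + C],
    identical for all velocity labels (shape (n_theta, n_theta, 1, 1)).
    """
    return grid_mod.pattern_current(
        cell.anchor_theta, config, axes, config.I_p, config.C
    )
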