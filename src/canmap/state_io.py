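"""HDF5 snapshots of attractor states."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from . import grid as grid_mod
from . import hd as hd_mod
from .config import GridConfig, HDConfig

__all__ = ["save_hd_state", "load_hd_state", "save_grid_state", "load_grid_state"]


def save_hd_state(state: hd_mod.HDState, config: HDConfig, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f["rates"] = state.rates
        f["theta"] = hd_mod.theta_coords(config)
        f["nu"] = hd_mod.nu_coords(config)
        f.attrs["t"] = state.t


def load_hd_state(path: str | Path) -> hd_mod.HDState:
    with h5py.File(path, "r") as f:
        return hd_mod.HDState(rates=np.asarray(f["rates"]), t=float(f.attrs["t"]))


def save_grid_state(
    state: grid_mod.GridState, config: GridConfig, path: str | Path
) -> None:
    with h5py.File(path, "w") as f:
        f["rates"] = state.rates
        f["theta"] = grid_mod.theta_coords(config)
        f["nu"] = grid_mod.nu_coords(config)
        f.attrs["t"] = state.t


def load_grid_state(path: str | Path) -> grid_mod.GridState:
    with h5py.File(path, "r") as f:
        return grid_mod.GridState(rates=np.asarray(f["rates"]), t=float(f.attrs["t"]))
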