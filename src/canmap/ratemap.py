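"""Spatially binned firing-rate maps of single units along a trajectory."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = ["RateMap", "compute_rate_map", "compute_rate_map_from_series"]


@dataclass
class RateMap:
    """Mean firing rate per spatial bin; unvisited bins are NaN (not zero)."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    rate: np.ndarray      # shape (n_x_bins, n_y_bins), NaN where unvisited
    counts: np.ndarray

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    def to_csv(self, path: str | Path) -> None:
        xc, yc = np.meshgrid(self.x_centers, self.y_centers, indexing="ij")
        pd.DataFrame(
            {
                "x": xc.ravel(),
                "y": yc.ravel(),
                "rate": self.rate.ravel(),
                "n_visits": self.counts.ravel().astype(int),
            }
        ).to_csv(path, index=False)

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f["x_edges"] = self.x_edges
            f["y_edges"] = self.y_edges
            f["rate"] = self.rate
            f["counts"] = self.counts


def compute_rate_map_from_series(
    rates: np.ndarray,
    positions: np.ndarray,
    bin_size: float,
) -> RateMap:
    """Bin a per-frame rate series over the visited positions."""
    rates = np.asarray(rates, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if len(rates) != len(positions):
        raise ValueError("rates and positions must be aligned")
    x, y = positions[:, 0], positions[:, 1]
    pad = 1e-9
    x_edges = np.arange(x.min(), x.max() + bin_size + pad, bin_size)
    y_edges = np.arange(y.min(), y.max() + bin_size + pad, bin_size)
    counts, _, _ = np.histogram2d(x, y, bins=(x_edges, y_edges))
    sums, _, _ = np.histogram2d(x, y, bins=(x_edges, y_edges), weights=rates)
    with np.errstate(invalid="ignore"):
        rate = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return RateMap(x_edges=x_edges, y_edges=y_edges, rate=rate, counts=counts)


def compute_rate_map(
    unit_index: tuple,
    state_history: np.ndarray,
    position_history: np.ndarray,
    bin_size: float,
) -> RateMap:
    """Rate map of one unit: mean rate per visited spatial bin.

    ``state_history`` holds one rate field per frame (frame axis first);
    ``unit_index`` selects the unit within a field.  The two histories must
    be frame-aligned.
    """
    hist = np.asarray(state_history, dtype=float)
    series = hist[(slice(None), *unit_index)]
    return compute_rate_map_from_series(series, position_history, bin_size)
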