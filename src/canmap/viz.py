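"""Heat-map replay of recorded network states and the evolving map."""

from __future__ import annotations

from pathlib import Path

import h5py
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["replay_states", "plot_hd_state", "plot_grid_state"]


def plot_hd_state(rates: np.ndarray, ax=None):
    """Heat map of the ring attractor: direction on x, rotation on y."""
    if ax is None:
        _, ax = plt.subplots()
    ax.imshow(rates.T, origin="lower", aspect="auto", cmap="jet")
    ax.set_xlabel("theta (units)")
    ax.set_ylabel("nu (units)")
    return ax


def plot_grid_state(rates: np.ndarray, ax=None):
    """Mosaic of torus slices, one panel per velocity label."""
    if ax is None:
        _, ax = plt.subplots()
    nth = rates.shape[0]
    nnu = rates.shape[2]
    mosaic = np.zeros((nnu * nth, nnu * nth))
    for a in range(nnu):
        for b in range(nnu):
            mosaic[a * nth : (a + 1) * nth, b * nth : (b + 1) * nth] = rates[:, :, b, a]
    ax.imshow(mosaic.T, origin="lower", cmap="jet")
    ax.set_xticks([])
    ax.set_yticks([])
    return ax


def replay_states(snapshot_path: str | Path, out_dir: str | Path) -> list[Path]:
    """Write per-frame PNGs (HD + grid heat maps, current map) from snapshots.

    A missing or empty snapshot file produces no output and succeeds.
    """
    snapshot_path = Path(snapshot_path)
    out_dir = Path(out_dir)
    written: list[Path] = []
    if not snapshot_path.exists():
        return written
    with h5py.File(snapshot_path, "r") as f:
        keys = sorted(f.keys())
        if not keys:
            return written
        out_dir.mkdir(parents=True, exist_ok=True)
        for key in keys:
            g = f[key]
            fig, axs = plt.subplots(1, 3, figsize=(12, 4))
            plot_hd_state(np.asarray(g["hd_rates"]), axs[0])
            axs[0].set_title("HD-by-rotation")
            plot_grid_state(np.asarray(g["grid_rates"]), axs[1])
            axs[1].set_title("grid-by-translation")
            pos = np.asarray(g["map_positions"])
            if pos.size:
                axs[2].plot(pos[:, 0], pos[:, 1], "g.-", lw=0.8, ms=3)
            axs[2].set_title("experience map")
            axs[2].set_aspect("equal", adjustable="datalim")
            fig.suptitle(f"t = {float(g.attrs['t']):.1f} s")
            path = out_dir / f"{key}.png"
            fig.savefig(path, dpi=80)
            plt.close(fig)
            written.append(path)
    return written
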