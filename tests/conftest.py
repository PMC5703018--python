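import numpy as np
import pytest

from canmap import grid as grid_mod
from canmap import hd as hd_mod
from canmap.config import GridConfig, HDConfig


@pytest.fixture(scope="session")
def hd_cfg():
    return HDConfig()


@pytest.fixture(scope="session")
def hd_kernel(hd_cfg):
    return hd_mod.build_hd_weight_kernel(hd_cfg)


@pytest.fixture(scope="session")
def hd_settled(hd_cfg, hd_kernel):
    """Ring attractor after random init and 500 relaxation steps at V = 0."""
    return hd_mod.settle(hd_cfg, hd_kernel, seed=1)


@pytest.fixture(scope="session")
def grid_cfg():
    return GridConfig()


@pytest.fixture(scope="session")
def grid_kernel(grid_cfg):
    return grid_mod.build_grid_weight_kernel(grid_cfg)


@pytest.fixture(scope="session")
def axes():
    return grid_mod.ProjectionAxes.square_torus()


@pytest.fixture(scope="session")
def grid_settled(grid_cfg, grid_kernel, axes):
    """Torus attractor after the anchored bootstrap settle at V = (0, 0)."""
    return grid_mod.settle(grid_cfg, grid_kernel, seed=1, axes=axes)


@pytest.fixture(scope="session")
def small_grid_cfg():
    """Small torus for dense-matrix oracle comparisons."""
    return GridConfig(n_theta=8, n_nu=3)


def wrap_components(mask: np.ndarray) -> int:
    """Count connected super-threshold regions on a 2-torus mask."""
    from scipy import ndimage

    lab, n = ndimage.label(mask, structure=np.ones((3, 3)))
    parent = list(range(n + 1))

    def find(a):
        while parent[a] != a:
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    nx, ny = mask.shape
    for i in range(nx):
        a, b = lab[i, 0], lab[i, -1]
        if a and b:
            union(a, b)
    for j in range(ny):
        a, b = lab[0, j], lab[-1, j]
        if a and b:
            union(a, b)
    # also merge diagonal wrap neighbours
    for i in range(nx):
        for di in (-1, 0, 1):
            a, b = lab[i, 0], lab[(i + di) % nx, -1]
            if a and b:
                union(a, b)
    return len({find(l) for l in range(1, n + 1)})
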