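import numpy as np
import pytest

from reefsim.grid import GridSpec, build_grid, place_reefs


@pytest.fixture(scope="session")
def grid211() -> GridSpec:
    """The standard 211x211 arena of 10 m cells."""
    return build_grid(211, 10.0)


@pytest.fixture(scope="session")
def small_grid() -> GridSpec:
    """A 21x21 arena, big enough to hold reefs at step 1-3."""
    return build_grid(21, 10.0)


@pytest.fixture(scope="session")
def layout_s1_step3(grid211):
    """1x1 natural reef with the artificial reef ~127 m away."""
    return place_reefs(grid211, s_r=1, distance_step=3)


def brute_force_distance(grid: GridSpec, cells) -> np.ndarray:
    """Independent oracle: per-cell min over reef cells of centre distance."""
    out = np.empty(grid.shape)
    for r in range(grid.n_side):
        for c in range(grid.n_side):
            out[r, c] = min(
                ((r - rr) ** 2 + (c - cc) ** 2) ** 0.5 for rr, cc in cells
            ) * grid.cell_size
    return out
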