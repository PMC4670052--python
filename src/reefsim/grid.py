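"""Discrete spatial arena: grid definition, reef placement, distance fields.

The model world is a square lattice of identical square cells. A natural
reef (NR) is a small block of cells at the grid centre; the artificial
reef (AR) is a single cell placed along the main diagonal. All distances
are Euclidean between cell centres, in metres.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable

import numpy as np

__all__ = [
    "GridSpec",
    "ReefLayout",
    "build_grid",
    "place_reefs",
    "distance_field",
    "DIAGONAL_STEP_CELLS",
    "N_DISTANCE_STEPS",
    "realized_separation",
]

#: Reef separations are laid out in diagonal steps of this many cells, so
#: each step adds 3 * cell_size * sqrt(2) metres of centre-to-centre distance
#: (42.43 m on the default 10 m grid).
DIAGONAL_STEP_CELLS = 3

#: Number of reef-separation levels on the standard distance ladder.
N_DISTANCE_STEPS = 12


@dataclass(frozen=True)
class GridSpec:
    """Square lattice of ``n_side`` x ``n_side`` cells of ``cell_size`` metres.

    ``n_side`` must be odd so a unique centre cell exists (the natural reef
    anchor). The default 211 x 211 arena of 10 m cells spans 2.11 km a side,
    large enough that edge truncation is negligible for the parameter ranges
    explored here.
    """

    n_side: int = 211
    cell_size: float = 10.0

    def __post_init__(self) -> None:
        if not isinstance(self.n_side, (int, np.integer)) or self.n_side < 3:
            raise ValueError(f"n_side must be an integer >= 3, got {self.n_side!r}")
        if self.n_side % 2 == 0:
            raise ValueError(f"n_side must be odd so a centre cell exists, got {self.n_side}")
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size!r}")

    @property
    def n_cells(self) -> int:
        return self.n_side * self.n_side

    @property
    def centre(self) -> tuple[int, int]:
        c = self.n_side // 2
        return (c, c)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_side, self.n_side)


def build_grid(n_side: int = 211, cell_size: float = 10.0) -> GridSpec:
    """Construct a :class:`GridSpec`, validating size and cell dimensions."""
    return GridSpec(n_side=n_side, cell_size=cell_size)


def realized_separation(step: int, cell_size: float = 10.0) -> float:
    """Centre-to-nearest-centre reef separation for a diagonal step index.

    Step ``k`` places the artificial reef ``3k`` cells away in both row and
    column, giving ``3k * cell_size * sqrt(2)`` metres (42.43, 84.85, ...,
    509.12 m on the default grid).
    """
    if not 1 <= step <= N_DISTANCE_STEPS:
        raise ValueError(f"distance step must be in 1..{N_DISTANCE_STEPS}, got {step}")
    return DIAGONAL_STEP_CELLS * step * cell_size * math.sqrt(2.0)


@dataclass(frozen=True)
class ReefLayout:
    """Placement of the natural-reef block and the single artificial-reef cell.

    ``d_r`` records the *realized* centre-to-nearest-centre separation in
    metres (not a nominal label). Natural and artificial cells are disjoint
    and within grid bounds; the artificial reef is always exactly one cell.
    """

    grid: GridSpec
    natural_cells: tuple[tuple[int, int], ...]
    artificial_cells: tuple[tuple[int, int], ...]
    s_r: int
    d_r: float

    def __post_init__(self) -> None:
        nat = set(self.natural_cells)
        art = set(self.artificial_cells)
        if not nat or not art:
            raise ValueError("both reefs must have at least one cell")
        if len(art) != 1:
            raise ValueError("artificial reef must be exactly one cell")
        if nat & art:
            raise ValueError("natural and artificial reef cells must be disjoint")
        for r, c in nat | art:
            if not (0 <= r < self.grid.n_side and 0 <= c < self.grid.n_side):
                raise ValueError(f"reef cell {(r, c)} outside grid bounds")
        if not self.d_r > 0:
            raise ValueError("reef separation d_r must be positive")

    @property
    def artificial_cell(self) -> tuple[int, int]:
        return self.artificial_cells[0]

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_side": self.grid.n_side,
                "cell_size": self.grid.cell_size,
                "natural_cells": [list(c) for c in self.natural_cells],
                "artificial_cells": [list(c) for c in self.artificial_cells],
                "s_r": self.s_r,
                "realized_D_r": self.d_r,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ReefLayout":
        obj = json.loads(text)
        return cls(
            grid=GridSpec(obj["n_side"], obj["cell_size"]),
            natural_cells=tuple(tuple(c) for c in obj["natural_cells"]),
            artificial_cells=tuple(tuple(c) for c in obj["artificial_cells"]),
            s_r=obj["s_r"],
            d_r=obj["realized_D_r"],
        )


def place_reefs(grid: GridSpec, s_r: int, distance_step: int) -> ReefLayout:
    """Place an ``s_r`` x ``s_r`` natural reef at the grid centre and a 1 x 1
    artificial reef along the main diagonal.

    The artificial cell sits ``3 * distance_step`` cells away (in both row
    and column) from the nearest natural-reef cell, reproducing the standard
    ladder of 12 separations ~42-509 m on the default grid.
    """
    if s_r not in (1, 2, 3):
        raise ValueError(f"natural reef side s_r must be 1, 2 or 3 cells, got {s_r}")
    if not 1 <= distance_step <= N_DISTANCE_STEPS:
        raise ValueError(
            f"distance step must be in 1..{N_DISTANCE_STEPS}, got {distance_step}"
        )

    cr, cc = grid.centre
    start = cr - (s_r - 1) // 2
    rows = range(start, start + s_r)
    natural = tuple((r, c) for r in rows for c in rows)
    anchor = start + s_r - 1  # natural cell nearest the artificial reef
    offset = DIAGONAL_STEP_CELLS * distance_step
    ar = (anchor + offset, anchor + offset)

    for r, c in natural + (ar,):
        if not (0 <= r < grid.n_side and 0 <= c < grid.n_side):
            raise ValueError(
                f"reef layout (s_r={s_r}, step={distance_step}) exceeds "
                f"{grid.n_side}x{grid.n_side} grid bounds at cell {(r, c)}"
            )

    d_r = offset * grid.cell_size * math.sqrt(2.0)
    return ReefLayout(grid=grid, natural_cells=natural, artificial_cells=(ar,), s_r=s_r, d_r=d_r)


def distance_field(grid: GridSpec, reef_cells: Iterable[tuple[int, int]]) -> np.ndarray:
    """Per-cell Euclidean distance (metres) to the nearest reef cell centre.

    Zero exactly on reef cells. Distance fields depend only on geometry, so
    repeated calls with the same layout are served from a cache.
    """
    cells = tuple(sorted(set(map(tuple, reef_cells))))
    if not cells:
        raise ValueError("reef_cells must be non-empty")
    for r, c in cells:
        if not (0 <= r < grid.n_side and 0 <= c < grid.n_side):
            raise ValueError(f"reef cell {(r, c)} outside grid bounds")
    return _distance_field_cached(grid.n_side, grid.cell_size, cells).copy()


@lru_cache(maxsize=256)
def _distance_field_cached(
    n_side: int, cell_size: float, cells: tuple[tuple[int, int], ...]
) -> np.ndarray:
    rows = np.arange(n_side, dtype=np.float64)
    rr = np.asarray([c[0] for c in cells], dtype=np.float64)
    cc = np.asarray([c[1] for c in cells], dtype=np.float64)
    # min over reef cells of squared index offsets, then one sqrt at the end
    dr2 = (rows[:, None] - rr[None, :]) ** 2  # (n_side, n_reef)
    dc2 = (rows[:, None] - cc[None, :]) ** 2
    d2 = (dr2[:, None, :] + dc2[None, :, :]).min(axis=2)
    out = np.sqrt(d2) * cell_size
    out.flags.writeable = False
    return out
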