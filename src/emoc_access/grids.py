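"""Georeferenced single-band grids.

All layers in the pipeline (elevation, land cover, pace, travel time, zones,
population) share one planar metric frame: a north-up affine transform with
square cells, addressed by 0-based ``(row, col)`` with row 0 at the northern
edge.  Layers passed jointly to any operation must share both transform and
shape exactly; there is no on-the-fly resampling or reprojection.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

__all__ = ["GridTransform", "Grid", "require_aligned"]


@dataclass(frozen=True)
class GridTransform:
    """North-up affine geometry: west edge, north edge, square cell size (m).

    Point-in-cell assignment uses half-open footprints: a point lying on a
    shared edge belongs to the cell to its south-east, so every point in the
    extent maps to exactly one cell.
    """

    x0: float
    y0: float
    cell: float

    def __post_init__(self) -> None:
        if not self.cell > 0:
            raise ValueError(f"cell size must be positive, got {self.cell}")

    def cell_center(self, row, col):
        """World coordinates of cell centers (vectorised)."""
        x = self.x0 + (np.asarray(col) + 0.5) * self.cell
        y = self.y0 - (np.asarray(row) + 0.5) * self.cell
        return x, y

    def world_to_cell(self, x, y):
        """Map world points to (row, col) under the south-east edge rule."""
        col = np.floor((np.asarray(x, dtype=float) - self.x0) / self.cell).astype(int)
        row = np.floor((self.y0 - np.asarray(y, dtype=float)) / self.cell).astype(int)
        return row, col

    def extent(self, shape):
        """(xmin, ymin, xmax, ymax) of an array of the given shape."""
        nrows, ncols = shape
        return (self.x0, self.y0 - nrows * self.cell, self.x0 + ncols * self.cell, self.y0)


@dataclass
class Grid:
    """A 2-D array tied to a :class:`GridTransform`."""

    data: np.ndarray
    transform: GridTransform

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"grid data must be 2-D, got shape {self.data.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def cell(self) -> float:
        return self.transform.cell

    def like(self, data: np.ndarray) -> "Grid":
        """New grid with the same geometry and different values."""
        data = np.asarray(data)
        if data.shape != self.shape:
            raise ValueError(f"shape mismatch: {data.shape} vs {self.shape}")
        return Grid(data, self.transform)

    def copy(self) -> "Grid":
        return Grid(self.data.copy(), self.transform)

    def contains_points(self, x, y) -> np.ndarray:
        xmin, ymin, xmax, ymax = self.transform.extent(self.shape)
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= xmin) & (x < xmax) & (y > ymin) & (y <= ymax)


def require_aligned(*grids: Grid) -> None:
    """Raise unless all grids share shape and transform exactly."""
    first = grids[0]
    for g in grids[1:]:
        if g.shape != first.shape or g.transform != first.transform:
            raise ValueError(
                "misaligned grids: "
                f"shape {first.shape} / transform {dataclasses.astuple(first.transform)} vs "
                f"shape {g.shape} / transform {dataclasses.astuple(g.transform)}"
            )
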