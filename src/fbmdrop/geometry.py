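"""Euclidean embedding of a network layer as a grid of square neurons.

A layer of ``N * N`` neurons is laid out in the unit square ``[0, 1]^2``.
Each neuron is a square cell of side ``1/(2N)``, and adjacent cells are
separated by gaps of the same width, so each axis tiles exactly:
``N * side + N * gap = 1``.  Cells cover one quarter of the layer area.
Cell ``k`` along an axis occupies ``[k/N, k/N + 1/(2N))``; membership uses
half-open intervals so no point belongs to two cells.  Coordinates are
continuous, origin at the lower-left; the flat neuron index is
``row * N + col`` with row 0 at the bottom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class NeuronGrid:
    """Geometry of an ``N x N`` layer of square neurons in the unit square."""

    n_side: int
    cell_side: float = field(init=False)
    cell_spacing: float = field(init=False)

    def __post_init__(self) -> None:
        if self.n_side < 1:
            raise ValueError(f"n_side must be a positive integer, got {self.n_side}")
        object.__setattr__(self, "cell_side", 1.0 / (2 * self.n_side))
        object.__setattr__(self, "cell_spacing", 1.0 / (2 * self.n_side))

    @property
    def neuron_count(self) -> int:
        return self.n_side * self.n_side

    @property
    def covered_fraction(self) -> float:
        """Fraction of layer area covered by cells: N^2 * (1/(2N))^2 = 1/4."""
        return self.neuron_count * self.cell_side**2

    @property
    def cell_origins(self) -> np.ndarray:
        """Lower-left corners of all cells, shape ``(N^2, 2)``, flat order."""
        k = np.arange(self.n_side) / self.n_side
        xs, ys = np.meshgrid(k, k)  # ys varies along rows
        return np.column_stack([xs.ravel(), ys.ravel()])

    def cell_center(self, index: int) -> np.ndarray:
        return self.cell_origins[index] + self.cell_side / 2.0

    def to_dataframe(self) -> pd.DataFrame:
        origins = self.cell_origins
        idx = np.arange(self.neuron_count)
        return pd.DataFrame(
            {
                "index": idx,
                "row": idx // self.n_side,
                "col": idx % self.n_side,
                "x0": origins[:, 0],
                "y0": origins[:, 1],
                "side": self.cell_side,
            }
        )


def build_grid(n_side: int) -> NeuronGrid:
    """Build the Euclidean grid for a layer of ``n_side**2`` neurons."""
    return NeuronGrid(n_side=n_side)


def wrap_periodic(point) -> np.ndarray:
    """Wrap coordinates into ``[0, 1)^2`` (periodic boundary conditions).

    Fibers never leave the layer: a coordinate crossing a border re-enters
    on the opposite side.  Idempotent; rejects non-finite input.
    """
    p = np.asarray(point, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError(f"coordinates must be finite, got {point}")
    wrapped = np.mod(p, 1.0)
    # mod of a tiny negative float rounds to exactly 1.0; fold it back
    return np.where(wrapped >= 1.0, 0.0, wrapped)


def neuron_indices(grid: NeuronGrid, points: np.ndarray) -> np.ndarray:
    """Map wrapped points to flat neuron indices; ``-1`` for gap points.

    Vectorized over ``points`` of shape ``(m, 2)``.  A point at scaled
    coordinate ``u * N = k + f`` is inside cell ``k`` iff ``f < 0.5``
    (cells occupy the first half of each ``1/N`` tile).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if np.any(pts < 0.0) or np.any(pts >= 1.0):
        raise ValueError("points must be wrapped into [0, 1)^2 before lookup")
    scaled = pts * grid.n_side
    cells = np.floor(scaled).astype(np.int64)
    np.clip(cells, 0, grid.n_side - 1, out=cells)
    frac = scaled - cells
    inside = (frac < 0.5).all(axis=1)
    flat = cells[:, 1] * grid.n_side + cells[:, 0]  # row from y, col from x
    return np.where(inside, flat, -1)


def point_to_neuron(grid: NeuronGrid, point) -> int | None:
    """Return the index of the cell containing ``point``, or None for a gap."""
    idx = int(neuron_indices(grid, np.asarray(point, dtype=float)[None, :])[0])
    return None if idx < 0 else idx
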