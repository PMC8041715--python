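"""Regular 2-D grids and symmetric 2x2 tensor fields.

Arrays are indexed ``A[i, j]`` with ``i`` along x and ``j`` along y
(``indexing='ij'``); flattening is C-order, so the flat index of node
``(i, j)`` is ``i * ny + j``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Grid2D", "TensorField"]


@dataclass(frozen=True)
class Grid2D:
    """Uniform node-centered grid on ``[x0, x0+(nx-1)h] x [y0, y0+(ny-1)h]``.

    Spacing ``h`` is unit-agnostic; the synthetic tissue routines interpret
    coordinates in micrometres.
    """

    nx: int
    ny: int
    h: float
    x0: float = 0.0
    y0: float = 0.0

    def __post_init__(self) -> None:
        if self.nx < 3 or self.ny < 3:
            raise ValueError("grid needs at least 3 nodes per direction")
        if self.h <= 0:
            raise ValueError("grid spacing must be positive")

    @classmethod
    def square(cls, length: float, n: int, origin: tuple[float, float] = (0.0, 0.0)) -> "Grid2D":
        """``n x n`` grid covering ``[0, length]^2`` (plus origin offset)."""
        return cls(nx=n, ny=n, h=length / (n - 1), x0=origin[0], y0=origin[1])

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nx, self.ny)

    @property
    def n_nodes(self) -> int:
        return self.nx * self.ny

    @property
    def x(self) -> np.ndarray:
        return self.x0 + self.h * np.arange(self.nx)

    @property
    def y(self) -> np.ndarray:
        return self.y0 + self.h * np.arange(self.ny)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        return (self.x0, self.x[-1], self.y0, self.y[-1])

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.x, self.y, indexing="ij")


class TensorField:
    """Symmetric 2x2 tensor per grid node, stored as three component arrays."""

    def __init__(self, grid: Grid2D, dxx: np.ndarray, dxy: np.ndarray, dyy: np.ndarray):
        self.grid = grid
        shape = grid.shape
        self.dxx = np.broadcast_to(np.asarray(dxx, dtype=float), shape).copy()
        self.dxy = np.broadcast_to(np.asarray(dxy, dtype=float), shape).copy()
        self.dyy = np.broadcast_to(np.asarray(dyy, dtype=float), shape).copy()

    @classmethod
    def isotropic(cls, grid: Grid2D, d: float) -> "TensorField":
        return cls(grid, d, 0.0, d)

    @classmethod
    def from_matrices(cls, grid: Grid2D, mats: np.ndarray) -> "TensorField":
        mats = np.asarray(mats, dtype=float)
        if mats.shape != grid.shape + (2, 2):
            raise ValueError("expected per-node 2x2 matrices")
        if not np.allclose(mats[..., 0, 1], mats[..., 1, 0], atol=1e-12):
            raise ValueError("tensors must be symmetric")
        return cls(grid, mats[..., 0, 0], mats[..., 0, 1], mats[..., 1, 1])

    def as_matrices(self) -> np.ndarray:
        out = np.empty(self.grid.shape + (2, 2))
        out[..., 0, 0] = self.dxx
        out[..., 0, 1] = self.dxy
        out[..., 1, 0] = self.dxy
        out[..., 1, 1] = self.dyy
        return out

    def trace(self) -> np.ndarray:
        return self.dxx + self.dyy

    def eigenvalues(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-node eigenvalues ``(l1, l2)`` with ``l1 >= l2`` (closed form)."""
        mean = 0.5 * (self.dxx + self.dyy)
        radius = np.hypot(0.5 * (self.dxx - self.dyy), self.dxy)
        return mean + radius, mean - radius

    def min_eigenvalue(self) -> float:
        return float(self.eigenvalues()[1].min())

    def scaled(self, factor: float) -> "TensorField":
        return TensorField(self.grid, self.dxx * factor, self.dxy * factor, self.dyy * factor)

    def is_psd(self, tol: float = 1e-12) -> bool:
        return bool(self.eigenvalues()[1].min() >= -tol)
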