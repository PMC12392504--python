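"""Scalar fields on uniform rectangular grids.

All physical coordinates are in micrometers.  A field stores its values as a
``(ny, nx)`` array with ``values[j, i]`` located at
``(origin[0] + i*dx, origin[1] + j*dx)``; the grid spacing is isotropic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates


@dataclass
class Grid:
    """Uniform square-spacing grid in physical (μm) coordinates."""

    nx: int
    ny: int
    dx: float
    origin: tuple[float, float] = (0.0, 0.0)

    @classmethod
    def centered(cls, extent_x: float, extent_y: float, dx: float) -> "Grid":
        """Grid symmetric about (0, 0) covering at least the given extents.

        Node counts are odd so that x=0 and y=0 are grid lines; this keeps
        mirror-symmetric patterns exactly symmetric on the lattice.
        """
        hx = int(np.ceil(extent_x / 2.0 / dx))
        hy = int(np.ceil(extent_y / 2.0 / dx))
        return cls(nx=2 * hx + 1, ny=2 * hy + 1, dx=dx,
                   origin=(-hx * dx, -hy * dx))

    @property
    def x(self) -> np.ndarray:
        return self.origin[0] + self.dx * np.arange(self.nx)

    @property
    def y(self) -> np.ndarray:
        return self.origin[1] + self.dx * np.arange(self.ny)

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.x, self.y)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Grid):
            return NotImplemented
        return (self.nx == other.nx and self.ny == other.ny
                and np.isclose(self.dx, other.dx)
                and np.allclose(self.origin, other.origin))


@dataclass
class ScalarField2D:
    """A real scalar field (ϕ, P, or χ) sampled on a :class:`Grid`."""

    values: np.ndarray
    grid: Grid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"field shape {self.values.shape} does not match grid "
                f"shape {self.grid.shape}")

    @property
    def dx(self) -> float:
        return self.grid.dx

    @property
    def origin(self) -> tuple[float, float]:
        return self.grid.origin

    def copy(self) -> "ScalarField2D":
        return ScalarField2D(self.values.copy(), self.grid)

    def like(self, values: np.ndarray) -> "ScalarField2D":
        return ScalarField2D(values, self.grid)

    def is_finite(self) -> bool:
        return bool(np.all(np.isfinite(self.values)))

    def sample(self, x: np.ndarray, y: np.ndarray, order: int = 1) -> np.ndarray:
        """Interpolate the field at physical points (bilinear by default).

        Points outside the grid are evaluated at the nearest edge value,
        consistent with the no-flux boundary conditions used throughout.
        """
        x_arr = np.atleast_1d(np.asarray(x, dtype=float))
        y_arr = np.atleast_1d(np.asarray(y, dtype=float))
        col = (x_arr - self.origin[0]) / self.dx
        row = (y_arr - self.origin[1]) / self.dx
        out = map_coordinates(self.values, [row, col], order=order,
                              mode="nearest")
        return float(out[0]) if np.isscalar(x) or np.ndim(x) == 0 else out

    def shifted(self, dx_um: float, dy_um: float) -> "ScalarField2D":
        """Return the same values on a grid translated by (dx_um, dy_um)."""
        g = Grid(self.grid.nx, self.grid.ny, self.grid.dx,
                 (self.origin[0] + dx_um, self.origin[1] + dy_um))
        return ScalarField2D(self.values.copy(), g)


def zeros_like(f: ScalarField2D) -> ScalarField2D:
    return ScalarField2D(np.zeros(f.grid.shape), f.grid)


def gradient(values: np.ndarray, dx: float) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference gradient with replicated (Neumann) edges.

    Returns (d/dx, d/dy) arrays of the same shape as ``values``.
    """
    p = np.empty((values.shape[0] + 2, values.shape[1] + 2))
    p[1:-1, 1:-1] = values
    p[0, 1:-1] = values[0]
    p[-1, 1:-1] = values[-1]
    p[:, 0] = p[:, 1]
    p[:, -1] = p[:, -2]
    gx = (p[1:-1, 2:] - p[1:-1, :-2]) / (2.0 * dx)
    gy = (p[2:, 1:-1] - p[:-2, 1:-1]) / (2.0 * dx)
    return gx, gy


def laplacian(values: np.ndarray, dx: float) -> np.ndarray:
    """Five-point Laplacian with replicated (Neumann) edges."""
    p = np.empty((values.shape[0] + 2, values.shape[1] + 2))
    p[1:-1, 1:-1] = values
    p[0, 1:-1] = values[0]
    p[-1, 1:-1] = values[-1]
    p[:, 0] = p[:, 1]
    p[:, -1] = p[:, -2]
    return (p[1:-1, 2:] + p[1:-1, :-2] + p[2:, 1:-1] + p[:-2, 1:-1]
            - 4.0 * values) / (dx * dx)
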