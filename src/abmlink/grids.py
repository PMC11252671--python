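"""Regular voxel grids shared by the histogramming and continuum solvers.

A :class:`GridSpec` is a uniform partition of the domain into ``shape``
voxels per axis.  Voxels are half-open ``[lo, hi)`` except the last along
each axis, which is closed, so every point of the domain belongs to
exactly one voxel.  2-D value arrays are indexed ``[ix, iy]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scenarios import Domain

__all__ = ["GridSpec", "block_average", "cells_per_voxel"]


@dataclass(frozen=True)
class GridSpec:
    domain: Domain
    shape: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.shape) != self.domain.dimension:
            raise ValueError("grid shape must have one count per domain axis")
        if any(int(n) != n or n < 1 for n in self.shape):
            raise ValueError("voxel counts must be positive integers")

    @classmethod
    def regular(cls, domain: Domain, n: int) -> "GridSpec":
        """``n`` voxels along every axis."""
        return cls(domain=domain, shape=(n,) * domain.dimension)

    @property
    def dimension(self) -> int:
        return self.domain.dimension

    @property
    def spacing(self) -> np.ndarray:
        return self.domain.extent / np.asarray(self.shape)

    @property
    def voxel_measure(self) -> float:
        return float(np.prod(self.spacing))

    def edges(self, axis: int) -> np.ndarray:
        return np.linspace(self.domain.lo[axis], self.domain.hi[axis], self.shape[axis] + 1)

    def centres(self, axis: int) -> np.ndarray:
        e = self.edges(axis)
        return 0.5 * (e[:-1] + e[1:])

    def centre_mesh(self) -> list[np.ndarray]:
        """Voxel-centre coordinate arrays broadcast to ``shape`` ('ij' indexing)."""
        axes = [self.centres(a) for a in range(self.dimension)]
        return list(np.meshgrid(*axes, indexing="ij"))

    def voxel_index(self, positions: np.ndarray) -> np.ndarray:
        """Voxel index per position; boundary points go to the greater-index
        side, with the last voxel closed."""
        p = np.atleast_2d(np.asarray(positions, dtype=float))
        frac = (p - self.domain.lo) / self.domain.extent
        idx = np.floor(frac * np.asarray(self.shape)).astype(np.int64)
        return np.clip(idx, 0, np.asarray(self.shape) - 1)

    def restriction_factor(self, coarse: "GridSpec") -> int:
        if coarse.domain != self.domain:
            raise ValueError("restriction requires matching domains")
        facs = set()
        for n_fine, n_coarse in zip(self.shape, coarse.shape):
            if n_fine % n_coarse:
                raise ValueError(
                    f"coarse count {n_coarse} does not divide fine count {n_fine}"
                )
            facs.add(n_fine // n_coarse)
        if len(facs) != 1:
            raise ValueError("restriction factor must be the same on every axis")
        return facs.pop()


def block_average(values: np.ndarray, factor: int) -> np.ndarray:
    """Conservative restriction: average ``factor``-sized blocks of a density
    array.  Averaging densities conserves total mass exactly because the
    coarse voxel measure scales by ``factor**dim``."""
    if factor == 1:
        return values.copy()
    if values.ndim == 1:
        (n,) = values.shape
        return values.reshape(n // factor, factor).mean(axis=1)
    nx, ny = values.shape
    return values.reshape(nx // factor, factor, ny // factor, factor).mean(axis=(1, 3))


def cells_per_voxel(density: float, grid: GridSpec) -> float:
    """Convert a number density into the cell count held by one voxel
    (e.g. 150 cells/mm^2 on a 240-voxel grid over 3 mm is ~0.0234 cells)."""
    return density * grid.voxel_measure
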