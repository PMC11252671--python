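"""Ensemble averaging of ABM realizations and figure-level summaries.

Many independent realizations are reduced to an ensemble-averaged (EA)
number-density histogram: per recorded day, all cell positions across
realizations are binned and the counts normalised by the number of
realizations and the voxel measure, giving cells/mm^2 (2-D) or cells/mm
(1-D).  Binning conserves counts exactly, so the integral of the EA
field equals the mean cell count across realizations at every time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .grids import GridSpec, block_average

__all__ = [
    "DensityField",
    "EnsembleDensity",
    "bin_positions",
    "nearest_neighbour_distances",
    "abm_radius_of_support",
    "column_average",
]


@dataclass
class DensityField:
    """Gridded number density at one time."""

    grid: GridSpec
    values: np.ndarray
    time: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != tuple(self.grid.shape):
            raise ValueError("values shape does not match grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("density values must be finite")

    @property
    def mass(self) -> float:
        """Total cell count represented by the field."""
        return float(self.values.sum() * self.grid.voxel_measure)

    def restrict(self, coarse: GridSpec) -> "DensityField":
        factor = self.grid.restriction_factor(coarse)
        return DensityField(grid=coarse, values=block_average(self.values, factor), time=self.time)


@dataclass
class EnsembleDensity:
    """EA density fields per recorded day, with per-day count statistics."""

    fields: list[DensityField]
    n_sim: int
    count_mean: np.ndarray
    count_std: np.ndarray

    def __post_init__(self) -> None:
        if self.n_sim < 1:
            raise ValueError("n_sim must be at least 1")

    @property
    def times(self) -> np.ndarray:
        return np.asarray([f.time for f in self.fields])

    @property
    def grid(self) -> GridSpec:
        return self.fields[0].grid

    def field_at(self, time: float) -> DensityField:
        times = self.times
        k = int(np.argmin(np.abs(times - time)))
        if abs(times[k] - time) > 1e-9:
            raise KeyError(f"no recorded frame at t = {time}")
        return self.fields[k]


def bin_positions(trajectories, grid: GridSpec) -> EnsembleDensity:
    """Accumulate an EA density from an iterable of trajectories.

    Trajectories are consumed lazily (one at a time) so large ensembles can
    be streamed from a generator without holding every realization in
    memory.  All realizations must share the recording ladder.
    """
    counts = None
    times = None
    per_real_counts = []
    n_sim = 0
    for traj in trajectories:
        t = traj.times
        if times is None:
            times = t
            counts = np.zeros((len(times),) + tuple(grid.shape))
        elif len(t) != len(times) or not np.allclose(t, times):
            raise ValueError("trajectories must share the same recording ladder")
        ncells = np.empty(len(times))
        for k, config in enumerate(traj.configs):
            ncells[k] = config.n_cells
            if config.n_cells:
                idx = grid.voxel_index(config.positions)
                np.add.at(counts, (k,) + tuple(idx.T), 1.0)
        per_real_counts.append(ncells)
        n_sim += 1
    if n_sim == 0:
        raise ValueError("no trajectories supplied")
    per_real_counts = np.asarray(per_real_counts)
    fields = [
        DensityField(grid=grid, values=counts[k] / (n_sim * grid.voxel_measure), time=times[k])
        for k in range(len(times))
    ]
    return EnsembleDensity(
        fields=fields,
        n_sim=n_sim,
        count_mean=per_real_counts.mean(axis=0),
        count_std=per_real_counts.std(axis=0),
    )


def nearest_neighbour_distances(config) -> np.ndarray:
    """Euclidean distance from each cell to its closest other cell (mm)."""
    pos = config.positions
    if pos.shape[0] < 2:
        raise ValueError("nearest-neighbour distances require at least 2 cells")
    tree = cKDTree(pos)
    dist, _ = tree.query(pos, k=2)
    return dist[:, 1]


def abm_radius_of_support(trajectories, origin) -> tuple[np.ndarray, np.ndarray]:
    """Per-day mean (over realizations) of the distance from ``origin`` to the
    most distant cell (Euclidean norm).  Returns ``(times, mean_radius)``."""
    origin = np.atleast_1d(np.asarray(origin, dtype=float))
    times = None
    radii = []
    for traj in trajectories:
        if times is None:
            times = traj.times
        r = np.empty(len(traj.configs))
        for k, config in enumerate(traj.configs):
            if config.n_cells == 0:
                raise ValueError("radius of support is undefined for an empty configuration")
            r[k] = np.max(np.linalg.norm(config.positions - origin, axis=1))
        radii.append(r)
    if times is None:
        raise ValueError("no trajectories supplied")
    return times, np.asarray(radii).mean(axis=0)


def column_average(field: DensityField) -> np.ndarray:
    """Average a 2-D field over the x-index, returning the 1-D y-profile."""
    if field.values.ndim != 2:
        raise ValueError("column_average requires a 2-D field")
    return field.values.mean(axis=0)
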