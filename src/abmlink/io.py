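"""Readers and writers for trajectories, EA densities and solutions.

CSV for small, human-readable artefacts (RFC-4180 via pandas); HDF5 for
gridded ensembles and solutions; JSON for fit results and run manifests.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .abm import CellConfiguration, Trajectory
from .continuum import ContinuumSolution
from .ensemble import DensityField, EnsembleDensity
from .grids import GridSpec
from .scenarios import Domain

__all__ = [
    "trajectories_to_csv",
    "trajectories_from_csv",
    "write_trajectories_h5",
    "read_trajectories_h5",
    "write_ensemble_h5",
    "read_ensemble_h5",
    "write_solution_h5",
    "counts_to_csv",
    "write_manifest",
]

_AXES = ("x_mm", "y_mm")


def trajectories_to_csv(trajectories: list[Trajectory], path) -> None:
    rows = []
    for r, traj in enumerate(trajectories):
        for config in traj.configs:
            for cid, pos in enumerate(config.positions):
                row = {"realization": r, "time_days": config.time, "cell_id": cid}
                for ax, val in zip(_AXES, pos):
                    row[ax] = val
                rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def trajectories_from_csv(path, model: str = "movement") -> list[Trajectory]:
    df = pd.read_csv(path)
    axes = [ax for ax in _AXES if ax in df.columns]
    out = []
    for _, real in df.groupby("realization"):
        configs = [
            CellConfiguration(positions=g[axes].to_numpy(), time=float(t))
            for t, g in real.groupby("time_days")
        ]
        out.append(Trajectory(configs=configs, model=model))
    return out


def write_trajectories_h5(trajectories, path, attrs: dict | None = None) -> int:
    """Write an iterable of trajectories (one group per realization)."""
    n = 0
    with h5py.File(path, "w") as f:
        for traj in trajectories:
            g = f.create_group(f"realization_{n:05d}")
            g.attrs["model"] = traj.model
            if traj.seed is not None:
                g.attrs["seed"] = traj.seed
            for k, config in enumerate(traj.configs):
                d = g.create_dataset(f"t_{k:05d}", data=config.positions)
                d.attrs["time_days"] = config.time
            n += 1
        f.attrs["n_realizations"] = n
        for key, val in (attrs or {}).items():
            f.attrs[key] = val
    return n


def read_trajectories_h5(path):
    with h5py.File(path, "r") as f:
        for name in sorted(k for k in f if k.startswith("realization_")):
            g = f[name]
            configs = []
            for dname in sorted(g):
                d = g[dname]
                configs.append(CellConfiguration(positions=d[()], time=float(d.attrs["time_days"])))
            yield Trajectory(configs=configs, model=str(g.attrs["model"]),
                             seed=int(g.attrs["seed"]) if "seed" in g.attrs else None)


def _write_grid(f, grid: GridSpec) -> None:
    f.attrs["domain_bounds"] = np.asarray(grid.domain.bounds, dtype=float)
    f.attrs["grid_shape"] = np.asarray(grid.shape)


def _read_grid(f) -> GridSpec:
    bounds = tuple(tuple(row) for row in np.asarray(f.attrs["domain_bounds"]))
    shape = tuple(int(n) for n in np.asarray(f.attrs["grid_shape"]))
    return GridSpec(domain=Domain(bounds=bounds), shape=shape)


def write_ensemble_h5(ea: EnsembleDensity, path, attrs: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        _write_grid(f, ea.grid)
        f.attrs["n_sim"] = ea.n_sim
        f.create_dataset("times", data=ea.times)
        f.create_dataset("density", data=np.asarray([fld.values for fld in ea.fields]))
        f.create_dataset("count_mean", data=ea.count_mean)
        f.create_dataset("count_std", data=ea.count_std)
        for key, val in (attrs or {}).items():
            f.attrs[key] = val


def read_ensemble_h5(path) -> EnsembleDensity:
    with h5py.File(path, "r") as f:
        grid = _read_grid(f)
        times = f["times"][()]
        density = f["density"][()]
        fields = [DensityField(grid=grid, values=density[k], time=float(t))
                  for k, t in enumerate(times)]
        return EnsembleDensity(fields=fields, n_sim=int(f.attrs["n_sim"]),
                               count_mean=f["count_mean"][()], count_std=f["count_std"][()])


def write_solution_h5(sol: ContinuumSolution, path, attrs: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        _write_grid(f, sol.fields[0].grid)
        f.attrs["model"] = sol.model
        for key in ("alpha", "gamma", "c_plus", "n_bir", "d_loc"):
            f.attrs[key] = getattr(sol.params, key)
        f.create_dataset("times", data=sol.times)
        f.create_dataset("density", data=np.asarray([fld.values for fld in sol.fields]))
        for key, val in (attrs or {}).items():
            f.attrs[key] = val


def counts_to_csv(ea: EnsembleDensity, path) -> None:
    pd.DataFrame({
        "time_days": ea.times,
        "count_mean": ea.count_mean,
        "count_std": ea.count_std,
    }).to_csv(path, index=False)


def write_manifest(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
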