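"""Configuration schema and the end-to-end pipeline runner.

A :class:`RunConfig` (typically loaded from a YAML file) selects the
preset, initial-condition region, model, ensemble size, grids, and fit
specification.  :func:`run_pipeline` executes simulate -> bin -> solve ->
fit, leaving a deterministic directory of artefacts: trajectories and EA
densities (HDF5), continuum solutions (HDF5), fit results (JSON), a
manifest recording every seed, and a log file.  Re-running with the same
config and seed regenerates identical numerics.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .abm import simulate_ensemble
from .continuum import ContinuumParams, solve_continuum
from .ensemble import bin_positions
from .fitting import fit_alpha, fit_birth, fit_combined
from .grids import GridSpec
from .scenarios import (
    BirthRule,
    SimulationSchedule,
    make_region,
    melanophore_preset,
    sample_initial_cells,
    uniform_initial_density,
)
from . import io as aio

__all__ = ["RunConfig", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)


class RegionSpec(BaseModel):
    kind: Literal["box", "stripe", "offset_rectangles", "two_stripes", "interval", "point"] = "box"
    rectangles: Optional[list] = None
    point: Optional[list] = None


class ParamsSpec(BaseModel):
    alpha: float = 1.0
    gamma: Optional[float] = None  # default 1/|Omega|
    c_plus: float = 7.0686
    n_bir: Optional[int] = None  # default: first entry of nbir_set


class FitSpec(BaseModel):
    mode: Literal["sequential", "simultaneous"] = "sequential"
    objective: Literal["l2", "count"] = "l2"
    alpha_bracket: tuple[float, float] = (0.3, 1.2)
    cplus_range: tuple[float, float] = (2.0, 15.0)
    dt_compare: Optional[float] = None


class RunConfig(BaseModel):
    preset: Literal["melanophore"] = "melanophore"
    dimension: Literal[1, 2] = 2
    model: Literal["movement", "birth", "combined"] = "movement"
    region: RegionSpec = Field(default_factory=RegionSpec)
    density: float = 400.0
    n_sim: int = 10
    nbir_set: list[int] = Field(default_factory=lambda: [150])
    n_bin: int = 240
    n_hist: int = 240
    t_final: Optional[float] = None
    seed: int = 0
    outdir: str = "abmlink_run"
    save_trajectories: bool = True
    params: ParamsSpec = Field(default_factory=ParamsSpec)
    fit: Optional[FitSpec] = Field(default_factory=FitSpec)

    @model_validator(mode="after")
    def _check_grids(self):
        if self.n_bin % self.n_hist:
            raise ValueError(f"n_hist={self.n_hist} must divide n_bin={self.n_bin}")
        if self.n_sim < 1:
            raise ValueError("n_sim must be at least 1")
        if self.density < 0:
            raise ValueError("density must be non-negative")
        return self


def load_config(path) -> RunConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return RunConfig.model_validate(payload)


def _setup(config: RunConfig):
    potential, rule0, schedule, domain = melanophore_preset(config.dimension)
    if config.t_final is not None:
        schedule = SimulationSchedule(
            dt_move=schedule.dt_move, dt_bir=schedule.dt_bir, dt_pde=schedule.dt_pde,
            dt_record=schedule.dt_record, t_final=config.t_final,
        )
    region = make_region(
        config.region.kind, domain,
        rectangles=config.region.rectangles,
        point=tuple(config.region.point) if config.region.point is not None else None,
    )
    return potential, rule0, schedule, domain, region


def _nbir_list(config: RunConfig) -> list[int]:
    if config.model == "movement":
        return [0]
    return list(config.nbir_set)


def _traj_path(outdir: Path, config: RunConfig, nbir: int) -> Path:
    if config.model == "movement":
        return outdir / "trajectories.h5"
    return outdir / f"trajectories_nbir{nbir}.h5"


def _ea_path(outdir: Path, config: RunConfig, nbir: int) -> Path:
    if config.model == "movement":
        return outdir / "ea.h5"
    return outdir / f"ea_nbir{nbir}.h5"


def stage_simulate(config: RunConfig, outdir: Path) -> None:
    potential, rule0, schedule, domain, region = _setup(config)
    sampler = lambda rng: sample_initial_cells(region, config.density, rng)
    children = np.random.SeedSequence(config.seed).spawn(len(_nbir_list(config)))
    for nbir, child in zip(_nbir_list(config), children):
        rule = None
        if config.model != "movement":
            rule = BirthRule(sites_per_day=nbir, interaction_radius=rule0.interaction_radius,
                             lower_bound=rule0.lower_bound, upper_bound=rule0.upper_bound)
        trajs = simulate_ensemble(config.model, sampler, potential, rule, schedule, domain,
                                  n_sim=config.n_sim, seed=child)
        t0 = time.perf_counter()
        n = aio.write_trajectories_h5(trajs, _traj_path(outdir, config, nbir),
                                      attrs={"preset": config.preset, "seed": config.seed,
                                             "n_bir": nbir})
        logger.info("simulate: %d realizations (N_bir=%s) in %.1f s",
                    n, nbir, time.perf_counter() - t0)


def stage_ensemble(config: RunConfig, outdir: Path) -> None:
    _, _, schedule, domain, _ = _setup(config)
    grid = GridSpec.regular(domain, config.n_hist)
    for nbir in _nbir_list(config):
        trajs = aio.read_trajectories_h5(_traj_path(outdir, config, nbir))
        ea = bin_positions(trajs, grid)
        mass_err = abs(ea.fields[0].mass - ea.count_mean[0])
        logger.info("ensemble: N_bir=%s binned, t=0 mass %.4f (count mean %.4f)",
                    nbir, ea.fields[0].mass, ea.count_mean[0])
        if mass_err > 1e-8 * max(1.0, ea.count_mean[0]):
            raise AssertionError("EA binning failed to conserve counts")
        aio.write_ensemble_h5(ea, _ea_path(outdir, config, nbir),
                              attrs={"n_bir": nbir})
        aio.counts_to_csv(ea, outdir / (f"counts_nbir{nbir}.csv" if config.model != "movement"
                                        else "counts.csv"))


def stage_solve(config: RunConfig, outdir: Path) -> None:
    potential, rule0, schedule, domain, region = _setup(config)
    solve_grid = GridSpec.regular(domain, config.n_bin)
    record_grid = GridSpec.regular(domain, config.n_hist)
    initial = uniform_initial_density(region, config.density, solve_grid)
    nbir = config.params.n_bir if config.params.n_bir is not None else _nbir_list(config)[0]
    gamma = config.params.gamma if config.params.gamma is not None else 1.0 / domain.measure
    params = ContinuumParams(alpha=config.params.alpha, gamma=gamma,
                             c_plus=config.params.c_plus, n_bir=nbir,
                             d_loc=rule0.interaction_radius)
    t0 = time.perf_counter()
    sol = solve_continuum(config.model, initial, params, potential, schedule,
                          record_grid=None if config.n_bin == config.n_hist else record_grid)
    logger.info("solve: %s model, mass %.3f -> %.3f in %.1f s",
                config.model, sol.mass[0], sol.mass[-1], time.perf_counter() - t0)
    aio.write_solution_h5(sol, outdir / "solution.h5")


def stage_fit(config: RunConfig, outdir: Path) -> None:
    potential, rule0, schedule, domain, region = _setup(config)
    solve_grid = GridSpec.regular(domain, config.n_bin)
    initial = uniform_initial_density(region, config.density, solve_grid)
    spec = config.fit or FitSpec()
    if config.model == "movement":
        ea = aio.read_ensemble_h5(_ea_path(outdir, config, 0))
        result = fit_alpha(ea, initial, potential, schedule, bracket=spec.alpha_bracket,
                           dt_compare=spec.dt_compare)
    elif config.model == "birth":
        ea_by_nbir = {n: aio.read_ensemble_h5(_ea_path(outdir, config, n))
                      for n in _nbir_list(config)}
        result = fit_birth(ea_by_nbir, initial, d_loc=rule0.interaction_radius,
                           schedule=schedule, mode=spec.mode, objective=spec.objective,
                           dt_compare=spec.dt_compare, cplus_range=spec.cplus_range)
    else:
        nbir = _nbir_list(config)[0]
        ea = aio.read_ensemble_h5(_ea_path(outdir, config, nbir))
        result = fit_combined(ea, initial, potential, schedule,
                              d_loc=rule0.interaction_radius, n_bir=nbir,
                              alpha_range=spec.alpha_bracket, cplus_range=spec.cplus_range)
    logger.info("fit: %s -> %s (objective %.6g)", result.mode, result.estimates,
                result.objective)
    (outdir / "fit.json").write_text(result.to_json())


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and return the artefact directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("abmlink")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    t0 = time.perf_counter()
    try:
        stage_simulate(config, outdir)
        stage_ensemble(config, outdir)
        stage_solve(config, outdir)
        if config.fit is not None:
            stage_fit(config, outdir)
        aio.write_manifest(outdir / "manifest.json", {
            "config": config.model_dump(),
            "seed": config.seed,
            "seed_scheme": "numpy SeedSequence(seed).spawn per N_bir, then per realization",
            "abmlink_version": __version__,
            "numpy_version": np.__version__,
            "wall_time_s": time.perf_counter() - t0,
        })
    finally:
        root.removeHandler(handler)
        handler.close()
    return outdir
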