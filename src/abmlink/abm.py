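"""Off-lattice agent-based model of cell migration and birth.

Migration is deterministic and overdamped: each cell moves with velocity
equal to the net force from its neighbours under a truncated pairwise
potential, integrated with explicit forward Euler.  Birth is stochastic
and synchronous: once per day, candidate sites are drawn uniformly from
the domain and a new cell appears wherever the number of pre-existing
cells within the birth radius satisfies short-range activation and
overcrowding prevention.  The two mechanisms run alone or combined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .scenarios import BirthRule, Domain, InteractionPotential, SimulationSchedule

__all__ = [
    "CellConfiguration",
    "Trajectory",
    "net_forces",
    "net_forces_bruteforce",
    "step_migration",
    "attempt_births",
    "simulate_abm",
    "simulate_ensemble",
]

MODEL_TAGS = ("movement", "birth", "combined")


@dataclass
class CellConfiguration:
    """Cell centre coordinates (N, dim) in mm at a given time in days."""

    positions: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.size and not np.all(np.isfinite(self.positions)):
            raise ValueError("cell positions must be finite")

    @property
    def n_cells(self) -> int:
        return self.positions.shape[0]

    @property
    def dimension(self) -> int:
        return self.positions.shape[1]


@dataclass
class Trajectory:
    """Recorded configurations of one realization on the recording ladder."""

    configs: list[CellConfiguration]
    model: str
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.model not in MODEL_TAGS:
            raise ValueError(f"model must be one of {MODEL_TAGS}")
        times = self.times
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("trajectory times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.asarray([c.time for c in self.configs])

    @property
    def counts(self) -> np.ndarray:
        return np.asarray([c.n_cells for c in self.configs])


def net_forces(config: CellConfiguration, potential: InteractionPotential) -> np.ndarray:
    """Net interaction velocity (mm/day) on each cell.

    Pairs are found with a KD-tree at the cutoff radius; contributions use
    the truncated potential gradient (strictly inside the cutoff, zero for
    coincident cells).  ``net_forces_bruteforce`` is the all-pairs oracle.
    """
    pos = config.positions
    if pos.shape[0] < 2:
        return np.zeros_like(pos)
    tree = cKDTree(pos)
    pairs = tree.query_pairs(potential.cutoff, output_type="ndarray")
    return _forces_from_pairs(pos, pairs, potential)


def net_forces_bruteforce(config: CellConfiguration, potential: InteractionPotential) -> np.ndarray:
    """All-pairs double-loop evaluation of the interaction forces (test oracle)."""
    pos = config.positions
    n = pos.shape[0]
    forces = np.zeros_like(pos)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            rij = pos[i] - pos[j]
            dist = float(np.sqrt(np.sum(rij * rij)))
            dwdr = float(potential.truncated_radial_derivative(dist))
            if dist > 0 and dwdr != 0.0:
                forces[i] -= dwdr * rij / dist
    return forces


class _PairCache:
    """Neighbour pairs at radius ``cutoff + margin``, rebuilt only once any
    cell has moved more than ``margin / 2`` since the last build.

    Every pair currently within the cutoff is guaranteed to be in the cached
    list, so forces computed from it equal the exact all-pairs result.
    """

    def __init__(self, cutoff: float, margin: float = 0.02):
        self.cutoff = cutoff
        self.margin = margin
        self._pairs: np.ndarray | None = None
        self._built_at: np.ndarray | None = None

    def pairs(self, positions: np.ndarray) -> np.ndarray:
        stale = (
            self._pairs is None
            or self._built_at.shape != positions.shape
            or np.max(np.abs(positions - self._built_at)) > 0.5 * self.margin
        )
        if stale:
            tree = cKDTree(positions)
            self._pairs = tree.query_pairs(self.cutoff + self.margin, output_type="ndarray")
            self._built_at = positions.copy()
        return self._pairs

    def invalidate(self) -> None:
        self._pairs = None


def _forces_from_pairs(pos: np.ndarray, pairs: np.ndarray,
                       potential: InteractionPotential) -> np.ndarray:
    forces = np.zeros_like(pos)
    if pairs.size == 0:
        return forces
    i, j = pairs[:, 0], pairs[:, 1]
    rij = pos[i] - pos[j]
    dist = np.linalg.norm(rij, axis=1)
    dwdr = potential.truncated_radial_derivative(dist)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(dist > 0, -dwdr / np.where(dist > 0, dist, 1.0), 0.0)
    f = scale[:, None] * rij
    np.add.at(forces, i, f)
    np.add.at(forces, j, -f)
    return forces


def step_migration(
    config: CellConfiguration,
    potential: InteractionPotential,
    dt: float,
    domain: Domain | None = None,
) -> CellConfiguration:
    """One forward-Euler migration step; positions are clamped to the domain."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    new = config.positions + dt * net_forces(config, potential)
    if domain is not None:
        new = domain.clamp(new)
    return CellConfiguration(positions=new, time=config.time + dt)


def _neighbour_counts(cells: np.ndarray, sites: np.ndarray, radius: float) -> np.ndarray:
    """Number of cells within ``radius`` of each site."""
    if cells.shape[0] == 0:
        return np.zeros(sites.shape[0], dtype=np.int64)
    if cells.shape[0] * sites.shape[0] <= 50_000:
        d = np.linalg.norm(cells[None, :, :] - sites[:, None, :], axis=2)
        return (d <= radius).sum(axis=1)
    tree = cKDTree(cells)
    return np.asarray(tree.query_ball_point(sites, radius, return_length=True), dtype=np.int64)


def attempt_births(
    config: CellConfiguration,
    rule: BirthRule,
    domain: Domain,
    rng,
) -> CellConfiguration:
    """One synchronous birth pass.

    Draws ``rule.sites_per_day`` i.i.d. uniform sites in the domain and
    accepts each site whose count of *pre-existing* cells within the birth
    radius lies in ``[lower_bound, upper_bound)``.  All sites see the
    start-of-call state only, so two accepted sites sharing a neighbourhood
    can push the local count above the upper bound — a rare but intended
    consequence of synchronous evaluation.
    """
    rng = np.random.default_rng(rng)
    n_sites = rule.sites_per_day
    if n_sites == 0:
        return CellConfiguration(positions=config.positions.copy(), time=config.time)
    sites = rng.uniform(domain.lo, domain.hi, size=(n_sites, domain.dimension))
    counts = _neighbour_counts(config.positions, sites, rule.interaction_radius)
    accept = (counts >= rule.lower_bound) & (counts < rule.upper_bound)
    new_pos = np.concatenate([config.positions, sites[accept]], axis=0)
    return CellConfiguration(positions=new_pos, time=config.time)


def simulate_abm(
    model: str,
    initial: CellConfiguration,
    potential: InteractionPotential | None,
    rule: BirthRule | None,
    schedule: SimulationSchedule,
    domain: Domain,
    seed=None,
) -> Trajectory:
    """Run one ABM realization, recording every ``dt_record`` days.

    ``movement``: forward-Euler substeps of ``dt_move``.
    ``birth``: one synchronous birth pass per ``dt_bir``.
    ``combined``: per day, a day's worth of migration substeps followed by
    one birth pass (migrate first, then birth).
    """
    if model not in MODEL_TAGS:
        raise ValueError(f"model must be one of {MODEL_TAGS}")
    if model in ("movement", "combined") and potential is None:
        raise ValueError("movement requires an interaction potential")
    if model in ("birth", "combined") and rule is None:
        raise ValueError("birth requires a birth rule")

    rng = np.random.default_rng(seed)
    seed_int = seed if isinstance(seed, (int, np.integer)) else None
    config = CellConfiguration(positions=initial.positions.copy(), time=0.0)
    records = [CellConfiguration(positions=config.positions.copy(), time=0.0)]

    n_records = int(round(schedule.t_final / schedule.dt_record))
    cache = _PairCache(potential.cutoff) if potential is not None else None

    def _migrate(positions: np.ndarray, n_steps: int) -> np.ndarray:
        for _ in range(n_steps):
            if positions.shape[0] >= 2:
                forces = _forces_from_pairs(positions, cache.pairs(positions), potential)
                positions = domain.clamp(positions + schedule.dt_move * forces)
        return positions

    if model == "movement":
        n_sub = int(round(schedule.dt_record / schedule.dt_move))
        for k in range(1, n_records + 1):
            config = CellConfiguration(positions=_migrate(config.positions, n_sub),
                                       time=k * schedule.dt_record)
            records.append(CellConfiguration(positions=config.positions.copy(), time=config.time))
    elif model == "birth":
        n_bir_per_rec = int(round(schedule.dt_record / schedule.dt_bir))
        for k in range(1, n_records + 1):
            for _ in range(n_bir_per_rec):
                config = attempt_births(config, rule, domain, rng)
            config.time = k * schedule.dt_record
            records.append(CellConfiguration(positions=config.positions.copy(), time=config.time))
    else:  # combined: per day, migrate for a day, then one birth pass
        n_sub = int(round(schedule.dt_bir / schedule.dt_move))
        n_bir_per_rec = int(round(schedule.dt_record / schedule.dt_bir))
        for k in range(1, n_records + 1):
            for _ in range(n_bir_per_rec):
                config = CellConfiguration(positions=_migrate(config.positions, n_sub),
                                           time=config.time)
                config = attempt_births(config, rule, domain, rng)
            config.time = k * schedule.dt_record
            records.append(CellConfiguration(positions=config.positions.copy(), time=config.time))
    return Trajectory(configs=records, model=model, seed=seed_int)


def simulate_ensemble(
    model: str,
    initial_sampler,
    potential: InteractionPotential | None,
    rule: BirthRule | None,
    schedule: SimulationSchedule,
    domain: Domain,
    n_sim: int,
    seed,
):
    """Yield ``n_sim`` independent realizations.

    ``initial_sampler(rng)`` must return the initial :class:`CellConfiguration`
    for one realization.  Child seeds are spawned deterministically from
    ``seed`` so ensembles are reproducible and realizations independent.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_sim)
    for child in children:
        rng = np.random.default_rng(child)
        initial = initial_sampler(rng)
        yield simulate_abm(model, initial, potential, rule, schedule, domain, seed=rng)
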