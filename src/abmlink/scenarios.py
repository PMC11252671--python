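"""Parameter presets, domain geometry, initial conditions.

Everything needed to set up a melanophore simulation lives here: the
rectangular simulation domain, the exponential interaction potential
governing cell--cell forces, the stochastic birth rule, the stepping
schedule, and seeded samplers for the initial cell configurations used
throughout (Box / Stripe / Offset rectangles / Two stripes in 2-D, a
single founder cell in 1-D).

Units are millimetres and days throughout; densities are cells/mm^2 in
2-D and cells/mm in 1-D.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "Domain",
    "InteractionPotential",
    "BirthRule",
    "SimulationSchedule",
    "Region",
    "melanophore_preset",
    "make_region",
    "sample_initial_cells",
    "uniform_initial_density",
]


@dataclass(frozen=True)
class Domain:
    """Axis-aligned simulation domain Omega (interval in 1-D, rectangle in 2-D).

    ``bounds`` has shape ``(dimension, 2)`` holding ``(lo, hi)`` per axis, in mm.
    """

    bounds: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        b = np.asarray(self.bounds, dtype=float)
        if b.ndim != 2 or b.shape[1] != 2 or b.shape[0] not in (1, 2):
            raise ValueError("bounds must be ((lo, hi),) or ((lo, hi), (lo, hi))")
        if not np.all(b[:, 1] > b[:, 0]):
            raise ValueError("domain must have positive extent on every axis")

    @property
    def dimension(self) -> int:
        return len(self.bounds)

    @property
    def lo(self) -> np.ndarray:
        return np.asarray(self.bounds, dtype=float)[:, 0]

    @property
    def hi(self) -> np.ndarray:
        return np.asarray(self.bounds, dtype=float)[:, 1]

    @property
    def extent(self) -> np.ndarray:
        return self.hi - self.lo

    @property
    def measure(self) -> float:
        """|Omega| in mm^d."""
        return float(np.prod(self.extent))

    @property
    def centre(self) -> np.ndarray:
        return 0.5 * (self.lo + self.hi)

    def contains(self, positions: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(positions)
        return np.all((p >= self.lo) & (p <= self.hi), axis=1)

    def clamp(self, positions: np.ndarray) -> np.ndarray:
        return np.clip(positions, self.lo, self.hi)


@dataclass(frozen=True)
class InteractionPotential:
    """Exponential pair potential W(r) = R e^{-|r|/omega} - A e^{-|r|/a}.

    ``repulsion_strength`` R and ``adhesion_strength`` A are in mm^2/day,
    the ranges ``omega`` and ``a`` in mm.  Interactions are truncated: the
    gradient is zeroed for |r| >= ``cutoff``.
    """

    repulsion_strength: float  # R, mm^2/day
    adhesion_strength: float  # A, mm^2/day
    repulsion_range: float  # omega, mm
    adhesion_range: float  # a, mm
    cutoff: float  # d_max, mm

    def __post_init__(self) -> None:
        if self.repulsion_strength < 0 or self.adhesion_strength < 0:
            raise ValueError("potential strengths must be non-negative")
        if min(self.repulsion_range, self.adhesion_range, self.cutoff) <= 0:
            raise ValueError("potential ranges and cutoff must be positive")

    def value(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        return (
            self.repulsion_strength * np.exp(-r / self.repulsion_range)
            - self.adhesion_strength * np.exp(-r / self.adhesion_range)
        )

    def radial_derivative(self, r: np.ndarray) -> np.ndarray:
        """dW/dr without the cutoff (negative where repulsion dominates)."""
        r = np.asarray(r, dtype=float)
        return (
            -self.repulsion_strength / self.repulsion_range * np.exp(-r / self.repulsion_range)
            + self.adhesion_strength / self.adhesion_range * np.exp(-r / self.adhesion_range)
        )

    def truncated_radial_derivative(self, r: np.ndarray) -> np.ndarray:
        """dW/dr with the cutoff applied: zero for r >= d_max and at r = 0.

        The strict inequality |r| < d_max follows the indicator convention of
        the force truncation; the value at r = 0 is defined as zero (the
        exponential potential has a kink at the origin, and coincident cells
        exert no force on one another).
        """
        r = np.asarray(r, dtype=float)
        out = self.radial_derivative(r)
        return np.where((r > 0.0) & (r < self.cutoff), out, 0.0)


@dataclass(frozen=True)
class BirthRule:
    """Stochastic synchronous birth rule.

    Each day ``sites_per_day`` candidate sites are drawn uniformly from the
    domain; a new cell appears at a site iff the number of pre-existing
    cells within ``interaction_radius`` lies in ``[lower_bound, upper_bound)``
    (short-range activation and overcrowding prevention).
    """

    sites_per_day: int  # N_bir
    interaction_radius: float = 0.075  # d_loc, mm
    lower_bound: int = 1  # c^-
    upper_bound: int = 6  # c^+_ABM
    birth_step: float = 1.0  # Delta t_bir, days

    def __post_init__(self) -> None:
        if self.sites_per_day < 0 or int(self.sites_per_day) != self.sites_per_day:
            raise ValueError("sites_per_day must be a non-negative integer")
        if not (0 < self.lower_bound <= self.upper_bound):
            raise ValueError("require 0 < lower_bound <= upper_bound")
        if self.interaction_radius <= 0:
            raise ValueError("interaction_radius must be positive")


@dataclass(frozen=True)
class SimulationSchedule:
    """Stepping and recording intervals, all in days."""

    dt_move: float = 0.01
    dt_bir: float = 1.0
    dt_pde: float = 0.05
    dt_record: float = 1.0
    t_final: float = 150.0

    def __post_init__(self) -> None:
        for name in ("dt_move", "dt_bir", "dt_pde", "dt_record", "t_final"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("dt_move", "dt_bir", "dt_pde"):
            ratio = self.dt_record / getattr(self, name)
            if abs(ratio - round(ratio)) > 1e-9:
                raise ValueError(f"dt_record must be an integer multiple of {name}")

    @property
    def record_times(self) -> np.ndarray:
        n = int(round(self.t_final / self.dt_record))
        return np.arange(n + 1) * self.dt_record


@dataclass(frozen=True)
class Region:
    """A union of non-overlapping axis-aligned rectangles, or discrete points.

    ``rectangles`` is a tuple of ``(dim, 2)`` bounds arrays (empty for point
    regions); ``points`` is a tuple of coordinates (empty otherwise).
    """

    kind: str
    rectangles: tuple[tuple[tuple[float, float], ...], ...] = ()
    points: tuple[tuple[float, ...], ...] = ()

    @property
    def dimension(self) -> int:
        if self.rectangles:
            return len(self.rectangles[0])
        return len(self.points[0])

    def component_measures(self) -> np.ndarray:
        if not self.rectangles:
            return np.zeros(len(self.points))
        out = []
        for rect in self.rectangles:
            r = np.asarray(rect, dtype=float)
            out.append(float(np.prod(r[:, 1] - r[:, 0])))
        return np.asarray(out)

    @property
    def measure(self) -> float:
        return float(self.component_measures().sum())

    def to_json(self) -> str:
        return json.dumps(asdict(self))


_REGION_KINDS = {"box", "stripe", "offset_rectangles", "two_stripes", "interval", "point"}


def _default_rectangles(kind: str, domain: Domain) -> list[np.ndarray]:
    cx = domain.centre
    lo, hi = domain.lo, domain.hi
    if kind == "box":
        return [np.array([[cx[0] - 0.5, cx[0] + 0.5], [cx[1] - 0.5, cx[1] + 0.5]])]
    if kind == "stripe":
        # full-width horizontal band, 1 mm tall, centred
        return [np.array([[lo[0], hi[0]], [cx[1] - 0.5, cx[1] + 0.5]])]
    if kind == "two_stripes":
        # two full-width bands of height 0.5 mm separated by a 0.5 mm gap
        return [
            np.array([[lo[0], hi[0]], [cx[1] - 0.75, cx[1] - 0.25]]),
            np.array([[lo[0], hi[0]], [cx[1] + 0.25, cx[1] + 0.75]]),
        ]
    if kind == "offset_rectangles":
        # two 1 x 0.5 mm^2 rectangles offset diagonally, touching at a corner
        return [
            np.array([[cx[0] - 1.0, cx[0]], [cx[1] - 0.5, cx[1]]]),
            np.array([[cx[0], cx[0] + 1.0], [cx[1], cx[1] + 0.5]]),
        ]
    if kind == "interval":
        return [np.array([[cx[0] - 0.5, cx[0] + 0.5]])]
    raise ValueError(f"unknown region kind {kind!r}")


def _rects_overlap(a: np.ndarray, b: np.ndarray) -> bool:
    return bool(np.all(np.minimum(a[:, 1], b[:, 1]) > np.maximum(a[:, 0], b[:, 0])))


def make_region(
    kind: str,
    domain: Domain,
    rectangles: list | None = None,
    point: tuple | float | None = None,
) -> Region:
    """Build an initial-condition region inside ``domain``.

    Default geometries for the named 2-D motifs are centred in the domain and
    fully configurable via ``rectangles``; ``point`` places a single founder
    cell (default: the domain centre / origin of a symmetric 1-D domain).
    """
    if kind not in _REGION_KINDS:
        raise ValueError(f"unknown region kind {kind!r}; choose from {sorted(_REGION_KINDS)}")
    if kind == "point":
        if point is None:
            coord = tuple(domain.centre)
        else:
            coord = tuple(np.atleast_1d(np.asarray(point, dtype=float)))
        if len(coord) != domain.dimension:
            raise ValueError("point dimensionality does not match domain")
        if not domain.contains(np.asarray(coord))[0]:
            raise ValueError("point lies outside the domain")
        return Region(kind="point", points=(coord,))

    if rectangles is None:
        rects = _default_rectangles(kind, domain)
    else:
        rects = [np.asarray(r, dtype=float) for r in rectangles]
    for r in rects:
        if r.shape != (domain.dimension, 2):
            raise ValueError("rectangle shape does not match domain dimension")
        if np.any(r[:, 0] < domain.lo - 1e-12) or np.any(r[:, 1] > domain.hi + 1e-12):
            raise ValueError("region rectangle lies outside the domain")
        if not np.all(r[:, 1] > r[:, 0]):
            raise ValueError("rectangle must have positive extent")
    for i in range(len(rects)):
        for j in range(i + 1, len(rects)):
            if _rects_overlap(rects[i], rects[j]):
                raise ValueError("region components must not overlap")
    return Region(kind=kind, rectangles=tuple(tuple(map(tuple, r)) for r in rects))


def sample_initial_cells(region: Region, density: float, rng) :
    """Sample an initial cell configuration uniformly at random in ``region``.

    The count per rectangular component is ``round(density * area)`` (fixed,
    not Poisson); point regions place exactly one cell per listed coordinate.
    Returns a :class:`~abmlink.abm.CellConfiguration` at time 0.
    """
    from .abm import CellConfiguration

    if density < 0:
        raise ValueError("density must be non-negative")
    rng = np.random.default_rng(rng)
    if region.kind == "point":
        pos = np.asarray(region.points, dtype=float)
        return CellConfiguration(positions=pos, time=0.0)
    chunks = []
    for rect in region.rectangles:
        r = np.asarray(rect, dtype=float)
        area = float(np.prod(r[:, 1] - r[:, 0]))
        n = int(round(density * area))
        if n:
            chunks.append(rng.uniform(r[:, 0], r[:, 1], size=(n, r.shape[0])))
    dim = region.dimension
    if chunks:
        pos = np.concatenate(chunks, axis=0)
    else:
        pos = np.empty((0, dim))
    return CellConfiguration(positions=pos, time=0.0)


def uniform_initial_density(region: Region, density: float, grid) :
    """Continuum counterpart of :func:`sample_initial_cells`.

    Each voxel receives ``density`` times the fraction of its volume inside
    the region (exact for axis-aligned rectangles).  A point region deposits
    one cell of mass into the containing voxel, the continuum analogue of a
    single founder cell.  Returns a :class:`~abmlink.ensemble.DensityField`.
    """
    from .ensemble import DensityField

    values = np.zeros(grid.shape)
    if region.kind == "point":
        for coord in region.points:
            idx = grid.voxel_index(np.asarray(coord, dtype=float)[None, :])[0]
            values[tuple(idx)] += 1.0 / grid.voxel_measure
        return DensityField(grid=grid, values=values, time=0.0)

    for rect in region.rectangles:
        r = np.asarray(rect, dtype=float)
        frac = 1.0
        # per-axis overlap of each voxel interval with the rectangle
        overlaps = []
        for ax in range(grid.dimension):
            edges = grid.edges(ax)
            lo = np.maximum(edges[:-1], r[ax, 0])
            hi = np.minimum(edges[1:], r[ax, 1])
            overlaps.append(np.clip(hi - lo, 0.0, None) / grid.spacing[ax])
        frac = overlaps[0]
        if grid.dimension == 2:
            frac = np.outer(overlaps[0], overlaps[1])
        values += density * frac
    return DensityField(grid=grid, values=values, time=0.0)


def melanophore_preset(dimension: int = 2):
    """Melanophore parameter set used throughout.

    Returns ``(potential, birth_rule, schedule, domain)``.  The 2-D domain is
    3 x 3 mm^2; the 1-D domain is the symmetric interval [-1.5, 1.5] mm.  The
    default birth-site rate is 150 sites/day (the value used for the combined
    benchmarks); it varies by experiment and is overridden per run.
    """
    potential = InteractionPotential(
        repulsion_strength=0.00124,  # R, mm^2/day (reported as R/omega = 0.062 mm/day)
        adhesion_strength=0.0,  # A: melanophores are purely repulsive
        repulsion_range=0.02,  # omega, mm
        adhesion_range=0.012,  # a, mm (inert since A = 0)
        cutoff=0.2,  # d_max, mm
    )
    rule = BirthRule(sites_per_day=150, interaction_radius=0.075, lower_bound=1, upper_bound=6)
    if dimension == 2:
        domain = Domain(bounds=((0.0, 3.0), (0.0, 3.0)))
        schedule = SimulationSchedule(dt_move=0.01, dt_bir=1.0, dt_pde=0.05, dt_record=1.0, t_final=150.0)
    elif dimension == 1:
        domain = Domain(bounds=((-1.5, 1.5),))
        schedule = SimulationSchedule(dt_move=0.1, dt_bir=1.0, dt_pde=0.05, dt_record=1.0, t_final=2000.0)
    else:
        raise ValueError("dimension must be 1 or 2")
    return potential, rule, schedule, domain
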