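# Methods

`abmlink` links an off-lattice agent-based model (ABM) of pigment-cell
migration and birth to continuum models of the same processes, and
estimates the scaling parameters that align the two descriptions.  This
note records the models, the numerical choices, and the places where the
design was genuinely open.

## Models

**Migration (discrete).**  Each cell centre `M_i(t)` (mm) obeys
overdamped dynamics: its velocity is the net force from pairwise
interactions under the exponential potential

    W(r) = R exp(-|r|/omega) - A exp(-|r|/a),

with the gradient truncated to zero for `|r| >= d_max` (cells interact
through extensions of finite reach).  The melanophore preset is purely
repulsive (`A = 0`, reported repulsion strength `R/omega = 0.062`
mm/day).  Integration is explicit forward Euler with `dt_move = 0.01`
day in 2-D and `0.1` day in 1-D.  There is no Brownian motion, so a
movement-only realization is deterministic given its initial condition.

**Birth (discrete).**  Once per day, `N_bir` candidate sites are drawn
uniformly from the domain and evaluated *synchronously* against the
start-of-day configuration: a cell appears at a site iff the number of
existing cells within `d_loc = 0.075` mm lies in `[1, 6)` (short-range
activation and overcrowding prevention).  Because accepted sites never
see each other within a day, local counts can transiently exceed the
upper bound; this is intended behaviour and raises the saturation
density a few percent above the naive bound.

**Migration (continuum).**  The number density `M(x,t)` follows the
non-local aggregation PDE

    dM/dt = alpha * div( M * (grad W_c conv M) ),

whose transport velocity is a convolution of the density with the
truncated potential gradient.  `alpha` multiplies the whole transport
term and therefore dilates time exactly: `M_alpha(., t) = M_1(., alpha t)`.
The mean-field value `alpha = 1` overpredicts the spreading speed of the
ensemble-averaged ABM at realistic cell numbers, which is the reason the
parameter exists.

**Birth (continuum).**  The source term is an indicator of the local
mass,

    dM/dt = gamma * N_bir * 1{ 1 <= int_{|y-x| <= d_loc} M(y) dy < c+ },

with the lower bound inclusive and the upper strict.  `gamma` (units
1/|Omega|) dilates time the same way alpha does; `c+` (cells) limits the
density.  Integrating over the domain bounds the birth rate by
`gamma*N_bir*|Omega|`, so the mean-field expectation is
`gamma ~ 1/|Omega|`.  Neighbourhoods are clipped at the boundary — no
mass exists outside the domain — which makes boundary densities
saturate well above interior ones (in 2-D the corner neighbourhood is a
quarter disc, so corner voxels self-cap extremely slowly; this is a real
feature of the model, mirrored by the ABM, where corner sites keep
accepting births long after the interior is full).

A useful closed form, derived from the travelling-front structure of the
1-D IDE and confirmed numerically: with unit source rate the interior
plateau density is `(c+ + 1) / W`, where `W` is the (discretised)
neighbourhood measure, and the front speed is `(W/2)^2 / 2` per unit
dilated time.  Plateau levels are therefore set by `c+` and front speeds
by `gamma` nearly independently, which is what makes the sequential fit
work.

**Combined model.**  The ABM migrates for a day (substeps) and then runs
one birth pass; the PDE applies both terms in one explicit step, with
the transport and the birth indicator both evaluated on the start-of-step
density.

## Numerics

- **Forces.**  Pairs are found with a KD-tree.  Inside trajectory
  simulation a padded pair list (radius `d_max + 0.02` mm) is reused
  until any cell has moved more than half the margin; every pair within
  the true cutoff is always contained in the list, so the result is
  identical to the all-pairs double loop, which is kept as the test
  oracle.  The gradient at `r = 0` is defined as zero (the potential has
  a kink there; coincident cells are a probability-zero event).
- **Boundary handling (ABM).**  Positions are clamped to the domain
  after each Euler step; birth sites are inside by construction.
- **Histograms.**  Voxels are half-open `[lo, hi)` with the last voxel
  closed; binning conserves counts exactly and the EA field integrates
  to the mean cell count by construction.
- **Convolutions.**  Zero-padded FFT convolutions (the domain is not
  periodic) with the kernel transform cached across steps; a direct
  offset-sum oracle is kept for tests.  The gradient kernel is exactly
  antisymmetric, so uniform interior density produces zero velocity to
  round-off.
- **Transport.**  Conservative donor-cell upwind fluxes with face
  velocities averaged from adjacent voxel centres and zero-flux boundary
  faces (mass-conserving, matching the clamped agents).  The CFL number
  is kept below 0.95 by internal sub-stepping with frozen velocity,
  which also preserves non-negativity.
- **Neighbourhood discretisation.**  The disc (1-D: interval) indicator
  is sampled at voxel centres, closed at the radius.  On the default
  240-voxel mesh over 3 mm the 2-D disc covers 113 voxels — within 0.1%
  of `pi*d_loc^2` — while the 1-D window covers 13 voxels (0.1625 mm,
  8.3% above `2*d_loc`).  The fitted `c+` and `gamma` absorb the
  discretised measure (plateau `(c++1)/W`, speed `(W/2)^2/2`), so the
  mesh convention is part of the model definition; 240 voxels is the
  package default in both dimensions.  A 300-voxel 1-D mesh, whose
  window is exactly 0.15 mm, shifts the fitted 1-D `c+` down by about
  7% and `gamma` up by about 15% — worth keeping in mind when comparing
  calibrations across implementations.
- **Indicator thresholds.**  A 1e-9-cell tolerance at both thresholds
  absorbs FFT round-off so exact-tie comparisons (local mass equal to
  `c+`) behave as the strict inequality dictates.
- **Dilated-time (unit-rate) solves.**  Fitting exploits the exact time
  dilation: one solve with unit scaling, recorded densely and linearly
  interpolated, replaces per-candidate solves.  Step sizes are chosen as
  local-mass increments per step of ~0.008 cells (1-D) and ~0.03 cells
  (2-D) — far below the activation thresholds, and finer than the
  per-step increments of a direct forward-Euler solve at `dt_pde = 0.05`
  with realistic `gamma*N_bir`.  Birth tables stop early at the exact
  steady state (no active voxel) and extend their horizon lazily to the
  largest dilated time a candidate actually queries.  The fast and
  per-candidate paths agree to well under 0.5% in fitted parameters
  (tested).

## Fitting

The objective is the squared space–time L2 difference on the comparison
histogram (`dt * dx * dy * sum (M_cts - M_EA)^2` over frames every
`dt_compare`), or optionally the squared difference of total cell
counts.  Searches are a coarse bracketing grid (log-spaced for `gamma`)
followed by bounded scalar refinement; 2-D/3-D fits use a grid plus
profile refinement or Nelder–Mead polish.  Every fit records its full
candidate trace; the combined fit scans the grid trace for ridge
directions (relative change < 1% through the optimum), since `alpha` and
`gamma` compensate along such directions and are not separately
identifiable from combined data alone.

Sequential birth fitting pins `gamma = 1/|Omega|` while fitting `c+`,
then fits `gamma`.  The count-based objective is near-degenerate along a
compensating `(c+, gamma)` ridge when the data never saturate, so
count-based calibration needs ensembles that reach their plateau.

Default search ranges: `alpha` in [0.3, 1.2], `c+` in [2, 15] cells,
`gamma` in [0.1, 3] / |Omega|.  Comparison strides: 10 days for the 1-D
benchmark, 1 day (every recorded frame) in 2-D.

## Synthetic data and what the benchmarks show

All data are generated internally by the ABM; nothing is measured from
real fish.  The generator reproduces the study conditions: 3 x 3 mm^2
domain (1-D: the symmetric interval [-1.5, 1.5] mm), initial densities
of 400 cells/mm^2 sampled uniformly in Box/Stripe/Offset/Two-stripe
motifs or a single founder cell, `N_bir` in {1..10} (1-D) and
{10, 25, 50, 100, 150, 200, 250} (2-D), recording every day for 2000
(1-D) or 150 (2-D) days.  Ensemble sizes in the shipped benchmarks are
about 100 realizations per condition — a tenth of the original
ensembles — which leaves sub-percent Monte-Carlo spread in the fitted
parameters (checked across disjoint seed batches).  What passing
benchmarks show is that the discrete rules, the continuum solvers and
the calibration pipeline are mutually consistent at these problem
sizes; they say nothing about real pigment-cell data, which carry
measurement noise, multiple cell types and longer-range interactions
that this single-population model omits.

Known residual systematics against the published reference estimates,
with ensembles regenerated here: 1-D sequential/simultaneous parameters
agree within 2–6%, and the 2-D `gamma` within ~2.5%, but the 2-D
sequential `c+` comes out ~13% below the reference.  The source is the
weighting of the saturation transient: the ABM interior approaches its
plateau (~520 cells/mm^2) gradually, while the IDE ramps linearly and
stops, so the field-L2 objective trades plateau accuracy against
mid-phase overshoot.  Total-count calibration on the same data prefers
`c+ ~ 9.2`, and the continuum run at the reference pair reproduces the
ABM mass curves almost exactly, bracketing the reference value between
the two objectives; the `gamma` profile through the reference `c+`
matches the reference `gamma` to 0.4%.  The discrepancy therefore
reflects unreported implementation details of the original calibration
rather than Monte-Carlo noise (which is an order of magnitude smaller).

The movement benchmarks (mesh-convergence of `alpha` across
`N_bin = 240/480` and four initial conditions, and pointwise EA errors
at ten thousand realizations) need hours of compute; they are wired
behind `abmlink reproduce --full` and are not part of the routine suite.
The oscillatory high/low density bands near the EA support edge appear
only on fine histograms of large movement ensembles, so they are likewise
observable in the full-scale run rather than asserted by a desk-scale
test.

## Open choices made here

- 1-D domain `[-1.5, 1.5]` mm with the founder at the origin (the
  boundary-anchored alternative `[0, 3]` changes fitted parameters by
  under 2%, checked).
- Combined-model ordering: migrate first, then birth, from day one.
- Fixed per-component cell counts (`round(density * area)`), not Poisson
  draws.
- Restriction to comparison grids by conservative block averaging.
- Region motif geometries (stripe width 1 mm, offset rectangles
  1 x 0.5 mm^2 touching at a corner, two 0.5 mm stripes 0.5 mm apart)
  are defaults, fully configurable, and nothing downstream depends on
  them.

## Limitations

Single cell population only; no cell death; no Brownian motion; no
density-dependent `gamma`; first-order schemes throughout (self-
convergence is first order, tested); identifiability of `(alpha, gamma)`
from combined data alone is poor by construction — calibrate modularly,
or fix `c+` from the analytic threshold `rho_max * |Omega_loc|` when the
combined model must cap at an empirical density.
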