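"""Objectives and parameter-recovery behaviour of the fitters."""

import numpy as np
import pytest

import abmlink as al
from abmlink.grids import GridSpec

from conftest import solution_as_ensemble


@pytest.fixture(scope="module")
def alpha_truth():
    """Movement PDE data generated with a known alpha on a coarse mesh."""
    pot, _, _, dom = al.melanophore_preset(2)
    grid = GridSpec.regular(dom, 48)
    region = al.make_region("box", dom)
    initial = al.uniform_initial_density(region, 400.0, grid)
    sched = al.SimulationSchedule(dt_pde=0.05, t_final=20.0)
    sol = al.solve_continuum("movement", initial,
                             al.ContinuumParams(alpha=0.7), pot, sched)
    return pot, dom, grid, initial, sched, solution_as_ensemble(sol)


@pytest.fixture(scope="module")
def birth_truth():
    """Birth IDE data generated with known (c_plus, gamma) in 1-D."""
    _, _, _, dom = al.melanophore_preset(1)
    grid = GridSpec.regular(dom, 120)
    region = al.make_region("point", dom, point=(0.0,))
    initial = al.uniform_initial_density(region, 0.0, grid)
    # long enough that the faster ensemble saturates: the plateau mass pins
    # c_plus, the growth time scale pins gamma
    sched = al.SimulationSchedule(dt_move=0.1, dt_pde=0.05, t_final=600.0)
    truth = {"c_plus": 5.0, "gamma": 0.5}
    ea_by_nbir = {}
    for nbir in (1, 3):
        sol = al.solve_continuum(
            "birth", initial,
            al.ContinuumParams(gamma=truth["gamma"], c_plus=truth["c_plus"],
                               n_bir=nbir, d_loc=0.075),
            None, sched, record_grid=GridSpec.regular(dom, 30),
        )
        ea_by_nbir[nbir] = solution_as_ensemble(sol)
    return dom, initial, sched, truth, ea_by_nbir


class TestObjectives:
    def _pair(self, offset=0.0):
        dom = al.Domain(bounds=((0.0, 3.0),))
        grid = GridSpec.regular(dom, 30)
        fields = [al.DensityField(grid, np.full(30, 10.0), float(t)) for t in range(4)]
        sol = al.ContinuumSolution(
            fields=[al.DensityField(grid, f.values + offset, f.time) for f in fields],
            model="birth", params=al.ContinuumParams(c_plus=5.0),
        )
        ea = al.EnsembleDensity(fields=fields, n_sim=1,
                                count_mean=np.asarray([f.mass for f in fields]),
                                count_std=np.zeros(4))
        return sol, ea, grid

    def test_l2_identical_is_zero(self):
        sol, ea, _ = self._pair()
        assert al.l2_error(sol, ea, dt_compare=1.0) == 0.0

    def test_l2_constant_offset_closed_form(self):
        sol, ea, grid = self._pair(offset=2.5)
        # dt * dx * V voxels * T frames * d^2
        expected = 1.0 * grid.voxel_measure * 30 * 4 * 2.5**2
        assert al.l2_error(sol, ea, dt_compare=1.0) == pytest.approx(expected)

    def test_l2_symmetric_in_arguments(self, rng):
        sol, ea, _ = self._pair()
        for f, g in zip(sol.fields, ea.fields):
            f.values += rng.uniform(0, 3, 30)
            g.values += rng.uniform(0, 3, 30)
        swapped = al.ContinuumSolution(fields=ea.fields, model="birth",
                                       params=sol.params)
        ea_from_sol = al.EnsembleDensity(fields=sol.fields, n_sim=1,
                                         count_mean=np.zeros(4), count_std=np.zeros(4))
        assert al.l2_error(sol, ea, 1.0) == pytest.approx(al.l2_error(swapped, ea_from_sol, 1.0))

    def test_l2_grid_mismatch_rejected(self):
        sol, ea, _ = self._pair()
        dom = al.Domain(bounds=((0.0, 3.0),))
        other = GridSpec.regular(dom, 15)
        bad = al.EnsembleDensity(
            fields=[al.DensityField(other, np.zeros(15), float(t)) for t in range(4)],
            n_sim=1, count_mean=np.zeros(4), count_std=np.zeros(4))
        with pytest.raises(ValueError, match="grid"):
            al.l2_error(sol, bad, 1.0)

    def test_count_error_closed_form(self):
        sol, ea, _ = self._pair()
        ea.count_mean = ea.count_mean + 1.0  # one cell off at every frame
        assert al.count_error(sol, ea, dt_compare=1.0) == pytest.approx(1.0 * 4)


class TestCplusFromDensity:
    def test_melanophore_value(self):
        assert al.cplus_from_density(400.0, 0.075, 2) == pytest.approx(7.0686, abs=1e-4)

    def test_zero_density(self):
        assert al.cplus_from_density(0.0, 0.075, 2) == 0.0

    def test_1d(self):
        assert al.cplus_from_density(10.0, 0.075, 1) == pytest.approx(1.5)


class TestFitAlpha:
    def test_recovers_generating_alpha(self, alpha_truth):
        pot, dom, grid, initial, sched, ea = alpha_truth
        result = al.fit_alpha(ea, initial, pot, sched)
        assert result.estimates["alpha"] == pytest.approx(0.7, rel=0.01)

    def test_alpha_one_is_worse_than_fit(self, alpha_truth):
        pot, dom, grid, initial, sched, ea = alpha_truth
        result = al.fit_alpha(ea, initial, pot, sched)
        obj_at_one = [v for p, v in result.trace if abs(p["alpha"] - 1.0) < 0.05]
        assert min(obj_at_one) > result.objective

    def test_dilation_and_resolve_paths_agree(self, alpha_truth):
        pot, dom, grid, initial, sched, ea = alpha_truth
        fast = al.fit_alpha(ea, initial, pot, sched, method="dilation")
        slow = al.fit_alpha(ea, initial, pot, sched, method="resolve", n_coarse=7)
        assert abs(fast.estimates["alpha"] - slow.estimates["alpha"]) < 0.005 * fast.estimates["alpha"]

    def test_boundary_minimum_rejected(self, alpha_truth):
        pot, dom, grid, initial, sched, ea = alpha_truth
        with pytest.raises(ValueError, match="interior minimum"):
            al.fit_alpha(ea, initial, pot, sched, bracket=(0.8, 1.2))


class TestFitBirth:
    def test_sequential_recovers_generating_parameters(self, birth_truth):
        dom, initial, sched, truth, ea_by_nbir = birth_truth
        result = al.fit_birth(ea_by_nbir, initial, d_loc=0.075, schedule=sched,
                              mode="sequential", dt_compare=10.0)
        assert result.estimates["c_plus"] == pytest.approx(truth["c_plus"], rel=0.02)
        assert result.estimates["gamma"] == pytest.approx(truth["gamma"], rel=0.02)

    def test_simultaneous_close_to_sequential(self, birth_truth):
        dom, initial, sched, truth, ea_by_nbir = birth_truth
        seq = al.fit_birth(ea_by_nbir, initial, d_loc=0.075, schedule=sched,
                           mode="sequential", dt_compare=10.0)
        sim = al.fit_birth(ea_by_nbir, initial, d_loc=0.075, schedule=sched,
                           mode="simultaneous", dt_compare=10.0, n_coarse=9)
        for key in ("c_plus", "gamma"):
            assert sim.estimates[key] == pytest.approx(seq.estimates[key], rel=0.05)

    def test_count_objective_recovers_parameters_jointly(self, birth_truth):
        # total-count curves identify (c_plus, gamma) through the plateau mass
        # and the growth time scale; the joint search recovers both
        dom, initial, sched, truth, ea_by_nbir = birth_truth
        result = al.fit_birth(ea_by_nbir, initial, d_loc=0.075, schedule=sched,
                              mode="simultaneous", objective="count", dt_compare=10.0,
                              n_coarse=9)
        assert result.estimates["gamma"] == pytest.approx(truth["gamma"], rel=0.05)
        assert result.estimates["c_plus"] == pytest.approx(truth["c_plus"], rel=0.05)

    def test_empty_data_rejected(self, birth_truth):
        dom, initial, sched, truth, _ = birth_truth
        with pytest.raises(ValueError, match="empty"):
            al.fit_birth({}, initial, d_loc=0.075, schedule=sched)


class TestFitResult:
    def test_estimate_must_attain_trace_minimum(self):
        with pytest.raises(ValueError, match="minimum"):
            al.FitResult(mode="alpha", estimates={"alpha": 1.0}, objective=5.0,
                         trace=[({"alpha": 0.5}, 1.0), ({"alpha": 1.0}, 5.0)])

    def test_json_round_trip_fields(self):
        result = al.FitResult(mode="alpha", estimates={"alpha": 0.63},
                              objective=1.0, trace=[({"alpha": 0.63}, 1.0)],
                              provenance={"n_sim": 10})
        import json

        payload = json.loads(result.to_json())
        assert payload["estimates"]["alpha"] == 0.63
        assert payload["provenance"]["n_sim"] == 10


class TestFitCombined:
    def test_recovers_generating_triple_and_flags_ridges(self):
        pot, _, _, dom = al.melanophore_preset(2)
        grid = GridSpec.regular(dom, 48)
        region = al.make_region("box", dom)
        initial = al.uniform_initial_density(region, 400.0, grid)
        sched = al.SimulationSchedule(dt_pde=0.1, dt_record=1.0, t_final=10.0)
        truth = al.ContinuumParams(alpha=0.6, gamma=0.12, c_plus=8.0, n_bir=150,
                                   d_loc=0.075)
        sol = al.solve_continuum("combined", initial, truth, pot, sched)
        ea = solution_as_ensemble(sol)
        result = al.fit_combined(ea, initial, pot, sched, d_loc=0.075, n_bir=150,
                                 alpha_range=(0.4, 1.0), cplus_range=(5.0, 11.0),
                                 gamma_range=(0.05, 0.3), n_grid=3)
        assert result.estimates["c_plus"] == pytest.approx(8.0, rel=0.2)
        assert result.estimates["gamma"] == pytest.approx(0.12, rel=0.3)
        assert isinstance(result.flat_directions, list)
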