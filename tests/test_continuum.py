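"""Continuum solvers: non-local transport, birth IDE, dilation properties."""

import numpy as np
import pytest

import abmlink as al
from abmlink.grids import GridSpec


@pytest.fixture(scope="module")
def box_setup():
    pot, rule, _, dom = al.melanophore_preset(2)
    grid = GridSpec.regular(dom, 48)
    region = al.make_region("box", dom)
    initial = al.uniform_initial_density(region, 400.0, grid)
    return pot, rule, dom, grid, initial


class TestGradientKernel:
    def test_cutoff_and_origin_zero(self, box_setup):
        pot, _, _, grid, _ = box_setup
        K = al.gradient_kernel(grid, pot)
        mesh = np.meshgrid(*[np.arange(-(K.shape[1] // 2), K.shape[1] // 2 + 1)
                             * grid.spacing[a] for a in range(2)], indexing="ij")
        dist = np.hypot(*mesh)
        assert np.all(K[:, dist >= pot.cutoff] == 0.0)
        centre = K.shape[1] // 2
        assert np.all(K[:, centre, centre] == 0.0)

    def test_exact_antisymmetry(self, box_setup):
        pot, _, _, grid, _ = box_setup
        K = al.gradient_kernel(grid, pot)
        assert np.array_equal(K, -K[:, ::-1, ::-1])

    def test_magnitude_at_omega(self, preset_2d):
        pot, _, _, dom = preset_2d
        grid = GridSpec.regular(dom, 300)  # 0.01 mm voxels: offset (2, 0) is at r = 0.02
        K = al.gradient_kernel(grid, pot)
        centre = K.shape[1] // 2
        mag = np.hypot(K[0, centre + 2, centre], K[1, centre + 2, centre])
        assert mag == pytest.approx(0.062 * np.exp(-1.0), rel=1e-9)

    def test_grid_too_coarse_rejected(self, preset_2d):
        pot, _, _, dom = preset_2d
        with pytest.raises(ValueError, match="coarse"):
            al.gradient_kernel(GridSpec.regular(dom, 20), pot)  # 0.15 mm voxels


class TestNonlocalVelocity:
    def test_matches_direct_double_sum(self, box_setup, rng):
        pot, _, _, grid, _ = box_setup
        K = al.gradient_kernel(grid, pot)
        field = al.DensityField(grid, rng.uniform(0, 400, grid.shape), 0.0)
        fast = al.nonlocal_velocity(field, K, 0.7)
        slow = al.nonlocal_velocity_direct(field, K, 0.7)
        assert np.abs(fast - slow).max() <= 1e-10 * np.abs(slow).max()

    def test_alpha_zero(self, box_setup, rng):
        pot, _, _, grid, _ = box_setup
        K = al.gradient_kernel(grid, pot)
        field = al.DensityField(grid, rng.uniform(0, 400, grid.shape), 0.0)
        assert np.all(al.nonlocal_velocity(field, K, 0.0) == 0.0)

    def test_uniform_interior_velocity_vanishes(self, box_setup):
        pot, _, _, grid, _ = box_setup
        K = al.gradient_kernel(grid, pot)
        field = al.DensityField(grid, np.full(grid.shape, 400.0), 0.0)
        u = al.nonlocal_velocity(field, K, 1.0)
        assert np.abs(u[:, 24, 24]).max() < 1e-8 * np.abs(K).max()

    def test_point_mass_gives_minus_kernel(self, box_setup):
        pot, _, _, grid, _ = box_setup
        K = al.gradient_kernel(grid, pot)
        values = np.zeros(grid.shape)
        values[24, 24] = 1.0
        u = al.nonlocal_velocity(al.DensityField(grid, values, 0.0), K, 1.0)
        m = K.shape[1] // 2
        expected = -grid.voxel_measure * K[:, m - 4:m + 5, m - 4:m + 5]
        assert np.allclose(u[:, 20:29, 20:29], expected, atol=1e-14)


class TestFvStep:
    def test_zero_velocity_identity(self, box_setup):
        _, _, _, grid, initial = box_setup
        out = al.fv_step(initial, np.zeros((2,) + tuple(grid.shape)), 0.05)
        assert np.array_equal(out.values, initial.values)

    def test_mass_conserved_and_nonnegative(self, box_setup, rng):
        pot, _, _, grid, initial = box_setup
        K = al.gradient_kernel(grid, pot)
        u = al.nonlocal_velocity(initial, K, 1.0)
        out = al.fv_step(initial, u, 0.05)
        assert abs(out.mass - initial.mass) < 1e-12 * initial.mass
        assert out.values.min() >= 0.0

    def test_uniform_advection_moves_centroid(self, preset_2d):
        dom = preset_2d[3]
        grid = GridSpec.regular(dom, 60)
        values = np.zeros(grid.shape)
        values[25:35, 25:35] = 100.0
        field = al.DensityField(grid, values, 0.0)
        speed = 0.4  # mm/day, rightward in x
        u = np.zeros((2,) + tuple(grid.shape))
        u[0] = speed
        dt = 0.5
        out = al.fv_step(field, u, dt)
        x = grid.centre_mesh()[0]
        shift = (x * out.values).sum() / out.values.sum() - (x * values).sum() / values.sum()
        assert shift == pytest.approx(speed * dt, rel=0.05)
        assert out.mass == pytest.approx(field.mass, rel=1e-13)


class TestLocalMassAndBirthStep:
    def test_uniform_density_neighbourhood_mass(self, preset_2d):
        dom = preset_2d[3]
        grid = GridSpec.regular(dom, 240)
        field = al.DensityField(grid, np.full(grid.shape, 400.0), 0.0)
        lm = al.local_mass(field, 0.075)
        # interior value equals the density integrated over the disc,
        # to pixelation accuracy (< 0.2% on this mesh)
        assert lm[120, 120] == pytest.approx(400 * np.pi * 0.075**2, rel=2e-3)

    def test_zero_field(self, box_setup):
        _, _, _, grid, _ = box_setup
        field = al.DensityField(grid, np.zeros(grid.shape), 0.0)
        assert np.all(al.local_mass(field, 0.075) == 0.0)

    def test_1d_interval_mass(self, preset_1d):
        dom = preset_1d[3]
        grid = GridSpec.regular(dom, 300)
        field = al.DensityField(grid, np.full(300, 10.0), 0.0)
        assert al.local_mass(field, 0.075)[150] == pytest.approx(1.5)

    def test_grid_too_coarse_rejected(self, preset_1d):
        grid = GridSpec.regular(preset_1d[3], 30)  # 0.1 mm > d_loc
        field = al.DensityField(grid, np.zeros(30), 0.0)
        with pytest.raises(ValueError, match="coarse"):
            al.local_mass(field, 0.075)

    def test_birth_step_thresholds(self, preset_1d):
        dom = preset_1d[3]
        grid = GridSpec.regular(dom, 300)
        params = al.ContinuumParams(gamma=0.5, c_plus=1.5, n_bir=4, d_loc=0.075)
        # empty field: local mass 0 everywhere, nothing happens
        empty = al.DensityField(grid, np.zeros(300), 0.0)
        assert np.all(al.birth_step(empty, params, 0.05).values == 0.0)
        # uniform field with local mass exactly c_plus: strict bound, unchanged
        at_cap = al.DensityField(grid, np.full(300, params.c_plus / 0.15), 0.0)
        out = al.birth_step(at_cap, params, 0.05)
        assert np.all(out.values[20:280] == at_cap.values[20:280])
        # uniform field with local mass 0.6 (inactive) vs 1.2 (active)
        low = al.DensityField(grid, np.full(300, 4.0), 0.0)  # lm = 0.6 < 1
        assert np.all(al.birth_step(low, params, 0.05).values[20:280] == 4.0)
        mid = al.DensityField(grid, np.full(300, 8.0), 0.0)  # lm = 1.2 in [1, 1.5)
        out = al.birth_step(mid, params, 0.05)
        assert out.values[150] == pytest.approx(8.0 + 0.05 * 0.5 * 4)


class TestSolveContinuum:
    def test_migration_mass_constant(self, box_setup):
        pot, _, _, grid, initial = box_setup
        sched = al.SimulationSchedule(dt_pde=0.05, t_final=10.0)
        sol = al.solve_continuum("movement", initial, al.ContinuumParams(alpha=1.0),
                                 pot, sched)
        drift = np.abs(sol.mass - sol.mass[0]).max()
        assert drift < 1e-10 * sol.mass[0]

    def test_birth_mass_growth_bounded(self, preset_1d):
        _, rule, _, dom = preset_1d
        grid = GridSpec.regular(dom, 300)
        region = al.make_region("point", dom, point=(0.0,))
        initial = al.uniform_initial_density(region, 0.0, grid)
        params = al.ContinuumParams(gamma=1 / 3, c_plus=7.0, n_bir=5, d_loc=0.075)
        sched = al.SimulationSchedule(dt_move=0.1, dt_pde=0.05, t_final=150.0)
        sol = al.solve_continuum("birth", initial, params, None, sched)
        per_day = np.diff(sol.mass)
        assert np.all(per_day <= params.gamma * params.n_bir * dom.measure + 1e-9)
        # piecewise-linear growth: once the travelling fronts are established
        # (and before they hit the boundary) the mass rate is constant
        assert np.std(per_day[80:140]) < 0.03 * np.mean(per_day[80:140])

    def test_birth_reaches_steady_state(self, preset_1d):
        _, _, _, dom = preset_1d
        small = al.Domain(bounds=((-0.3, 0.3),))
        grid = GridSpec.regular(small, 60)
        region = al.make_region("point", small, point=(0.0,))
        initial = al.uniform_initial_density(region, 0.0, grid)
        params = al.ContinuumParams(gamma=2.0, c_plus=3.0, n_bir=5, d_loc=0.075)
        sched = al.SimulationSchedule(dt_move=0.1, dt_pde=0.05, t_final=40.0)
        sol = al.solve_continuum("birth", initial, params, None, sched)
        # once every neighbourhood is at or above c+, the source switches off
        assert sol.mass[-1] == pytest.approx(sol.mass[-2])
        lm = al.local_mass(sol.fields[-1], params.d_loc)
        assert np.all((lm >= params.c_plus) | (lm < 1.0))

    def test_gamma_time_dilation(self, preset_1d):
        _, _, _, dom = preset_1d
        grid = GridSpec.regular(dom, 150)
        region = al.make_region("point", dom, point=(0.0,))
        initial = al.uniform_initial_density(region, 0.0, grid)
        sched = al.SimulationSchedule(dt_move=0.1, dt_pde=0.05, t_final=100.0)
        half = al.solve_continuum("birth", initial,
                                  al.ContinuumParams(gamma=0.5, c_plus=5.0, n_bir=2,
                                                     d_loc=0.075), None, sched)
        sched2 = al.SimulationSchedule(dt_move=0.1, dt_pde=0.05, t_final=50.0)
        unit = al.solve_continuum("birth", initial,
                                  al.ContinuumParams(gamma=1.0, c_plus=5.0, n_bir=2,
                                                     d_loc=0.075), None, sched2)
        a = half.field_at(100.0).values
        b = unit.field_at(50.0).values
        assert np.linalg.norm(a - b) <= 0.02 * np.linalg.norm(b)


class TestRadiusOfSupport:
    def test_zero_field(self, box_setup):
        _, _, _, grid, _ = box_setup
        field = al.DensityField(grid, np.zeros(grid.shape), 0.0)
        assert al.pde_radius_of_support(field) == 0.0

    def test_linf_distance_to_occupied_voxel(self, preset_2d):
        dom = preset_2d[3]
        grid = GridSpec.regular(dom, 30)
        values = np.zeros(grid.shape)
        values[grid.voxel_index([[2.0, 1.3]])[0, 0], grid.voxel_index([[2.0, 1.3]])[0, 1]] = 5.0
        field = al.DensityField(grid, values, 0.0)
        r = al.pde_radius_of_support(field, origin=(1.5, 1.5))
        assert r == pytest.approx(0.55, abs=grid.spacing[0])

    def test_threshold_filters_noise(self, box_setup):
        _, _, _, grid, _ = box_setup
        values = np.full(grid.shape, 1e-9)
        field = al.DensityField(grid, values, 0.0)
        assert al.pde_radius_of_support(field, threshold=1e-7) == 0.0


class TestUnitRateSolver:
    def test_unit_rate_matches_direct_birth_solve(self, preset_1d):
        _, _, _, dom = preset_1d
        grid = GridSpec.regular(dom, 150)
        region = al.make_region("point", dom, point=(0.0,))
        initial = al.uniform_initial_density(region, 0.0, grid)
        gamma, nbir = 0.4, 3
        sched = al.SimulationSchedule(dt_move=0.1, dt_pde=0.05, t_final=60.0)
        direct = al.solve_continuum("birth", initial,
                                    al.ContinuumParams(gamma=gamma, c_plus=6.0,
                                                       n_bir=nbir, d_loc=0.075),
                                    None, sched)
        table = al.solve_birth_unit_rate(initial, c_plus=6.0, d_loc=0.075,
                                         tau_max=gamma * nbir * 60.0, dtau=0.01,
                                         record_dtau=0.05)
        for t in (20.0, 40.0, 60.0):
            a = direct.field_at(t).values
            b = table.values_at(gamma * nbir * t)
            assert np.linalg.norm(a - b) <= 0.03 * max(np.linalg.norm(a), 1e-12)
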