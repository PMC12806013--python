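import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from _reference import ref_step
from angiofv.config import SimulationConfig
from angiofv.grid import build_grid, default_partition
from angiofv.integrate import (
    BoundarySetup,
    SimulationState,
    StabilityError,
    initial_state,
    run,
    stable_timestep,
    step,
)
from angiofv.model import ModelParams, TimeConfig
from angiofv.operators import ScalarField, robin_ghost_factor


def make_state(grid, u, v, t=0.0):
    return SimulationState(t=t, u=ScalarField(u, grid), v=ScalarField(v, grid))


def uniform_state(grid, cu=1.0, cv=1.0):
    return make_state(grid, np.full(grid.shape, cu), np.full(grid.shape, cv))


class TestStableTimestep:
    def test_zero_drift_diffusive_bound(self):
        """No TAF gradient, no cells, μ=0: the bound is 0.9·h²/(4·Dv)."""
        g = build_grid(100)
        state = make_state(g, np.zeros(g.shape), np.full(g.shape, 0.3))
        params = ModelParams(mu=0.0)
        assert stable_timestep(params, g, state) == pytest.approx(2.25e-3, rel=1e-6)

    def test_halving_h_quarters_the_bound(self):
        params = ModelParams(mu=0.0)
        dts = []
        for n in (50, 100):
            g = build_grid(n)
            dts.append(stable_timestep(params, g, make_state(g, np.zeros(g.shape), np.zeros(g.shape))))
        assert dts[0] / dts[1] == pytest.approx(4.0, rel=1e-6)

    def test_steep_gradient_tightens_the_bound(self):
        g = build_grid(20)
        _, Y = g.meshgrid()
        flat = make_state(g, np.ones(g.shape), np.full(g.shape, 0.5))
        steep = make_state(g, np.ones(g.shape), 5.0 * Y)
        params = ModelParams()
        assert stable_timestep(params, g, steep) < stable_timestep(params, g, flat)


class TestStep:
    def test_uniform_fields_are_stationary_without_sources(self):
        g = build_grid(8)
        params = ModelParams(gamma=0.0, mu=0.0)
        s0 = uniform_state(g, 0.7, 0.3)
        s1 = step(s0, 1e-3, params, BoundarySetup(default_partition()))
        assert np.array_equal(s1.u.values, s0.u.values)
        assert np.array_equal(s1.v.values, s0.v.values)
        assert s1.t == pytest.approx(1e-3)

    def test_pure_consumption_decay(self):
        """Uniform u=v=1 with μ=0: only the sink acts, v' = 1 − dt·γ."""
        g = build_grid(8)
        params = ModelParams(gamma=0.1, mu=0.0)
        s1 = step(uniform_state(g), 0.01, params, BoundarySetup(default_partition()))
        assert np.allclose(s1.v.values, 1.0 - 0.01 * 0.1, atol=1e-15)
        assert np.array_equal(s1.u.values, np.ones(g.shape))

    def test_oversized_step_rejected(self):
        g = build_grid(50)
        state = initial_state(g, default_partition())
        with pytest.raises(StabilityError):
            step(state, 1.0, ModelParams(), BoundarySetup(default_partition()))

    @pytest.mark.parametrize("u_leak", [False, True])
    def test_full_update_matches_brute_force_assembly(self, u_leak):
        """One explicit step on a 4×4 grid with ramp TAF and an EC bump
        equals the loop-assembled oracle to machine precision."""
        g = build_grid(4)
        X, Y = g.meshgrid()
        u0 = np.exp(-((X - 0.4) ** 2 + Y**2) / 0.1)
        v0 = 0.2 + 0.7 * Y
        params = ModelParams()
        dt = 0.5 * stable_timestep(params, g, make_state(g, u0, v0))
        s1 = step(
            make_state(g, u0, v0), dt, params, BoundarySetup(default_partition(), u_leak=u_leak)
        )
        u_ref, v_ref = ref_step(
            u0, v0, g.h, dt, params.Du, params.Dv, params.chi, params.alpha,
            params.gamma, params.mu, "top", u_leak,
        )
        assert np.allclose(s1.u.values, u_ref, rtol=0, atol=1e-14)
        assert np.allclose(s1.v.values, v_ref, rtol=0, atol=1e-14)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        u=arrays(np.float64, (5, 5), elements=st.floats(0, 3)),
        v=arrays(np.float64, (5, 5), elements=st.floats(0, 3)),
        mu=st.floats(0, 5),
        u_leak=st.booleans(),
    )
    def test_positivity_preserved_at_the_stable_step(self, u, v, mu, u_leak):
        """The combined diffusion+chemotaxis+consumption update stays
        nonnegative for any nonnegative fields when dt obeys the bound
        (step itself raises if positivity is ever violated)."""
        g = build_grid(5)
        params = ModelParams(mu=mu)
        state = make_state(g, u, v)
        dt = stable_timestep(params, g, state)
        s1 = step(state, dt, params, BoundarySetup(default_partition(), u_leak=u_leak))
        assert np.all(s1.u.values >= 0) and np.all(s1.v.values >= 0)


class TestRun:
    def test_heat_equation_oracle(self):
        """χ=γ=μ=0 with v₀=cos(πy) is a pure Neumann heat problem:
        v(t) = cos(πy)·exp(−Dv π² t), matched to 1e-3 relative L² at n=100."""
        n = 100
        cfg = SimulationConfig(
            params=ModelParams(chi=0.0, gamma=0.0, mu=0.0),
            n=n,
            time=TimeConfig(t_end=2.0, snapshot_times=(2.0,)),
        )
        g = build_grid(n)
        _, Y = g.meshgrid()
        init = make_state(g, np.zeros(g.shape), 1.0 + np.cos(np.pi * Y))
        traj = run(cfg, initial=init)
        v_T = traj.snapshots[-1].v.values
        exact = 1.0 + np.cos(np.pi * Y) * np.exp(-0.01 * np.pi**2 * 2.0)
        rel_l2 = np.linalg.norm(v_T - exact) / np.linalg.norm(exact)
        assert rel_l2 <= 1e-3

    def test_heat_equation_second_order_convergence(self):
        errors = []
        for n in (16, 32, 64):
            cfg = SimulationConfig(
                params=ModelParams(chi=0.0, gamma=0.0, mu=0.0),
                n=n,
                time=TimeConfig(t_end=1.0, snapshot_times=(1.0,)),
            )
            g = build_grid(n)
            _, Y = g.meshgrid()
            init = make_state(g, np.zeros(g.shape), 1.0 + np.cos(np.pi * Y))
            traj = run(cfg, initial=init)
            exact = 1.0 + np.cos(np.pi * Y) * np.exp(-0.01 * np.pi**2)
            errors.append(
                np.linalg.norm(traj.snapshots[-1].v.values - exact) / np.linalg.norm(exact)
            )
        orders = np.log2(np.array(errors[:-1]) / np.array(errors[1:]))
        assert np.all(orders > 1.7) and np.all(orders < 2.3)

    def test_closed_system_conserves_both_masses(self):
        """χ=γ=μ=0: no sources, no sinks, no boundary flux — both masses
        are flat to 1e-12 relative over the whole run."""
        cfg = SimulationConfig(
            params=ModelParams(chi=0.0, gamma=0.0, mu=0.0),
            n=50,
            time=TimeConfig(t_end=1.0, snapshot_times=()),
        )
        traj = run(cfg)
        mass_u = np.array([r.mass_u for r in traj.diagnostics])
        mass_v = np.array([r.mass_v for r in traj.diagnostics])
        assert np.abs(mass_u / mass_u[0] - 1).max() <= 1e-12
        assert np.abs(mass_v / mass_v[0] - 1).max() <= 1e-12

    def test_per_step_v_mass_balance_is_exact(self):
        """Each explicit step changes the v-mass by exactly
        dt·(Robin influx − γ Σ u v h²)."""
        g = build_grid(20)
        params = ModelParams(mu=2.0)
        bcs = BoundarySetup(default_partition())
        state = initial_state(g, default_partition())
        factor = robin_ghost_factor(g.h, params.mu)
        for _ in range(25):
            dt = stable_timestep(params, g, state)
            influx = params.Dv * (state.v.values[:, -1] * (factor - 1.0)).sum()
            consumption = params.gamma * (state.u.values * state.v.values).sum() * g.cell_area
            expected = dt * (influx - consumption)
            new = step(state, dt, params, bcs)
            delta = (new.v.values.sum() - state.v.values.sum()) * g.cell_area
            assert delta == pytest.approx(expected, rel=1e-10, abs=1e-15)
            state = new

    def test_leak_closure_u_mass_decreases_only_through_tumor_edge(self):
        """Under the literal-reading closure the EC mass lost per step is
        exactly the chemotactic outflow through the Robin face."""
        g = build_grid(20)
        params = ModelParams(mu=2.0)
        bcs = BoundarySetup(default_partition(), u_leak=True)
        state = initial_state(g, default_partition())
        from angiofv.model import chemotactic_sensitivity
        from angiofv.operators import robin_ghost

        for _ in range(25):
            dt = stable_timestep(params, g, state)
            vb = state.v.values[:, -1]
            vg = robin_ghost(vb, g.h, params.mu)
            a_out = chemotactic_sensitivity(0.5 * (vb + vg), params) * (vg - vb) / g.h
            # outward drift takes the boundary cell as donor
            outflow = (np.where(a_out > 0, state.u.values[:, -1], 0.0) * a_out).sum() * g.h
            new = step(state, dt, params, bcs)
            delta = (new.u.values.sum() - state.u.values.sum()) * g.cell_area
            assert delta == pytest.approx(-dt * outflow, rel=1e-10, abs=1e-16)
            state = new

    def test_snapshots_land_exactly_on_requested_times(self):
        cfg = SimulationConfig(
            n=32, time=TimeConfig(t_end=0.3, snapshot_times=(0.0, 0.13, 0.3))
        )
        traj = run(cfg)
        assert [s.t for s in traj.snapshots] == [0.0, 0.13, 0.3]
        assert traj.diagnostics[-1].t == 0.3

    def test_determinism_bit_identical(self):
        cfg = SimulationConfig(n=32, time=TimeConfig(t_end=0.2, snapshot_times=(0.2,)))
        a, b = run(cfg), run(cfg)
        assert np.array_equal(a.snapshots[-1].u.values, b.snapshots[-1].u.values)
        assert np.array_equal(a.snapshots[-1].v.values, b.snapshots[-1].v.values)
        assert a.diagnostics == b.diagnostics

    def test_explicit_unstable_dt_is_rejected(self):
        cfg = SimulationConfig(
            n=50, time=TimeConfig(t_end=1.0, dt=0.5, snapshot_times=())
        )
        with pytest.raises(StabilityError):
            run(cfg)

    def test_zero_length_run_returns_initial_conditions(self):
        cfg = SimulationConfig(n=16, time=TimeConfig(t_end=0.0, snapshot_times=(0.0,)))
        traj = run(cfg)
        g = build_grid(16)
        init = initial_state(g, default_partition())
        assert traj.n_steps == 0
        assert np.array_equal(traj.snapshots[0].u.values, init.u.values)
        assert np.array_equal(traj.snapshots[0].v.values, init.v.values)

    def test_grid_self_convergence(self):
        """Terminal TAF maxima converge under refinement: successive
        differences shrink from n=25 → 50 → 100."""
        maxima = []
        for n in (25, 50, 100):
            cfg = SimulationConfig(n=n, time=TimeConfig(t_end=1.0, snapshot_times=()))
            maxima.append(run(cfg).diagnostics[-1].max_v)
        d1, d2 = abs(maxima[1] - maxima[0]), abs(maxima[2] - maxima[1])
        assert d2 < d1
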