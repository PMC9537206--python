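"""Flow-solver validation against closed-form oracles and invariants."""

import numpy as np
import pytest

from stenoflow.geometry import StenosedVesselSpec, build_grid
from stenoflow.rheology import BloodProperties, CarreauYasudaParams, NewtonianParams
from stenoflow.solver import (
    AxisymFlowSolver,
    BoundaryConditions,
    FlowState,
    SolverConfig,
    SolverNonConvergence,
    centerline_velocity,
    observed_order,
    poiseuille_wss,
    run_simulation,
    wall_traction_snapshot,
    womersley_profile,
)
from stenoflow.waveforms import WaveformSpec, inlet_velocity_waveform, outlet_pressure_waveform

from conftest import MU_NEWT, RADIUS, solve_steady_tube


class TestEquilibrium:
    def test_rest_state_stays_at_rest(self, newtonian_props, straight_spec):
        grid = build_grid(straight_spec, 16, 8, growth_rate=1.0)
        bcs = BoundaryConditions(inlet_mean=lambda t: 0.0,
                                 outlet_pressure=lambda t: 500.0)
        solver = AxisymFlowSolver(grid, newtonian_props, bcs, SolverConfig())
        state = FlowState.at_rest(grid, p0=500.0)
        for _ in range(3):
            state = solver.step(state, 0.01)
        assert np.max(np.abs(state.u)) < 1e-12
        assert np.max(np.abs(state.v)) < 1e-12
        assert np.max(np.abs(state.p - 500.0)) < 1e-9


class TestPoiseuille:
    def test_centerline_to_mean_ratio(self, poiseuille_runs):
        solver, state, grid = poiseuille_runs[48]
        u_mean = np.sum(state.flux_z[-1]) / grid.inlet_area
        ratio = centerline_velocity(state.u, grid, grid.n_axial // 2) / u_mean
        assert ratio == pytest.approx(2.0, rel=0.01)

    def test_wall_shear_stress(self, poiseuille_runs, newtonian_props):
        solver, state, grid = poiseuille_runs[48]
        u_mean = np.sum(state.flux_z[-1]) / grid.inlet_area
        tau = wall_traction_snapshot(state.u, state.v, grid, newtonian_props)
        expected = poiseuille_wss(MU_NEWT, u_mean, RADIUS)
        assert tau[grid.n_axial // 2] == pytest.approx(expected, rel=0.01)

    def test_observed_spatial_order(self, poiseuille_runs):
        errs = []
        for nr in (12, 24, 48):
            solver, state, grid = poiseuille_runs[nr]
            u_mean = np.sum(state.flux_z[-1]) / grid.inlet_area
            ratio = centerline_velocity(state.u, grid, grid.n_axial // 2) / u_mean
            errs.append(abs(ratio - 2.0))
        p1 = observed_order(errs[0], errs[1], 2.0)
        p2 = observed_order(errs[1], errs[2], 2.0)
        assert p1 >= 1.8
        assert p2 >= 1.8

    def test_stokes_linearity_in_stenosed_tube(self, newtonian_props):
        # creeping flow: doubling the inflow doubles the wall traction
        taus = {}
        for u in (1e-4, 2e-4):
            _, state, grid = solve_steady_tube(newtonian_props, u, 16,
                                               severity=0.35)
            taus[u] = wall_traction_snapshot(state.u, state.v, grid,
                                             newtonian_props)
        ratio = taus[2e-4] / taus[1e-4]
        assert np.allclose(ratio, 2.0, rtol=0.01)


class TestShearThinning:
    def test_wall_stress_bounded_by_newtonian_limits(self):
        cy = CarreauYasudaParams()
        u_mean = 0.1
        props_cy = BloodProperties(rheology=cy)
        _, state, grid = solve_steady_tube(props_cy, u_mean, 24)
        tau = wall_traction_snapshot(state.u, state.v, grid, props_cy)
        col = grid.n_axial // 2
        lo = poiseuille_wss(cy.mu_inf, u_mean, RADIUS)
        hi = poiseuille_wss(cy.mu_zero, u_mean, RADIUS)
        assert lo < tau[col] < hi


class TestWomersleyOracle:
    def test_no_slip_at_wall(self):
        u = womersley_profile(RADIUS, 1060.0, MU_NEWT, 100.0, 10.0, 0.3, RADIUS)
        assert u == pytest.approx(0.0, abs=1e-12)

    def test_low_alpha_matches_quasi_steady_poiseuille(self):
        rho, mu, R, G = 1060.0, MU_NEWT, RADIUS, 50.0
        alpha = 0.03
        om = alpha**2 * mu / (rho * R**2)
        r = np.linspace(0.0, 0.95 * R, 20)
        t = 0.1 / om                      # instant with nonzero gradient
        u = womersley_profile(R, rho, mu, G, om, t, r)
        u_qs = G * np.cos(om * t) * (R**2 - r**2) / (4.0 * mu)
        assert np.allclose(u, u_qs, rtol=0.01)

    def test_high_alpha_inertial_attenuation(self):
        rho, mu, R, G = 1060.0, MU_NEWT, RADIUS, 50.0
        alpha = 10.0
        om = alpha**2 * mu / (rho * R**2)
        t = np.linspace(0.0, 2 * np.pi / om, 200, endpoint=False)
        amp = np.max(np.abs(womersley_profile(R, rho, mu, G, om, t, 0.0)))
        amp_qs = G * R**2 / (4.0 * mu)
        assert amp < amp_qs

    def test_r_outside_tube_rejected(self):
        with pytest.raises(ValueError):
            womersley_profile(RADIUS, 1060.0, MU_NEWT, 10.0, 5.0, 0.0, 2 * RADIUS)


class TestWomersleyAgreement:
    def test_single_harmonic_pulsatile_tube(self, newtonian_props):
        # alpha = 4: pulsatile inertia matters; inlet driven by the analytic
        # profile, so the interior must reproduce it everywhere
        rho, mu = 1060.0, MU_NEWT
        R = 2e-3
        alpha = 4.0
        om = alpha**2 * mu / (rho * R**2)
        T = 2 * np.pi / om
        G = 200.0
        spec = StenosedVesselSpec(inlet_radius=R, length=10e-3,
                                  stenosis_center=5e-3, stenosis_length=2e-3,
                                  severity=0.0)
        grid = build_grid(spec, 16, 48, growth_rate=1.0)
        bcs = BoundaryConditions(
            inlet_mean=lambda t: 0.0,
            outlet_pressure=lambda t: 0.0,
            inlet_profile=lambda r, t: womersley_profile(R, rho, mu, G, om, t, r),
        )
        solver = AxisymFlowSolver(grid, newtonian_props, bcs, SolverConfig())
        state = FlowState.at_rest(grid)
        steps = 200
        dt = T / steps
        num = den = 0.0
        col = 8
        for n in range(3 * steps):
            state = solver.step(state, dt)
            if n >= 2 * steps:
                ua = womersley_profile(R, rho, mu, G, om, state.time, grid.rc[col])
                num += np.sum((state.u[col] - ua) ** 2)
                den += np.sum(ua**2)
        assert np.sqrt(num / den) < 0.02


class TestPulsatileRun:
    def test_mass_balance_every_stored_instant(self, pulsatile_small):
        sol = pulsatile_small
        peak = np.max(np.abs(sol.inflow))
        assert np.max(np.abs(sol.inflow - sol.outflow)) < 1e-6 * peak

    def test_divergence_residual_within_tolerance(self, pulsatile_small):
        assert pulsatile_small.metadata["max_div_residual"] < SolverConfig().div_tol

    def test_periodicity_residual_small(self, pulsatile_small):
        assert pulsatile_small.periodicity_residual < 0.02

    def test_probe_series_length_contract(self, pulsatile_small):
        sol = pulsatile_small
        assert sol.times.size == 100
        assert np.allclose(np.diff(sol.times), sol.period / 100)
        for data in sol.probes.values():
            assert data["velocity"].size == 100
            assert data["pressure"].size == 100

    def test_traction_sign_follows_near_wall_velocity(self, pulsatile_small,
                                                      newtonian_props):
        # the inlet notch reverses the flow; the wall traction must flip
        # sign exactly when the near-wall tangential velocity does
        sol = pulsatile_small
        grid = sol.grid
        col = grid.n_axial // 2
        u_nw = np.array([u[col, -1] for _, u, _, _ in sol.states])
        tau = np.array([
            wall_traction_snapshot(u, v, grid, newtonian_props)[col]
            for _, u, v, _ in sol.states
        ])
        # the reversal happens and the signs agree away from the brief
        # annular-reversal onset (wall layer flips before the bulk)
        assert tau.min() < 0.0 < tau.max()
        strong = np.abs(u_nw) > 0.1 * np.max(np.abs(u_nw))
        assert np.all(np.sign(tau[strong]) == np.sign(u_nw[strong]))

    def test_wall_traction_series_shape(self, pulsatile_small):
        wts = pulsatile_small.wall_traction
        assert wts.tau.shape == (pulsatile_small.grid.n_axial, 100, 2)
        assert np.allclose(wts.tau[:, :, 1], 0.0)   # swirl-free

    def test_inlet_probe_identical_across_severities(self, newtonian_props):
        # the inlet waveform is Dirichlet-imposed, so severity cannot alter it
        wspec = WaveformSpec(peak_velocity=0.2, reverse_fraction=0.1)
        sols = {}
        for sev in (0.0, 0.25):
            spec = StenosedVesselSpec(inlet_radius=RADIUS, severity=sev)
            bcs = BoundaryConditions(inlet_mean=inlet_velocity_waveform(wspec),
                                     outlet_pressure=outlet_pressure_waveform(wspec))
            sols[sev] = run_simulation(
                spec, SolverConfig(n_cycles=1), newtonian_props, bcs,
                n_axial=32, n_radial=10, growth_rate=1.0,
            )
        assert np.allclose(
            sols[0.0].probes["inlet"]["velocity"],
            sols[0.25].probes["inlet"]["velocity"],
            rtol=1e-10, atol=1e-12,
        )


class TestNonConvergence:
    def test_exceeding_inner_iterations_raises(self, straight_spec):
        props = BloodProperties(rheology=CarreauYasudaParams())
        grid = build_grid(straight_spec, 16, 8, growth_rate=1.0)
        bcs = BoundaryConditions(inlet_mean=lambda t: 0.3,
                                 outlet_pressure=lambda t: 0.0)
        cfg = SolverConfig(picard_tol=1e-14, max_inner_iterations=2)
        solver = AxisymFlowSolver(grid, props, bcs, cfg)
        state = FlowState.at_rest(grid)
        with pytest.raises(SolverNonConvergence) as exc_info:
            solver.step(state, 0.01)
        assert exc_info.value.residual > 0.0
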