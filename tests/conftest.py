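"""Shared fixtures: small solver runs reused across test modules."""

import numpy as np
import pytest

from stenoflow.geometry import StenosedVesselSpec, build_grid
from stenoflow.rheology import BloodProperties, NewtonianParams
from stenoflow.solver import (
    AxisymFlowSolver,
    BoundaryConditions,
    SolverConfig,
    run_simulation,
)
from stenoflow.waveforms import WaveformSpec, inlet_velocity_waveform, outlet_pressure_waveform

MU_NEWT = 0.0035
RADIUS = 1.5e-3


@pytest.fixture(scope="session")
def newtonian_props():
    return BloodProperties(density=1060.0, rheology=NewtonianParams(mu=MU_NEWT))


@pytest.fixture(scope="session")
def straight_spec():
    return StenosedVesselSpec(inlet_radius=RADIUS, severity=0.0)


def solve_steady_tube(props, u_mean, n_radial, n_axial=24, growth_rate=1.0,
                      severity=0.0, tol=1e-10):
    """Steady solve in a (possibly stenosed) tube; returns (solver, state, grid)."""
    spec = StenosedVesselSpec(inlet_radius=RADIUS, severity=severity)
    grid = build_grid(spec, n_axial=n_axial, n_radial=n_radial, growth_rate=growth_rate)
    bcs = BoundaryConditions(inlet_mean=lambda t: u_mean,
                             outlet_pressure=lambda t: 0.0)
    cfg = SolverConfig(steady_tol=tol, steady_max_steps=400)
    solver = AxisymFlowSolver(grid, props, bcs, cfg)
    return solver, solver.steady_state(u_mean, 0.0), grid


@pytest.fixture(scope="session")
def poiseuille_runs(newtonian_props):
    """Steady Newtonian Poiseuille at three radial resolutions (uniform)."""
    out = {}
    for nr in (12, 24, 48):
        solver, state, grid = solve_steady_tube(newtonian_props, 0.1, nr)
        out[nr] = (solver, state, grid)
    return out


@pytest.fixture(scope="session")
def pulsatile_small(newtonian_props, straight_spec):
    """Coarse pulsatile Newtonian run in a straight tube (fast, reused)."""
    wspec = WaveformSpec(peak_velocity=0.3, reverse_fraction=0.3)
    inlet = inlet_velocity_waveform(wspec)
    outlet = outlet_pressure_waveform(wspec)
    bcs = BoundaryConditions(inlet_mean=inlet, outlet_pressure=outlet)
    cfg = SolverConfig(n_cycles=3)
    probes = {
        "inlet": 0.0,
        "throat": straight_spec.stenosis_center,
        "outlet": straight_spec.length,
    }
    return run_simulation(
        straight_spec, cfg, newtonian_props, bcs,
        n_axial=32, n_radial=12, growth_rate=1.0, probes=probes,
    )
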