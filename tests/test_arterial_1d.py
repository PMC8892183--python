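"""1D pulse-wave solver: tube law, gravity, and wave-propagation oracles.

The oracles are classical: the analytic wave speed of the elastic tube law,
hydrostatic equilibrium in a closed vertical vessel, pressure doubling at a
closed end, transparency of a matched terminal impedance, and first-order
grid convergence. Expected values are computed independently of the solver
(closed forms) and the solver output is compared against them.
"""
import math

import numpy as np
import pytest

from orthosim.arterial_1d import (WallLaw, GravityContext, wall_pressure,
                                  wave_speed, axial_gravity_term,
                                  beta_from_wave_speed, VesselGrid,
                                  VesselState, advance_vessel,
                                  junction_solve, SolverStateError,
                                  CFLError)

RHO = 1050.0


def _grid(length=1.0, radius=0.01, c0=6.0, n=40, **kw):
    A0 = math.pi * radius ** 2
    beta = beta_from_wave_speed(c0, A0, RHO)
    return VesselGrid(length=length, n_elements=n, A0_prox=A0, A0_dist=A0,
                      beta_prox=beta, beta_dist=beta, rho=RHO, **kw)


# ----------------------------------------------------------------------------
# wall law and gravity term
# ----------------------------------------------------------------------------

def test_wall_pressure_reference_state_and_linearity():
    law = WallLaw(beta=1000.0, A0=1e-4, reference_pressure=123.0)
    assert wall_pressure(law.A0, law) == pytest.approx(123.0)
    p1 = wall_pressure(1.3e-4, law) - 123.0
    law2 = WallLaw(beta=2000.0, A0=1e-4, reference_pressure=123.0)
    p2 = wall_pressure(1.3e-4, law2) - 123.0
    assert p2 == pytest.approx(2.0 * p1, rel=1e-12)


def test_wall_pressure_elastic_term_value():
    # beta*sqrt(A0)/A0 = 1e4 Pa and A = 1.21 A0 gives an elastic term of
    # 0.1 * 1e4 = 1e3 Pa
    A0 = 1e-4
    beta = 1e4 * A0 / math.sqrt(A0)
    law = WallLaw(beta=beta, A0=A0)
    assert wall_pressure(1.21 * A0, law) == pytest.approx(1e3, rel=1e-12)


def test_wall_pressure_rejects_nonpositive_area():
    law = WallLaw(beta=1000.0, A0=1e-4)
    with pytest.raises(SolverStateError):
        wall_pressure(0.0, law)


def test_wave_speed_matches_configured_reference():
    A0 = math.pi * 1e-4
    law = WallLaw(beta=beta_from_wave_speed(5.0, A0, RHO), A0=A0)
    assert wave_speed(A0, law, RHO) == pytest.approx(5.0, rel=1e-12)
    assert wave_speed(1.2 * A0, law, RHO) > 5.0  # stiffer when distended


def test_axial_gravity_term():
    ctx0 = GravityContext(tilt_angle_alpha=0.0, longitudinal_projection=1.0)
    assert axial_gravity_term(ctx0, 1e-4, RHO) == 0.0
    ctx = GravityContext(tilt_angle_alpha=math.pi / 2,
                         longitudinal_projection=1.0)
    # magnitude rho*g*A = 1050*9.81*1e-4 = 1.03 N/m, feetward positive
    assert axial_gravity_term(ctx, 1e-4, RHO) == pytest.approx(1.0301,
                                                               rel=1e-3)
    ctx_head = GravityContext(tilt_angle_alpha=math.pi / 2,
                              longitudinal_projection=-1.0)
    assert axial_gravity_term(ctx_head, 1e-4, RHO) == pytest.approx(
        -axial_gravity_term(ctx, 1e-4, RHO))


# ----------------------------------------------------------------------------
# solver oracles
# ----------------------------------------------------------------------------

def _gaussian_pulse_state(grid, dp=200.0, x0=0.2, sigma=0.04):
    """Rest state plus a small Gaussian pressure bump (Pa)."""
    p = dp * np.exp(-((grid.x - x0) / sigma) ** 2)
    sqA = np.sqrt(grid.A0) + p / grid.b
    return VesselState(A=sqA ** 2, Q=np.zeros(grid.n_nodes))


def _run(grid, state, t_end, alpha=0.0, inlet=("closed",), outlet=("closed",),
         safety=0.8):
    t = 0.0
    while t < t_end:
        dt = grid.max_stable_dt(state.A, state.Q, safety=safety)
        state = advance_vessel(grid, state, dt, alpha=alpha,
                               inlet=inlet, outlet=outlet)
        t += dt
    return state, None


def test_rest_state_is_discrete_equilibrium():
    grid = _grid(n=20)
    state = grid.initial_state(0.0)
    A0 = state.A.copy()
    state, _ = _run(grid, state, 0.05)
    assert np.allclose(state.A, A0, rtol=1e-12)
    assert np.allclose(state.Q, 0.0, atol=1e-15)


def test_pulse_speed_matches_analytic_wave_speed():
    c0 = 6.0
    grid = _grid(length=2.0, c0=c0, n=80)
    state = _gaussian_pulse_state(grid, dp=100.0, x0=0.4, sigma=0.08)
    # time the pressure peak past two stations by quadratic interpolation
    i1 = np.argmin(np.abs(grid.x - 0.8))
    i2 = np.argmin(np.abs(grid.x - 1.4))
    dt = grid.max_stable_dt(state.A, state.Q, safety=0.8)
    t = 0.0
    s1, s2 = [], []
    while t < 0.25:
        state = advance_vessel(grid, state, dt, inlet=("absorbing",),
                               outlet=("absorbing",))
        t += dt
        p = grid.pressure(state.A)
        s1.append(p[i1])
        s2.append(p[i2])
    t1 = np.argmax(s1) * dt
    t2 = np.argmax(s2) * dt
    c_measured = (grid.x[i2] - grid.x[i1]) / (t2 - t1)
    assert c_measured == pytest.approx(c0, rel=0.02)


def test_hydrostatic_equilibrium_in_closed_vertical_vessel():
    grid = _grid(length=0.5, c0=5.0, n=20, gamma_visc=1.0,
                 longitudinal_projection=1.0)
    state = grid.initial_state(2000.0)  # pressurized so A stays positive
    state, _ = _run(grid, state, 4.0, alpha=math.pi / 2, safety=0.5)
    p = grid.pressure(state.A)
    # axial pressure gradient equals rho*g (vessel aligned with gravity)
    grad = np.polyfit(grid.x, p, 1)[0]
    assert grad == pytest.approx(RHO * 9.81, rel=0.01)
    assert np.max(np.abs(state.Q)) < 1e-6


def test_closed_end_reflection_doubles_pressure():
    # measure the incident peak at a station near the closed end before the
    # reflection arrives, then the peak at the end itself: ratio ~ 2
    grid = _grid(length=3.0, c0=6.0, n=120)
    state = _gaussian_pulse_state(grid, dp=150.0, x0=1.0, sigma=0.15)
    ist = np.argmin(np.abs(grid.x - 2.6))
    t, incident, peak_end = 0.0, 0.0, 0.0
    while t < 0.55:
        dt = grid.max_stable_dt(state.A, state.Q, safety=0.8)
        state = advance_vessel(grid, state, dt, inlet=("absorbing",),
                               outlet=("closed",))
        t += dt
        p = grid.pressure(state.A)
        if t < 0.30:  # before the reflection returns to the station
            incident = max(incident, p[ist])
        peak_end = max(peak_end, p[-1])
    assert peak_end / incident == pytest.approx(2.0, rel=0.05)


def test_matched_terminal_impedance_is_non_reflecting():
    grid = _grid(length=1.5, c0=6.0, n=60)
    state = _gaussian_pulse_state(grid, dp=150.0, x0=0.75, sigma=0.08)
    A0 = grid.A0[-1]
    Zc = RHO * wave_speed(A0, WallLaw(beta=grid.beta_dist, A0=A0), RHO) / A0

    dt = grid.max_stable_dt(state.A, state.Q, safety=0.8)
    t = 0.0
    post = 0.0
    t_exit = (1.5 - 0.75) / 6.0
    while t < 3.0 * t_exit:
        state = advance_vessel(grid, state, dt, inlet=("absorbing",),
                               outlet=("impedance", 0.0, Zc))
        t += dt
        if t > 1.8 * t_exit:
            post = max(post, np.max(np.abs(grid.pressure(state.A))))
    assert post < 0.05 * 75.0  # reflected amplitude below 5% of incident


def test_junction_symmetry_transparency_and_mass():
    # symmetric bifurcation: identical children receive identical flows
    parent = _grid(length=0.3, radius=0.012, c0=5.5, n=12)
    child = _grid(length=0.3, radius=0.0085, c0=6.5, n=12)
    ps = _gaussian_pulse_state(parent, dp=400.0, x0=0.25, sigma=0.05)
    cs1 = child.initial_state(0.0)
    cs2 = child.initial_state(0.0)
    (Ap, Qp), kids = junction_solve((parent, ps),
                                    [(child, cs1), (child, cs2)])
    assert kids[0][1] == pytest.approx(kids[1][1], rel=1e-12)
    assert Qp == pytest.approx(kids[0][1] + kids[1][1], abs=1e-12 * abs(Qp)
                               + 1e-18)
    # single identical child: transparent interface, no reflection
    ps2 = _gaussian_pulse_state(parent, dp=400.0, x0=0.25, sigma=0.05)
    cs = VesselState(A=ps2.A.copy(), Q=ps2.Q.copy())
    (Ap1, Qp1), [(Ac, Qc)] = junction_solve((parent, ps2), [(parent, cs)])
    assert Qp1 == pytest.approx(Qc, rel=1e-12)
    assert Ap1 == pytest.approx(Ac, rel=1e-10)


def test_grid_convergence_is_at_least_first_order():
    c0 = 6.0

    def solve(n):
        grid = _grid(length=2.0, c0=c0, n=n)
        state = _gaussian_pulse_state(grid, dp=100.0, x0=0.7, sigma=0.12)
        t, t_end = 0.0, 0.08
        while t < t_end:
            dt = min(grid.max_stable_dt(state.A, state.Q, safety=0.8),
                     t_end - t)
            state = advance_vessel(grid, state, dt, inlet=("absorbing",),
                                   outlet=("absorbing",))
            t += dt
        x = np.linspace(0.05, 1.95, 200)
        return np.interp(x, grid.x, grid.pressure(state.A))

    ref = solve(320)
    e20 = np.linalg.norm(solve(20) - ref)
    e40 = np.linalg.norm(solve(40) - ref)
    assert e20 / e40 >= 2.0


def test_mass_conservation_with_closed_ends():
    grid = _grid(length=1.0, c0=6.0, n=30)
    state = _gaussian_pulse_state(grid, dp=300.0, x0=0.5, sigma=0.07)
    v0 = grid.volume(state.A)
    state, _ = _run(grid, state, 1.0, inlet=("closed",), outlet=("closed",))
    v1 = grid.volume(state.A)
    # < 0.1% per simulated minute; here it should be near machine precision
    assert abs(v1 - v0) / v0 < 1e-3 / 60.0


def test_cfl_violation_raises():
    grid = _grid(n=10)
    state = grid.initial_state(0.0)
    with pytest.raises(CFLError, match="dt"):
        advance_vessel(grid, state, 1.0)


def test_negative_area_raises_state_error():
    grid = _grid(n=10)
    state = grid.initial_state(0.0)
    state.A[3] = -1e-6
    with pytest.raises(SolverStateError):
        advance_vessel(grid, state, 1e-4)
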