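"""Lumped compartments: hydrostatics, RLC dynamics, leg-vein law, valves."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from orthosim.lumped_0d import (HydrostaticColumn, hydrostatic_gradient,
                                CompartmentState, compartment_rates,
                                ohmic_flow, LegVeinLaw, leg_vein_volume,
                                leg_vein_pressure, leg_vein_compliance,
                                ValveParams, VenousValveState,
                                venous_valve_step, valve_steady_flow)


def test_hydrostatic_gradient_supine_and_upright():
    assert hydrostatic_gradient(
        HydrostaticColumn(rho=1050, anatomical_height=0.5, alpha=0.0)) == 0.0
    # Stevino: 1050 * 9.81 * 0.5 / 133.322 = 38.63 mmHg
    v = hydrostatic_gradient(
        HydrostaticColumn(rho=1050, anatomical_height=0.5,
                          alpha=math.pi / 2))
    assert v == pytest.approx(1050 * 9.81 * 0.5 / 133.322, rel=1e-12)
    assert v == pytest.approx(38.63, abs=0.01)


def test_compartment_rates_ohmic_limit_and_mass_balance():
    st_ = CompartmentState(p=20.0, Q_out=5.0, V=100.0)
    # steady state: dp/dt = 0 when inflow equals outflow
    dp, dq = compartment_rates(st_, Q_in=5.0, R=2.0, L=1e-3, C=1.5,
                               p_downstream=10.0)
    assert dp == 0.0
    # algebraic (L = 0) outflow reduces to Ohm's law
    assert ohmic_flow(20.0, 10.0, R=2.0) == pytest.approx(5.0)
    dp, dq = compartment_rates(st_, Q_in=5.0, R=2.0, L=0.0, C=1.5,
                               p_downstream=10.0)
    assert dq is None


def test_rc_discharge_matches_exponential():
    # isolated compartment discharging through R: p(t) = p0 exp(-t/RC)
    R, C = 1.2, 2.5
    p = 40.0
    dt = 1e-3
    for _ in range(int(2.0 / dt)):  # RK2 on dp/dt = -p/(RC)
        q1 = p / R
        p_star = p + dt * (-q1 / C)
        q2 = p_star / R
        p = p + 0.5 * dt * (-(q1 + q2) / C)
    assert p == pytest.approx(40.0 * math.exp(-2.0 / (R * C)), rel=0.01)


def test_leg_vein_law_limits_and_compliance():
    law = LegVeinLaw(C0=9.0, deltaV_max=480.0, V_u=700.0)
    assert leg_vein_volume(0.0, law) == 700.0
    assert leg_vein_volume(1e9, law) == pytest.approx(700.0 + 480.0,
                                                      rel=1e-6)
    # local compliance at zero transmural pressure equals C0 (also by
    # central finite difference)
    eps = 1e-6
    fd = (leg_vein_volume(eps, law) - leg_vein_volume(-eps, law)) / (2 * eps)
    assert fd == pytest.approx(9.0, rel=1e-6)
    assert leg_vein_compliance(0.0, law) == pytest.approx(9.0, rel=1e-9)
    # below zero the law is linear with slope C0
    assert leg_vein_volume(-5.0, law) == pytest.approx(700.0 - 45.0)


@given(st.floats(min_value=-20.0, max_value=200.0))
@settings(max_examples=50, deadline=None)
def test_leg_vein_inverse_round_trip(p_tm):
    law = LegVeinLaw(C0=9.0, deltaV_max=480.0, V_u=700.0)
    v = leg_vein_volume(p_tm, law)
    assert leg_vein_pressure(v, law) == pytest.approx(p_tm, rel=1e-9,
                                                      abs=1e-9)


def test_venous_valve_closes_under_reverse_gradient():
    params = ValveParams(A_max=1.2, A_min=0.02)
    vs = VenousValveState(zeta=1.0, Q=10.0)
    zetas = []
    for _ in range(200):
        vs = venous_valve_step(vs, dp=-5.0, params=params, dt=1e-3)
        zetas.append(vs.zeta)
    assert zetas == sorted(zetas, reverse=True)
    assert vs.zeta == 0.0
    # sealed cardiac valve (A_min = 0) passes no flow at all
    cv = ValveParams(A_max=4.0, A_min=0.0)
    vs2 = VenousValveState(zeta=0.0, Q=0.0)
    vs2 = venous_valve_step(vs2, dp=-50.0, params=cv, dt=1e-3)
    assert vs2.Q == 0.0


def test_open_valve_reaches_bernoulli_orifice_flow():
    params = ValveParams(A_max=1.2, A_min=0.02, R_visc=0.0)
    vs = VenousValveState(zeta=1.0, Q=0.0)
    for _ in range(4000):
        vs = venous_valve_step(vs, dp=4.0, params=params, dt=1e-3)
    # steady Bernoulli orifice: Q = A_eff sqrt(2 dp / rho), unit-converted
    A_eff = 1.2e-4  # m^2
    q_expect = A_eff * math.sqrt(2 * 4.0 * 133.322 / 1050.0) * 1e6  # ml/s
    assert vs.Q == pytest.approx(q_expect, rel=1e-3)
    assert valve_steady_flow(4.0, 1.0, params) == pytest.approx(q_expect,
                                                                rel=1e-6)


def test_closed_valve_leak_bounded_by_minimum_area():
    params = ValveParams(A_max=1.2, A_min=0.02)
    vs = VenousValveState(zeta=0.0, Q=0.0)
    for _ in range(4000):
        vs = venous_valve_step(vs, dp=-10.0, params=params, dt=1e-3)
    A_min = 0.02e-4
    q_leak = A_min * math.sqrt(2 * 10.0 * 133.322 / 1050.0) * 1e6
    assert abs(vs.Q) <= q_leak * 1.001


def test_valve_rectifies_sinusoidal_forcing():
    params = ValveParams(A_max=1.2, A_min=0.008)
    vs = VenousValveState(zeta=0.5, Q=0.0)
    dt = 5e-4
    fwd = back = 0.0
    for i in range(int(5.0 / dt)):  # five 1-Hz cycles
        dp = 6.0 * math.sin(2 * math.pi * i * dt)
        vs = venous_valve_step(vs, dp=dp, params=params, dt=dt)
        if vs.Q >= 0:
            fwd += vs.Q * dt
        else:
            back -= vs.Q * dt
    assert back < 0.02 * fwd


def test_valve_steady_flow_solves_quadratic():
    params = ValveParams(A_max=2.0, A_min=0.0, R_visc=0.05)
    q = valve_steady_flow(8.0, 0.7, params)
    from orthosim.lumped_0d import _valve_bernoulli_B
    B = _valve_bernoulli_B(0.7, 2.0, 0.0, 1050.0)
    assert B * q * abs(q) + 0.05 * q == pytest.approx(8.0, rel=1e-12)


def test_ring_of_compartments_conserves_volume():
    # four linear compartments in a ring with no external sources
    n = 4
    R = [1.0, 0.5, 2.0, 0.8]
    L = [1e-3] * n
    C = [2.0, 1.0, 3.0, 1.5]
    V = np.array([100.0, 80.0, 120.0, 60.0])
    Vu = np.array([60.0, 50.0, 40.0, 30.0])
    Q = np.zeros(n)
    dt = 2e-4
    total0 = V.sum()

    def rhs(V, Q):
        p = (V - Vu) / C
        dQ = np.array([(p[i] - p[(i + 1) % n] - R[i] * Q[i]) / L[i]
                       for i in range(n)])
        dV = np.array([Q[(i - 1) % n] - Q[i] for i in range(n)])
        return dV, dQ

    for _ in range(int(10.0 / dt)):
        dV1, dQ1 = rhs(V, Q)
        dV2, dQ2 = rhs(V + dt * dV1, Q + dt * dQ1)
        V = V + 0.5 * dt * (dV1 + dV2)
        Q = Q + 0.5 * dt * (dQ1 + dQ2)
    assert V.sum() == pytest.approx(total0, rel=1e-12)
    # pressures equalize toward the common equilibrium
    p = (V - Vu) / C
    assert np.ptp(p) < 0.01
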