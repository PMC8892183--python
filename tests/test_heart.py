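"""Elastance heart, cardiac valves, intrathoracic pressure, pulmonary bed."""
import math

import numpy as np
import pytest

from orthosim.heart import (ElastanceParams, ChamberState,
                            normalized_elastance, elastance,
                            chamber_pressure, CardiacValveParams,
                            cardiac_valve_flow, IntrathoracicPressure,
                            intrathoracic_pressure, pulmonary_rates,
                            pv_loop_area)
from orthosim.lumped_0d import VenousValveState, valve_steady_flow

VENT = ElastanceParams(E_max=3.0, E_min=0.1, V_u=15.0,
                       chamber_kind="ventricle")
ATR = ElastanceParams(E_max=0.45, E_min=0.25, V_u=8.0,
                      chamber_kind="atrium", activation_onset=0.85,
                      activation_duration=0.16)


def test_ventricular_activation_shape():
    assert normalized_elastance(0.0, VENT, rr=0.8) == 0.0
    phases = np.linspace(0.0, 0.999, 500)
    e = np.array([normalized_elastance(p, VENT, rr=0.8) for p in phases])
    assert e.max() == pytest.approx(1.0, abs=5e-3)  # peaks at one
    assert np.all(e >= 0.0) and np.all(e <= 1.0 + 1e-9)
    # relaxed through late diastole
    assert normalized_elastance(0.8, VENT, rr=0.8) < 1e-3


def test_atrial_bump_is_late_and_wraps():
    assert normalized_elastance(0.5, ATR) == 0.0
    assert normalized_elastance(0.93, ATR) == pytest.approx(1.0, abs=1e-9)
    # wraps past the beat boundary (pre-ventricular kick)
    assert normalized_elastance(0.005, ATR) > 0.0


def test_activation_integral_shrinks_with_beat_period():
    def integral(rr):
        ph = np.linspace(0, 0.999, 2000)
        e = np.array([normalized_elastance(p, VENT, rr=rr) for p in ph])
        return np.trapezoid(e, ph * rr)
    # absolute systolic duration shortens as the beat shortens
    assert integral(0.6) < integral(0.9)


def test_chamber_pressure_contract():
    st = ChamberState(V=50.0, p=0.0)
    assert chamber_pressure(st, E=2.0, V_u=50.0, p_ext=-4.0) == -4.0
    st = ChamberState(V=100.0, p=0.0)
    assert chamber_pressure(st, E=2.0, V_u=50.0, p_ext=-4.0) == 96.0


def test_cardiac_valve_closed_blocks_flow():
    params = CardiacValveParams(A_max=4.0)
    vs = VenousValveState(zeta=0.0, Q=0.0)
    vs = cardiac_valve_flow(dp=-30.0, state=vs, params=params, dt=1e-3)
    assert vs.Q == 0.0 and vs.zeta == 0.0


def test_open_cardiac_valve_steady_flow_solves_quadratic():
    params = CardiacValveParams(A_max=4.0, R_visc=0.003)
    vs = VenousValveState(zeta=1.0, Q=0.0)
    for _ in range(3000):
        vs = cardiac_valve_flow(dp=3.0, state=vs, params=params, dt=1e-3)
    assert vs.Q == pytest.approx(valve_steady_flow(3.0, 1.0, params),
                                 rel=1e-3)


def test_valve_inertance_prevents_instantaneous_reversal():
    params = CardiacValveParams(A_max=4.0, R_visc=0.003)
    vs = VenousValveState(zeta=1.0, Q=300.0)
    vs2 = cardiac_valve_flow(dp=-20.0, state=vs, params=params, dt=2e-4)
    assert vs2.Q > 0.0  # decays continuously, no jump to reverse flow
    assert vs2.Q < 300.0


def test_intrathoracic_pressure_posture_dependence():
    p = IntrathoracicPressure(p_it_supine=-4.0, delta_p_it=3.0)
    assert intrathoracic_pressure(0.0, p) == -4.0
    a70 = math.radians(70.0)
    assert intrathoracic_pressure(a70, p) == pytest.approx(
        -4.0 - 3.0 * math.sin(a70))
    angles = np.linspace(0, math.pi / 2, 50)
    vals = [intrathoracic_pressure(a, p) for a in angles]
    assert all(np.diff(vals) <= 0)  # monotone along a tilt-up ramp


def test_pulmonary_windkessel_steady_and_time_constant():
    dp, q_out = pulmonary_rates(p=15.0, Q_in=100.0, R=0.15, C=4.0,
                                p_downstream=0.0)
    assert q_out == pytest.approx(100.0)
    assert dp == 0.0
    # step inflow: exponential approach with tau = RC
    R, C = 0.15, 4.0
    p, dt = 0.0, 1e-3
    for _ in range(int(0.6 / dt)):
        d1, _ = pulmonary_rates(p, 100.0, R, C, 0.0)
        d2, _ = pulmonary_rates(p + dt * d1, 100.0, R, C, 0.0)
        p += 0.5 * dt * (d1 + d2)
    expected = 15.0 * (1.0 - math.exp(-0.6 / (R * C)))
    assert p == pytest.approx(expected, rel=1e-3)


def test_pv_loop_area_rectangle_and_orientation():
    # rectangular loop V: 50 -> 120 ml at p = 10 and 100 mmHg, traversed
    # counterclockwise (filling at low pressure): area = 70 * 90
    V = np.array([50.0, 120.0, 120.0, 50.0])
    p = np.array([10.0, 10.0, 100.0, 100.0])
    assert pv_loop_area(V, p) == pytest.approx(70.0 * 90.0)
    # clockwise traversal flips the sign
    assert pv_loop_area(V[::-1], p[::-1]) == pytest.approx(-6300.0)


def test_lv_loop_counterclockwise_in_beating_steady_state(hut70_record):
    rec = hut70_record
    t = rec.time
    pre_end = rec.phases["pre_tilt_end"]
    b = np.searchsorted(rec.beat_times, pre_end) - 2
    m = (t >= rec.beat_times[b]) & (t < rec.beat_times[b + 1])
    area = pv_loop_area(rec.comp_v["lv"][m], rec.comp_p["lv"][m])
    assert area > 0.0


def test_frank_starling_preload_sweep():
    """Reducing ventricular filling pressure reduces stroke volume.

    Isolated left heart: constant-pressure atrial source -> mitral valve ->
    elastance LV -> aortic valve -> 2-element Windkessel afterload.
    """
    def stroke_volume(p_fill):
        rr = 0.9
        mitral = CardiacValveParams(A_max=5.0, R_visc=0.0025)
        aortic = CardiacValveParams(A_max=4.0, R_visc=0.003)
        vmit = VenousValveState(zeta=1.0, Q=0.0)
        vao = VenousValveState(zeta=0.0, Q=0.0)
        V = 120.0
        p_art = 80.0
        R_wk, C_wk = 1.0, 1.3
        dt = 5e-4
        sv = 0.0
        nbeats = 6
        for i in range(int(nbeats * rr / dt)):
            phase = (i * dt % rr) / rr
            E = elastance(phase, VENT, rr=rr)
            p_lv = E * (V - VENT.V_u)
            vmit = cardiac_valve_flow(p_fill - p_lv, vmit, mitral, dt)
            vao = cardiac_valve_flow(p_lv - p_art, vao, aortic, dt)
            V += dt * (vmit.Q - vao.Q)
            p_art += dt * (vao.Q - p_art / R_wk) / C_wk
            if i * dt > (nbeats - 1) * rr:
                sv += vao.Q * dt
        return sv

    svs = [stroke_volume(p) for p in (6.0, 7.5, 9.0, 10.5, 12.0)]
    assert all(np.diff(svs) > 0)
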