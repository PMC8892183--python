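"""Baroreflex, cardiopulmonary reflex, cerebral autoregulation, ICP."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from orthosim.regulation import (autonomic_activities, Effector,
                                 effector_update, cardiopulmonary_drive,
                                 AutoregParams, AutoregState,
                                 cerebral_autoregulation, ICPParams,
                                 intracranial_pressure)


def test_autonomic_activities_midpoint_and_limits():
    act = autonomic_activities(90.0, 90.0, nu=7.0)
    assert act.n_sym == pytest.approx(0.5) and act.n_para == pytest.approx(0.5)
    low = autonomic_activities(1e-5, 90.0, nu=7.0)
    assert low.n_sym > 0.999  # hypotension drives sympathetic outflow
    # direct sigmoid evaluation: p/pt = 0.9, nu = 7
    act = autonomic_activities(81.0, 90.0, nu=7.0)
    assert act.n_sym == pytest.approx(1.0 / (1.0 + 0.9 ** 7), rel=1e-12)
    assert act.n_sym == pytest.approx(0.676, abs=1e-3)


@given(st.floats(min_value=40.0, max_value=200.0),
       st.floats(min_value=1.0, max_value=15.0))
@settings(max_examples=60, deadline=None)
def test_activities_are_complementary(p, nu):
    act = autonomic_activities(p, 92.0, nu=nu)
    assert act.n_sym + act.n_para == pytest.approx(1.0, abs=1e-12)
    assert 0.0 < act.n_sym < 1.0


def test_nonpositive_afferent_clamped_with_warning():
    with pytest.warns(UserWarning):
        act = autonomic_activities(-5.0, 90.0, nu=7.0)
    assert act.n_sym > 0.999


def test_effector_fixed_point_and_step_response():
    balanced = autonomic_activities(90.0, 90.0, nu=7.0)
    eff = Effector(basal=66.0, gain_sym=100.0, gain_para=50.0, tau=2.0)
    for _ in range(100):
        effector_update(balanced, eff, dt=0.05)
    assert eff.value == pytest.approx(66.0)
    # step to full sympathetic drive: first-order rise with tau
    saturated = autonomic_activities(1e-5, 90.0, nu=7.0)
    t, dt = 0.0, 0.01
    while t < 2.0:  # one time constant
        effector_update(saturated, eff, dt=dt)
        t += dt
    target = 66.0 + 100.0 * 0.5 + 50.0 * 0.5
    expected = target + (66.0 - target) * math.exp(-1.0)
    assert eff.value == pytest.approx(expected, rel=5e-3)
    # all gains zero: effector never moves (regulation-off mode)
    frozen = Effector(basal=66.0, gain_sym=0.0, gain_para=0.0, tau=2.0)
    effector_update(saturated, frozen, dt=1.0)
    assert frozen.value == 66.0


def test_effector_clamped_to_bounds():
    eff = Effector(basal=66.0, gain_sym=1000.0, tau=0.01, lo=40.0, hi=180.0)
    sat = autonomic_activities(1e-5, 90.0, nu=7.0)
    for _ in range(200):
        effector_update(sat, eff, dt=0.05)
    assert eff.value == 180.0


def test_cardiopulmonary_reflex_scope_and_signs():
    # on target: no contribution
    assert cardiopulmonary_drive(4.0, 4.0, nu=2.0, gain=1.0) == 0.0
    # reduced preload (below target) raises the resistance drive
    assert cardiopulmonary_drive(1.0, 4.0, nu=2.0, gain=1.0) > 0.0
    assert cardiopulmonary_drive(8.0, 4.0, nu=2.0, gain=1.0) < 0.0
    with pytest.raises(ValueError):
        cardiopulmonary_drive(1.0, 0.0, nu=2.0, gain=1.0)


def test_autoregulation_fixed_point_and_dilation():
    par = AutoregParams(C_n=0.15, gain=8.0, tau=5.0)
    stt = AutoregState(x_aut=0.0, CBF_ref=12.5)
    C_a, r = cerebral_autoregulation(12.5, stt, par, dt=0.1, p_tm=60.0,
                                     p_tm_n=60.0)
    assert C_a == pytest.approx(0.15) and r == pytest.approx(1.0)
    # sustained low flow dilates: compliance up, resistance scale down
    stt = AutoregState(x_aut=0.0, CBF_ref=12.5)
    for _ in range(400):
        C_a, r = cerebral_autoregulation(10.0, stt, par, dt=0.1, p_tm=60.0,
                                         p_tm_n=60.0)
    assert C_a > 0.15 and r < 1.0
    # asymmetric saturation: dilation range exceeds constriction range
    s_hi = AutoregState(x_aut=0.0, CBF_ref=12.5)
    for _ in range(400):
        C_hi, _ = cerebral_autoregulation(25.0, s_hi, par, dt=0.1)
    assert (C_a - par.C_n) > (par.C_n - C_hi)


def test_poiseuille_scaling_quadruples_resistance_at_half_volume():
    par = AutoregParams(C_n=0.15, gain=0.0, tau=5.0)
    stt = AutoregState(x_aut=0.0, CBF_ref=12.5)
    # gain 0 keeps C_a = C_n; halving transmural pressure halves the
    # arteriolar volume and quadruples the Poiseuille resistance
    _, r_full = cerebral_autoregulation(12.5, stt, par, dt=0.1, p_tm=60.0,
                                        p_tm_n=60.0)
    _, r_half = cerebral_autoregulation(12.5, stt, par, dt=0.1, p_tm=30.0,
                                        p_tm_n=60.0)
    assert r_half == pytest.approx(4.0 * r_full, rel=1e-12)


def test_icp_supine_davson():
    par = ICPParams(R_csf=9.0, I_f=0.35)
    cvp = 4.0
    assert intracranial_pressure(cvp, 0.0, par) == pytest.approx(
        9.0 * 0.35 + cvp)


def test_icp_continuous_at_jugular_collapse():
    par = ICPParams()
    a = math.radians(40.0)
    lo = intracranial_pressure(3.0, a, par, p_jugular=-1e-9)
    hi = intracranial_pressure(3.0, a, par, p_jugular=+1e-9)
    assert lo == pytest.approx(hi, abs=1e-6)


def test_icp_decreases_monotonically_with_tilt():
    par = ICPParams()
    angles = np.linspace(0.0, math.pi / 2, 30)
    vals = [intracranial_pressure(4.0, a, par) for a in angles]
    assert all(np.diff(vals) < 0)
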