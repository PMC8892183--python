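"""Derived hemodynamic parameters, decomposition, ensemble averaging."""
import copy
import math

import numpy as np
import pytest

from orthosim.analysis import (beat_metrics, steady_window,
                               hydrostatic_decomposition, ensemble_waveform,
                               record_beat_waveforms, steady_state_report,
                               AnalysisError)
from orthosim.engine.runner import SimulationRecord
from orthosim.heart import pv_loop_area


def _synthetic_record(n_beats=5, rr=1.0, fs=250.0, p_const=None):
    """Minimal record: rectangular LV loop and simple site signals."""
    n = int(n_beats * rr * fs)
    t = np.arange(n) / fs
    phase = (t % rr) / rr
    p_site = (np.full(n, 100.0) if p_const is None
              else np.full(n, p_const))
    # rectangular LV loop: fill 50->120 ml at 10 mmHg, eject at 100 mmHg
    lvv = np.where(phase < 0.5, 50.0 + 140.0 * phase, 120.0 - 140.0 *
                   (phase - 0.5))
    lvp = np.where(phase >= 0.5, 100.0, 10.0)
    q_av = np.where((phase >= 0.5) & (phase < 0.75), 280.0, 0.0)
    zeros = np.zeros(n)
    comp_names = ["ra", "rv", "la", "lv", "pa", "pv", "legs_vein"]
    comp_p = {k: np.full(n, 5.0) for k in comp_names}
    comp_v = {k: np.full(n, 100.0) for k in comp_names}
    comp_p["lv"] = lvp
    comp_v["lv"] = lvv
    return SimulationRecord(
        time=t, alpha=zeros, hr=np.full(n, 60.0 / rr), n_sym=zeros + 0.5,
        p_ic=zeros, q_av=q_av, cbf=np.full(n, 12.5),
        site_p={"brachial": p_site, "aortic_arch": p_site},
        site_q={"brachial": zeros, "aortic_arch": zeros},
        comp_p=comp_p, comp_v=comp_v, eff={},
        beat_times=np.arange(n_beats) * rr, beat_rr=np.full(n_beats, rr),
        phases={"pre_tilt_end": n_beats * rr}, schedule=None)


def test_constant_pressure_collapses_map_sbp_dbp():
    rec = _synthetic_record(p_const=88.0)
    m = beat_metrics(rec)
    assert np.allclose(m.MAP, 88.0)
    assert np.allclose(m.SBP, 88.0)
    assert np.allclose(m.pulse_pressure, 0.0)


def test_stroke_work_of_rectangular_loop():
    rec = _synthetic_record()
    m = beat_metrics(rec)
    # area of the 70 ml x 90 mmHg rectangle
    assert m.SW.iloc[1] == pytest.approx(70.0 * 90.0, rel=0.02)


def test_tti_reduces_to_sixty_times_mean_lv_pressure():
    rec = _synthetic_record()
    m = beat_metrics(rec)
    lvp = rec.comp_p["lv"]
    t = rec.time
    mask = (t >= rec.beat_times[1]) & (t < rec.beat_times[2])
    assert m.TTI.iloc[1] == pytest.approx(60.0 * lvp[mask].mean(),
                                          rel=1e-12)
    # constant LV pressure of 50 mmHg: TTI = 3000 regardless of RR
    rec50 = _synthetic_record(rr=0.6)
    rec50.comp_p["lv"][:] = 50.0
    assert np.allclose(beat_metrics(rec50).TTI, 3000.0)


def test_stroke_volume_is_valve_flow_integral():
    rec = _synthetic_record()
    m = beat_metrics(rec)
    assert m.SV.iloc[1] == pytest.approx(280.0 * 0.25, rel=0.02)
    assert m.CO.iloc[1] == pytest.approx(m.SV.iloc[1] * m.HR.iloc[1] / 1000,
                                         rel=1e-9)


def test_unknown_site_raises():
    rec = _synthetic_record()
    with pytest.raises(AnalysisError, match="site"):
        beat_metrics(rec, pressure_site="elbow")


def test_shoelace_equals_trapezoid_work_integral():
    th = np.linspace(0.0, 2 * math.pi, 400, endpoint=False)
    V = 90.0 + 35.0 * np.cos(th)
    p = 55.0 + 45.0 * np.sin(th)  # counterclockwise ellipse
    area = pv_loop_area(V, p)
    # ∮ p dV by trapezoid around the closed loop
    Vc = np.append(V, V[0])
    pc = np.append(p, p[0])
    work = np.trapezoid(pc, Vc)
    assert area == pytest.approx(abs(work), rel=1e-3)
    assert area == pytest.approx(math.pi * 35.0 * 45.0, rel=1e-3)


def test_hydrostatic_decomposition():
    assert hydrostatic_decomposition(10.0, 1.2, 0.0) == 10.0
    assert hydrostatic_decomposition(10.0, 0.0, 70.0) == 10.0
    # removed column: rho g z sin(70 deg) = 1050*9.81*1.2*0.9397/133.322
    col = 1050 * 9.81 * 1.2 * math.sin(math.radians(70)) / 133.322
    assert hydrostatic_decomposition(100.0, 1.2, 70.0) == pytest.approx(
        100.0 - col)
    assert col == pytest.approx(87.1, abs=0.1)
    # round trip: delta_p* + column = delta_p exactly
    dstar = hydrostatic_decomposition(123.4, 0.8, 55.0)
    assert dstar + (123.4 - hydrostatic_decomposition(123.4, 0.8, 55.0)) \
        == 123.4


def test_ensemble_identical_beats_and_two_point_variance():
    beat = np.sin(np.linspace(0, math.pi, 120)) * 40 + 80
    ew = ensemble_waveform([beat, beat, beat])
    assert np.allclose(ew.sd, 0.0)
    assert np.allclose(ew.mean, np.interp(ew.grid,
                                          np.linspace(0, 1, 120), beat))
    two = ensemble_waveform([np.full(90, 80.0), np.full(140, 120.0)])
    assert np.allclose(two.mean, 100.0)
    assert np.allclose(two.sd, 20.0)


def test_ensemble_resampling_is_rr_invariant():
    base = np.sin(np.linspace(0, 2 * math.pi, 100)) + 2.0
    stretched = np.interp(np.linspace(0, 1, 400), np.linspace(0, 1, 100),
                          base)
    ew1 = ensemble_waveform([base])
    ew2 = ensemble_waveform([stretched])
    assert np.allclose(ew1.mean, ew2.mean, atol=1e-3)


def test_ensemble_total_variance_combines_within_and_between():
    g1 = [np.full(50, 90.0), np.full(50, 110.0)]   # var 100, mean 100
    g2 = [np.full(50, 70.0), np.full(50, 90.0)]    # var 100, mean 80
    ew = ensemble_waveform([g1, g2])
    assert np.allclose(ew.mean, 90.0)
    assert np.allclose(ew.sd ** 2, 100.0 + 100.0)  # law of total variance


def test_ensemble_empty_input_rejected():
    with pytest.raises(AnalysisError):
        ensemble_waveform([])


def test_record_beat_waveforms_window(hut70_record):
    beats = record_beat_waveforms(hut70_record, "brachial",
                                  t_start=hut70_record.phases[
                                      "pre_tilt_end"] - 10,
                                  t_end=hut70_record.phases["pre_tilt_end"])
    assert len(beats) >= 8
    ew = ensemble_waveform(beats, rescale=False)
    assert ew.mean.shape == (200,)
    assert np.all(ew.sd < 2.0)  # periodic steady state: tiny beat scatter


def test_steady_state_report_identity_and_scaling():
    rec = _synthetic_record(n_beats=8)
    rep = steady_state_report(rec, supine_record=rec)
    assert np.allclose(rep.change_percent.fillna(0.0), 0.0, atol=1e-9)
    scaled = copy.deepcopy(rec)
    scaled.q_av = rec.q_av * 0.81
    rep = steady_state_report(scaled, supine_record=rec)
    assert rep.loc["CO", "change_percent"] == pytest.approx(-19.0, abs=1e-6)
    # central and site pressures are reported separately
    assert {"MAP", "MAP_central"} <= set(rep.index)


def test_steady_state_report_reference_ranges():
    rec = _synthetic_record(n_beats=8)
    scaled = copy.deepcopy(rec)
    scaled.q_av = rec.q_av * 0.81
    rep = steady_state_report(scaled, supine_record=rec,
                              reference_ranges={"CO": (-30.0, -10.0),
                                                "HR": (5.0, 40.0)})
    assert bool(rep.loc["CO", "within_reference"]) is True
    assert bool(rep.loc["HR", "within_reference"]) is False
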