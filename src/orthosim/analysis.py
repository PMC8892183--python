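"""Derived hemodynamic parameters, waveform analytics and reporting.

Beat-wise metrics are computed from a :class:`SimulationRecord` between the
logged beat boundaries (ventricular activation onsets):

- MAP/SBP/DBP and pulse pressure at a named arterial site;
- SV as the aortic-valve flow integral per beat, CO = SV * HR,
  TPR = aortic MAP / CO (the cuff-style estimate; a (MAP - CVP)/CO variant
  is available), CVP as beat-mean right-atrial pressure;
- SW as the shoelace area of the left-ventricular pressure-volume loop and
  TTI = 60 * beat-mean LV pressure (mean LV pressure times RR, per minute);
- CBF as the beat-mean carotid+vertebral inflow, and the cardio-pulmonary
  (V_cp: four chambers + pulmonary circulation) and legs (V_L: all legs
  compartments) blood pools.

The hydrostatic decomposition removes the heart-referenced blood column
from a pressure change (Delta p* = Delta p - rho g z sin(alpha)); ensemble
averaging resamples beats onto a normalized time grid and combines within-
and between-source variance by the law of total variance.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .heart import pv_loop_area
from .units import hydrostatic_mmhg

V_CP_COMPARTMENTS = ("ra", "rv", "la", "lv", "pa", "pv")


class AnalysisError(ValueError):
    pass


def _beat_slices(time: np.ndarray, beat_times: np.ndarray):
    for b in range(len(beat_times) - 1):
        m = (time >= beat_times[b]) & (time < beat_times[b + 1])
        if np.count_nonzero(m) > 3:
            yield b, m


def beat_metrics(record, pressure_site: str = "brachial",
                 central_site: str = "aortic_arch",
                 tpr_uses_cvp: bool = False) -> pd.DataFrame:
    """Per-beat hemodynamic parameters as a DataFrame indexed by beat time.

    Columns: t, RR, HR, MAP, SBP, DBP, pulse_pressure (at
    ``pressure_site``), MAP_central, SV, CO, TPR, CVP, SW, TTI, CBF, V_cp,
    V_L, alpha.
    """
    if pressure_site not in record.site_p:
        raise AnalysisError(f"unknown site {pressure_site!r}; configured "
                            f"sites: {sorted(record.site_p)}")
    t = record.time
    p = record.site_p[pressure_site]
    pc = record.site_p[central_site]
    lvp = record.comp_p["lv"]
    lvv = record.comp_v["lv"]
    rap = record.comp_p["ra"]
    legs = [k for k in record.comp_v if k.startswith("legs_")]
    vl = sum(record.comp_v[k] for k in legs)
    vcp = sum(record.comp_v[k] for k in V_CP_COMPARTMENTS)
    rows = []
    for b, m in _beat_slices(t, record.beat_times):
        rr = record.beat_rr[b + 1] if b + 1 < len(record.beat_rr) \
            else record.beat_rr[b]
        rr_meas = record.beat_times[b + 1] - record.beat_times[b]
        hr = 60.0 / rr_meas
        sv = float(np.trapezoid(record.q_av[m], t[m]))
        co = sv * hr / 1000.0  # ml/beat * bpm -> l/min
        map_site = float(np.mean(p[m]))
        map_c = float(np.mean(pc[m]))
        cvp = float(np.mean(rap[m]))
        co_mls = sv / rr_meas
        tpr = (map_c - (cvp if tpr_uses_cvp else 0.0)) / co_mls \
            if co_mls > 0 else math.nan
        sw = pv_loop_area(lvv[m], lvp[m])
        tti = 60.0 * float(np.mean(lvp[m]))
        rows.append(dict(
            t=record.beat_times[b], RR=rr_meas, HR=hr,
            MAP=map_site, SBP=float(np.max(p[m])), DBP=float(np.min(p[m])),
            pulse_pressure=float(np.max(p[m]) - np.min(p[m])),
            MAP_central=map_c,
            SBP_central=float(np.max(pc[m])),
            DBP_central=float(np.min(pc[m])),
            SV=sv, CO=co, TPR=tpr, CVP=cvp, SW=sw, TTI=tti,
            CBF=float(np.mean(record.cbf[m])),
            V_cp=float(np.mean(vcp[m])), V_L=float(np.mean(vl[m])),
            alpha=float(np.mean(record.alpha[m])),
        ))
    if not rows:
        raise AnalysisError("record contains no complete beats")
    return pd.DataFrame(rows)


def steady_window(metrics: pd.DataFrame, t_end: float | None = None,
                  n_beats: int = 8) -> pd.Series:
    """Mean of the last ``n_beats`` complete beats before ``t_end``."""
    if t_end is None:
        df = metrics
    else:
        df = metrics[(metrics.t + metrics.RR) <= t_end]
    return df.tail(n_beats).mean(numeric_only=True)


def hydrostatic_decomposition(delta_p: float, z_site: float, alpha_deg: float,
                              rho: float = 1050.0) -> float:
    """Remove the heart-referenced hydrostatic column from a pressure change.

    ``delta_p*`` = delta_p - rho g z sin(alpha) (mmHg); ``z_site`` is
    measured from the right atrium, feetward positive.
    """
    return delta_p - hydrostatic_mmhg(
        rho, z_site, math.sin(math.radians(alpha_deg)))


@dataclass
class EnsembleWaveform:
    grid: np.ndarray   # normalized time in [0, 1]
    mean: np.ndarray
    sd: np.ndarray


def ensemble_waveform(beats: list, n_points: int = 200,
                      rescale: bool = False) -> EnsembleWaveform:
    """Ensemble-average beats after normalizing each to its RR duration.

    ``beats``: either arrays of samples (one beat each), or lists of such
    arrays grouped by source (e.g. subject); with groups, the SD band
    combines within-source and between-source variance by the law of total
    variance. ``rescale`` divides each source by its own mean before
    averaging (waveform-shape comparison).
    """
    if not beats:
        raise AnalysisError("ensemble_waveform needs at least one beat")
    grid = np.linspace(0.0, 1.0, n_points)
    grouped = isinstance(beats[0], (list, tuple))
    groups = beats if grouped else [[b] for b in beats]
    src_means = []
    src_vars = []
    for g in groups:
        res = []
        for b in g:
            b = np.asarray(b, dtype=float)
            x = np.linspace(0.0, 1.0, len(b))
            res.append(np.interp(grid, x, b))
        res = np.array(res)
        if rescale:
            res = res / np.mean(res)
        src_means.append(res.mean(axis=0))
        src_vars.append(res.var(axis=0))
    src_means = np.array(src_means)
    src_vars = np.array(src_vars)
    mean = src_means.mean(axis=0)
    total_var = src_vars.mean(axis=0) + src_means.var(axis=0)
    return EnsembleWaveform(grid=grid, mean=mean, sd=np.sqrt(total_var))


def record_beat_waveforms(record, site: str, t_start: float = -np.inf,
                          t_end: float = np.inf) -> list:
    """Extract per-beat sampled waveforms of a site within a time window."""
    out = []
    p = record.site_p[site]
    for b, m in _beat_slices(record.time, record.beat_times):
        if record.beat_times[b] >= t_start and \
                record.beat_times[b + 1] <= t_end:
            out.append(p[m].copy())
    return out


def steady_state_report(record, supine_record=None,
                        pressure_site: str = "brachial",
                        reference_ranges: dict | None = None
                        ) -> pd.DataFrame:
    """Tilt-vs-supine comparison of beat-averaged parameters.

    With one record, the pre-tilt window is used as the supine reference
    (requires phase markers); with two records, the steady tail of each.
    Reports absolute values and relative changes; optional pass/fail
    against a literature reference-range table ``{param: (lo, hi)}`` on the
    relative change in percent.
    """
    m_t = beat_metrics(record, pressure_site=pressure_site)
    if supine_record is None:
        pre_end = record.phases.get("pre_tilt_end")
        sup = steady_window(m_t, t_end=pre_end)
        til = steady_window(m_t)
    else:
        sup = steady_window(beat_metrics(supine_record,
                                         pressure_site=pressure_site))
        til = steady_window(m_t)
    rows = []
    for k in ("MAP", "MAP_central", "SBP_central", "DBP_central", "HR",
              "SV", "CO", "TPR", "CVP", "SW", "TTI", "CBF", "V_cp", "V_L",
              "pulse_pressure"):
        rel = 100.0 * (til[k] - sup[k]) / sup[k] if sup[k] != 0 else math.nan
        row = dict(parameter=k, supine=sup[k], tilt=til[k],
                   change_percent=rel)
        if reference_ranges and k in reference_ranges:
            lo, hi = reference_ranges[k]
            row["within_reference"] = bool(lo <= rel <= hi)
        rows.append(row)
    return pd.DataFrame(rows).set_index("parameter")
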