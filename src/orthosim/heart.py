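"""Four-chamber time-varying-elastance heart, cardiac valves, pulmonary
circulation and intrathoracic pressure.

Chamber transmural pressure is tied to stressed volume through a
time-varying elastance ``p = E(t) (V - V_u) + p_ext`` with
``E(t) = E_min + (E_max - E_min) e(t)``. The normalized activation ``e(t)``
is a double-Hill waveform for the ventricles and a raised-cosine bump placed
late in the beat (pre-ventricular) for the atria. Systolic duration scales
with the square root of the beat period, so systole occupies a growing
fraction of the beat as heart rate rises.

Cardiac valves are the same graded non-ideal diodes as the venous valves
(Bernoulli resistance + viscous resistance + inertance), with zero minimum
area allowed (no leak when closed).

Intrathoracic pressure is a constant sub-atmospheric external pressure on
thoracic compartments that decreases with the sine of the tilt angle; since
the tilt ramp is cosinusoidal in time, so is the intrathoracic transition.
The pulmonary arterial and venous compartments are 2-element Windkessels
exposed to intrathoracic pressure.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .lumped_0d import ValveParams, VenousValveState, venous_valve_step

# Double-Hill shape constants (ventricles); time constants scale with the
# systolic duration T_sys = k_sys * sqrt(RR).
VENT_M1 = 1.32
VENT_M2 = 27.4
VENT_TAU1_FRAC = 0.65   # tau1 = frac * T_sys
VENT_TAU2_FRAC = 1.09
SYS_DUR_COEFF = 0.35    # T_sys = coeff * RR**exp (s)
SYS_DUR_EXP = 0.5


@dataclass(frozen=True)
class ElastanceParams:
    E_max: float   # mmHg/ml
    E_min: float   # mmHg/ml
    V_u: float     # ml
    chamber_kind: str           # 'atrium' | 'ventricle'
    activation_onset: float = 0.0    # fraction of RR
    activation_duration: float = 0.18  # atria only, fraction of RR
    sys_dur_coeff: float = SYS_DUR_COEFF
    sys_dur_exp: float = SYS_DUR_EXP

    def __post_init__(self):
        if not self.E_max >= self.E_min > 0:
            raise ValueError("need E_max >= E_min > 0")
        if self.chamber_kind not in ("atrium", "ventricle"):
            raise ValueError("chamber_kind must be atrium or ventricle")
        if not 0.0 <= self.activation_onset <= 1.0:
            raise ValueError("activation_onset must be a fraction of RR")


@dataclass
class ChamberState:
    V: float  # ml
    p: float  # mmHg


@njit(cache=True)
def _vent_shape(t, t_sys):
    """Unnormalized double-Hill ventricular activation at time t (s)."""
    if t <= 0.0:
        return 0.0
    tau1 = VENT_TAU1_FRAC * t_sys
    tau2 = VENT_TAU2_FRAC * t_sys
    x1 = (t / tau1) ** VENT_M1
    g1 = x1 / (1.0 + x1)
    g2 = 1.0 / (1.0 + (t / tau2) ** VENT_M2)
    return g1 * g2


@njit(cache=True)
def _vent_shape_peak(t_sys, rr):
    """Peak of the double-Hill waveform over the beat (for normalization)."""
    peak = 0.0
    n = 160
    for i in range(1, n):
        v = _vent_shape(rr * i / n, t_sys)
        if v > peak:
            peak = v
    return peak


@njit(cache=True)
def _atrial_shape(phase, onset, dur):
    """Raised-cosine atrial bump at beat phase in [0,1), wrapping the end."""
    s = phase - onset
    if s < 0.0:
        s += 1.0
    if s < dur:
        return 0.5 * (1.0 - math.cos(2.0 * math.pi * s / dur))
    return 0.0


def normalized_elastance(t_beat: float, params: ElastanceParams,
                         rr: float = 0.8) -> float:
    """Normalized activation e in [0, 1] at beat phase ``t_beat`` in [0, 1).

    ``rr`` is the current beat period (s); the ventricular systolic duration
    follows ``sys_dur_coeff * rr**sys_dur_exp`` (exponent < 1), so the
    systolic fraction of the beat rises as heart rate rises.
    """
    if not 0.0 <= t_beat < 1.0:
        raise ValueError("t_beat must lie in [0, 1)")
    if params.chamber_kind == "ventricle":
        t_sys = params.sys_dur_coeff * rr ** params.sys_dur_exp
        t = (t_beat - params.activation_onset) * rr
        if t < 0.0:
            return 0.0
        peak = _vent_shape_peak(t_sys, rr)
        return _vent_shape(t, t_sys) / peak
    return _atrial_shape(t_beat, params.activation_onset,
                         params.activation_duration)


def elastance(t_beat: float, params: ElastanceParams, rr: float = 0.8) -> float:
    """E(t) = E_min + (E_max - E_min) e(t), mmHg/ml."""
    return params.E_min + (params.E_max - params.E_min) * normalized_elastance(
        t_beat, params, rr)


def chamber_pressure(state: ChamberState, E: float, V_u: float,
                     p_ext: float = 0.0) -> float:
    """p = E (V - V_u) + p_ext (mmHg)."""
    return E * (state.V - V_u) + p_ext


@dataclass(frozen=True)
class CardiacValveParams(ValveParams):
    """Cardiac valve: graded diode with viscous resistance; A_min = 0 by
    default (competent valve seals completely)."""

    A_min: float = 0.0
    K_open: float = 50.0
    K_close: float = 50.0
    R_visc: float = 0.003      # mmHg s/ml
    inertance: float = 3e-4    # mmHg s^2/ml

    def __post_init__(self):
        if not self.A_max > self.A_min >= 0:
            raise ValueError("need A_max > A_min >= 0")


def cardiac_valve_flow(dp: float, state: VenousValveState,
                       params: CardiacValveParams, dt: float
                       ) -> VenousValveState:
    """Advance a cardiac valve one step; same diode structure as the venous
    valves plus series viscous resistance. No flow when fully closed."""
    return venous_valve_step(state, dp, params, dt)


@dataclass(frozen=True)
class IntrathoracicPressure:
    p_it_supine: float = -4.0  # mmHg (sub-atmospheric)
    delta_p_it: float = 3.0    # mmHg magnitude of the upright decrease

    def __post_init__(self):
        if self.p_it_supine >= 0:
            raise ValueError("supine intrathoracic pressure must be negative")
        if self.delta_p_it < 0:
            raise ValueError("delta_p_it must be >= 0")


def intrathoracic_pressure(alpha: float, params: IntrathoracicPressure
                           ) -> float:
    """External (extra-chamber) pressure on thoracic compartments, mmHg.

    ``p_it = p_it_supine - delta_p_it sin(alpha)`` (alpha in rad). Along a
    cosinusoidal tilt ramp this inherits the cosinusoidal time course.
    """
    return params.p_it_supine - params.delta_p_it * math.sin(alpha)


def pulmonary_rates(p: float, Q_in: float, R: float, C: float,
                    p_downstream: float, dp_ext_dt: float = 0.0):
    """2-element Windkessel rates: (dp/dt, Q_out) with algebraic outflow."""
    q_out = (p - p_downstream) / R
    return (Q_in - q_out) / C + dp_ext_dt, q_out


def pv_loop_area(V: np.ndarray, p: np.ndarray) -> float:
    """Signed shoelace area of a pressure-volume loop (mmHg*ml).

    Positive for counterclockwise traversal in the (V, p) plane, i.e. a
    working (ejecting) ventricle.
    """
    V = np.asarray(V, dtype=float)
    p = np.asarray(p, dtype=float)
    return 0.5 * float(np.sum(V * np.roll(p, -1) - np.roll(V, -1) * p))
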