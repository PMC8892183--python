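"""Short-term regulation: arterial baroreflex, cardiopulmonary reflex,
cerebral autoregulation and intracranial pressure.

Afferent pressures (mean aortic-carotid sinus pressure for the baroreflex,
mean right-atrial pressure for the cardiopulmonary reflex) are exponential
moving averages of the instantaneous signals. Sympathetic/parasympathetic
activities are sigmoids of the afferent over its target::

    n_sym  = 1 / (1 + (p/p_t)^nu),      n_para = 1 - n_sym

so both equal 1/2 on target and hypotension drives sympathetic activity
toward 1. Each effector x (heart rate, ventricular contractility, regional
arteriolar resistance, venous unstressed volume and compliance) relaxes with
first-order dynamics toward a basal value plus gain-weighted activity
deviations::

    tau_x dx/dt = -x + x_basal + G_sym (n_sym - 1/2) - G_para (n_para - 1/2)

clamped to configured bounds. The parasympathetic branch acts on heart rate
only; the cardiopulmonary reflex reuses the same structure but affects only
peripheral resistance and venous tone, adding to the baroreflex contribution.

Cerebral autoregulation holds cerebral blood flow (CBF) near its supine
reference by varying cerebral arteriolar compliance between asymmetric
dilation/constriction bounds (first-order filtered flow error through a
saturating sigmoid) with resistance following Poiseuille scaling
R ~ 1/V^2 of the arteriolar blood volume.

Intracranial pressure follows Davson's equation
``p_ic = R_csf I_f + p_dural``; upright, the dural venous pressure is the
central venous pressure minus the head-to-heart hydrostatic column until the
jugular (superior vena cava) pressure reaches zero, beyond which the column
extends only from the head to the collapse point.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from numba import njit

from .units import hydrostatic_mmhg


@dataclass
class AutonomicActivity:
    n_sym: float
    n_para: float
    nu: float


@njit(cache=True)
def _sigmoid_activity(p_mean, p_target, nu):
    r = p_mean / p_target
    n_sym = 1.0 / (1.0 + r ** nu)
    return n_sym, 1.0 - n_sym


def autonomic_activities(p_mean: float, p_target: float,
                         nu: float) -> AutonomicActivity:
    """Sympathetic/parasympathetic activity from afferent over target."""
    if p_target <= 0:
        raise ValueError("target pressure must be positive")
    if p_mean <= 0:
        warnings.warn("non-positive afferent pressure clamped", stacklevel=2)
        p_mean = 1e-6
    n_sym, n_para = _sigmoid_activity(p_mean, p_target, nu)
    return AutonomicActivity(n_sym=n_sym, n_para=n_para, nu=nu)


@dataclass
class Effector:
    """One first-order controlled quantity with gains, time constant and
    saturation bounds."""

    basal: float
    gain_sym: float
    gain_para: float = 0.0
    tau: float = 3.0
    lo: float = -math.inf
    hi: float = math.inf
    value: float = field(default=math.nan)

    def __post_init__(self):
        if math.isnan(self.value):
            self.value = self.basal


@njit(cache=True)
def _effector_step(x, basal, g_sym, g_para, n_sym, n_para, tau, lo, hi,
                   dt, extra_drive):
    """Exact exponential step of tau x' = -x + x_inf, then clamp."""
    x_inf = (basal + g_sym * (n_sym - 0.5) - g_para * (n_para - 0.5)
             + extra_drive)
    x = x_inf + (x - x_inf) * math.exp(-dt / tau)
    if x < lo:
        x = lo
    elif x > hi:
        x = hi
    return x


def effector_update(act: AutonomicActivity, eff: Effector, dt: float,
                    extra_drive: float = 0.0) -> Effector:
    """Advance one effector by ``dt`` (exponential integrator + clamp).

    ``extra_drive`` carries the additive contribution of a second reflex
    sharing the same effector (cardiopulmonary on resistances/venous tone).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    eff.value = _effector_step(eff.value, eff.basal, eff.gain_sym,
                               eff.gain_para, act.n_sym, act.n_para, eff.tau,
                               eff.lo, eff.hi, dt, extra_drive)
    return eff


def cardiopulmonary_drive(p_ra_mean: float, cp_target: float, nu: float,
                          gain: float) -> float:
    """Additive drive of the cardiopulmonary reflex on a shared effector.

    Low-pressure receptors in the right atrium: a fall of mean right-atrial
    pressure below its supine target raises sympathetic outflow to the
    peripheral resistances and venous tone (only); the drive vanishes on
    target.
    """
    if cp_target <= 0:
        raise ValueError("cardiopulmonary target pressure must be positive")
    p = max(p_ra_mean, 1e-6)
    n_sym, _ = _sigmoid_activity(p, cp_target, nu)
    return gain * (n_sym - 0.5)


# ----------------------------------------------------------------------------
# Cerebral autoregulation (flow-error sigmoid on arteriolar compliance)
# ----------------------------------------------------------------------------

@dataclass
class AutoregParams:
    C_n: float            # central cerebral arteriolar compliance, ml/mmHg
    gain: float = 6.0     # on relative CBF error
    tau: float = 10.0     # s
    amp_dilation: float = 2.2    # (C_max - C_n)/C_n when flow is low
    amp_constriction: float = 0.6  # (C_n - C_min)/C_n when flow is high


@dataclass
class AutoregState:
    x_aut: float = 0.0
    C_a: float = math.nan
    CBF_ref: float = math.nan


@njit(cache=True)
def _autoreg_compliance(x, C_n, amp_dil, amp_con):
    """Asymmetric sigmoid: x < 0 (low flow) dilates toward C_n(1+amp_dil)."""
    if x < 0.0:
        amp = amp_dil
    else:
        amp = amp_con
    s = math.tanh(-x)
    return C_n * (1.0 + amp * s) if x < 0.0 else C_n * (1.0 + amp * s)


def cerebral_autoregulation(CBF_mean: float, st: AutoregState,
                            params: AutoregParams, dt: float,
                            p_tm: float = 60.0, R_n: float | None = None,
                            p_tm_n: float = 60.0):
    """Advance the autoregulation state; returns (C_a, R_scale).

    ``tau x' = -x + gain (CBF - CBF_ref)/CBF_ref``; compliance from the
    asymmetric saturating sigmoid of x (dilation range > constriction
    range); arteriolar volume V_a = C_a p_tm and Poiseuille resistance
    R_a = R_n (V_n / V_a)^2.
    """
    if st.CBF_ref <= 0 or math.isnan(st.CBF_ref):
        raise ValueError("CBF_ref must be positive (capture supine mean)")
    x_inf = params.gain * (CBF_mean - st.CBF_ref) / st.CBF_ref
    st.x_aut = x_inf + (st.x_aut - x_inf) * math.exp(-dt / params.tau)
    st.C_a = _autoreg_compliance(st.x_aut, params.C_n,
                                 params.amp_dilation,
                                 params.amp_constriction)
    V_n = params.C_n * p_tm_n
    V_a = max(st.C_a * max(p_tm, 1e-6), 1e-9)
    r_scale = (V_n / V_a) ** 2
    if R_n is not None:
        return st.C_a, R_n * r_scale
    return st.C_a, r_scale


# ----------------------------------------------------------------------------
# Intracranial pressure (Davson + jugular collapse)
# ----------------------------------------------------------------------------

@dataclass(frozen=True)
class ICPParams:
    R_csf: float = 9.0       # mmHg/(ml/min) CSF outflow resistance
    I_f: float = 0.35        # ml/min CSF formation rate
    z_dural: float = -0.23   # m, dural sinus position (headward negative)
    z_jugular: float = -0.10  # m, jugular/superior-cava collapse point
    rho: float = 1050.0

    @property
    def davson_offset(self) -> float:
        """R_csf * I_f in mmHg."""
        return self.R_csf * self.I_f


@njit(cache=True)
def _icp(cvp, p_jug, sin_alpha, rcsf_if, z_dural, z_jug, rho, g_mmhg_per_m):
    """p_ic = R_csf I_f + p_dural with a continuous collapse switch.

    Below collapse the dural pressure is cvp minus the full head-heart
    column; at and beyond collapse (jugular pressure <= 0) the column spans
    only head to collapse point. Writing
    p_dural = max(p_jug, 0) - rho g (z_jug - z_dural) sin(alpha)
    makes the two branches agree exactly where the jugular pressure is zero.
    """
    col_head_jug = g_mmhg_per_m * rho * (z_jug - z_dural) * sin_alpha
    pj = p_jug if p_jug > 0.0 else 0.0
    return rcsf_if + pj - col_head_jug


def intracranial_pressure(cvp: float, alpha: float, params: ICPParams,
                          p_jugular: float | None = None) -> float:
    """Intracranial pressure (mmHg) at tilt angle ``alpha`` (rad).

    ``cvp`` is the (mean) right-atrial pressure; ``p_jugular`` the superior
    vena cava pressure, defaulting to the cvp minus the heart-jugular
    column. Supine this reduces to Davson's ``R_csf I_f + cvp``.
    """
    sin_a = math.sin(alpha)
    g_per_m = hydrostatic_mmhg(1.0, 1.0)  # mmHg per (kg/m^3 * m)
    if p_jugular is None:
        p_jugular = cvp + params.rho * g_per_m * params.z_jugular * sin_a
    return _icp(cvp, p_jugular, sin_a, params.davson_offset, params.z_dural,
                params.z_jugular, params.rho, g_per_m)
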