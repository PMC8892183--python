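"""Lumped (0D) systemic microvasculature and venous return.

Each compartment is a 3-element RLC Windkessel (arteriolar compartments are
RLCR, with the terminal characteristic impedance as a series resistance):
a compliance C stores volume against the local extravascular pressure, and
the outflow obeys a resistive-inertial momentum balance with an in-series
hydrostatic generator (Stevino's law) representing the blood column of the
compartment when the body is tilted::

    C d(p - p_ext)/dt = Q_in - Q_out
    L dQ_out/dt       = p - p_down - R Q_out + dp_h
    V                 = V_u + C (p - p_ext)        (linear compartments)

Working units are mmHg, ml, s. Microvascular compartments (arterioles,
capillaries, venules) describe spatially confined districts and carry no
hydrostatic column; veins and venae cavae carry the full regional heights.

The legs venous compartment uses a saturating (arctangent) pressure-volume
law to represent the non-linear distension of dependent veins under
orthostatic load; venous valves on the legs->abdominal-cava and
arms->superior-cava links are non-ideal diodes with a graded opening state.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from numba import njit

from .units import G_STANDARD, PA_TO_MMHG, hydrostatic_mmhg


@dataclass
class CompartmentState:
    p: float      # mmHg at compartment inlet
    Q_out: float  # ml/s leaving the compartment
    V: float      # ml


@dataclass(frozen=True)
class HydrostaticColumn:
    rho: float                # kg/m^3
    anatomical_height: float  # m, >= 0
    alpha: float              # rad

    def __post_init__(self):
        if self.anatomical_height < 0:
            raise ValueError("anatomical_height must be >= 0")


def hydrostatic_gradient(col: HydrostaticColumn) -> float:
    """Hydrostatic pressure difference across the column, mmHg.

    Stevino's law: rho * g * h * sin(alpha), converted to mmHg.
    """
    return hydrostatic_mmhg(col.rho, col.anatomical_height,
                            math.sin(col.alpha))


def compartment_rates(state: CompartmentState, Q_in: float, R: float,
                      L: float, C: float, p_downstream: float,
                      dp_ext_dt: float = 0.0, dp_h: float = 0.0):
    """Time derivatives (dp/dt, dQ_out/dt) of one RLC compartment.

    ``dp_h`` is the in-series hydrostatic generator on the outflow branch
    (positive when it assists the flow toward the downstream compartment).
    With zero inertance the momentum equation degenerates to the Ohmic
    relation and ``dQ_out/dt`` is returned as None (algebraic flow).
    """
    if C <= 0:
        raise ValueError("compliance must be positive")
    dp_dt = (Q_in - state.Q_out) / C + dp_ext_dt
    if L > 0:
        dq_dt = (state.p - p_downstream - R * state.Q_out + dp_h) / L
        return dp_dt, dq_dt
    return dp_dt, None


def ohmic_flow(p: float, p_downstream: float, R: float,
               dp_h: float = 0.0) -> float:
    """Algebraic outflow of an inertance-free compartment."""
    if R <= 0:
        raise ValueError("resistance must be positive for algebraic flow")
    return (p - p_downstream + dp_h) / R


# ----------------------------------------------------------------------------
# Non-linear leg-vein pressure-volume law
# ----------------------------------------------------------------------------

@dataclass(frozen=True)
class LegVeinLaw:
    """Saturating distension law of the legs venous compartment.

    V(p_tm) = V_u + (2 dV_max / pi) atan(pi C0 p_tm / (2 dV_max)) for
    p_tm >= 0, linear with slope C0 below zero. C1-continuous at p_tm = 0
    with local compliance C0; total distension saturates at dV_max.
    """

    C0: float          # ml/mmHg at zero transmural pressure
    deltaV_max: float  # ml
    V_u: float         # ml

    def __post_init__(self):
        if self.C0 <= 0 or self.deltaV_max <= 0:
            raise ValueError("C0 and deltaV_max must be positive")


@njit(cache=True)
def _legvein_v(p_tm, C0, dVmax, Vu):
    if p_tm >= 0.0:
        return Vu + (2.0 * dVmax / math.pi) * math.atan(
            math.pi * C0 * p_tm / (2.0 * dVmax))
    return Vu + C0 * p_tm


@njit(cache=True)
def _legvein_p(V, C0, dVmax, Vu):
    dv = V - Vu
    if dv >= 0.0:
        if dv >= dVmax:
            dv = dVmax * (1.0 - 1e-12)
        return (2.0 * dVmax / (math.pi * C0)) * math.tan(
            math.pi * dv / (2.0 * dVmax))
    return dv / C0


@njit(cache=True)
def _legvein_dVdp(p_tm, C0, dVmax):
    if p_tm >= 0.0:
        x = math.pi * C0 * p_tm / (2.0 * dVmax)
        return C0 / (1.0 + x * x)
    return C0


def leg_vein_volume(p_tm: float, law: LegVeinLaw) -> float:
    """Volume (ml) at transmural pressure ``p_tm`` (mmHg)."""
    return _legvein_v(p_tm, law.C0, law.deltaV_max, law.V_u)


def leg_vein_pressure(V: float, law: LegVeinLaw) -> float:
    """Inverse law: transmural pressure (mmHg) at volume ``V`` (ml)."""
    return _legvein_p(V, law.C0, law.deltaV_max, law.V_u)


def leg_vein_compliance(p_tm: float, law: LegVeinLaw) -> float:
    """Local compliance dV/dp (ml/mmHg) at ``p_tm``."""
    return _legvein_dVdp(p_tm, law.C0, law.deltaV_max)


# ----------------------------------------------------------------------------
# Venous valves (non-ideal diodes with graded opening state)
# ----------------------------------------------------------------------------

@dataclass
class VenousValveState:
    zeta: float  # opening state in [0, 1]
    Q: float     # ml/s

    def __post_init__(self):
        if not 0.0 <= self.zeta <= 1.0:
            raise ValueError("zeta must lie in [0, 1]")


@dataclass(frozen=True)
class ValveParams:
    """Diode parameters; areas in cm^2, pressures mmHg, flows ml/s.

    The Bernoulli resistance is B(zeta) = rho / (2 A_eff^2) with
    A_eff = A_min + zeta (A_max - A_min); A_min > 0 leaves a small leak so
    the diode is non-ideal (A_min = 0 allowed for cardiac valves).
    """

    A_max: float              # cm^2
    A_min: float = 0.0        # cm^2
    K_open: float = 40.0      # 1/(mmHg s)
    K_close: float = 100.0    # 1/(mmHg s)
    dp_open: float = 0.0      # mmHg
    dp_close: float = 0.0     # mmHg
    R_visc: float = 0.0       # mmHg s/ml
    inertance: float = 5e-5   # mmHg s^2/ml
    rho: float = 1050.0

    def __post_init__(self):
        if self.A_max <= self.A_min or self.A_min < 0:
            raise ValueError("need A_max > A_min >= 0")


@njit(cache=True)
def _valve_zeta_update(zeta, dp, K_open, K_close, dp_open, dp_close, dt):
    """Exact exponential update of d(zeta)/dt = (1-zeta)ko' - zeta kc'."""
    ko = K_open * (dp - dp_open) if dp > dp_open else 0.0
    kc = K_close * (dp_close - dp) if dp < dp_close else 0.0
    b = ko + kc
    if b <= 0.0:
        return zeta
    target = ko / b
    z = target + (zeta - target) * math.exp(-b * dt)
    if z < 1e-6:
        z = 0.0
    elif z > 1.0:
        z = 1.0
    return z


@njit(cache=True)
def _valve_bernoulli_B(zeta, A_max_cm2, A_min_cm2, rho):
    """B (mmHg/(ml/s)^2): rho/(2 A_eff^2) unit-converted, cm^2 and ml/s."""
    A_eff = (A_min_cm2 + zeta * (A_max_cm2 - A_min_cm2)) * 1e-4  # m^2
    if A_eff <= 1e-9:
        return -1.0  # marker: fully sealed (area below 1e-5 cm^2)
    return rho / (2.0 * A_eff * A_eff) * 1e-12 * PA_TO_MMHG


@njit(cache=True)
def _valve_q_implicit(q, dp, zeta, A_max, A_min, R_visc, L, rho, dt):
    """Backward-Euler update of L dQ/dt = dp - B Q|Q| - R Q.

    The quadratic orifice term is stiff whenever the effective area is
    small; the implicit update has a closed-form root and is stable for any
    dt. Returns the new flow (0 if the valve is sealed).
    """
    B = _valve_bernoulli_B(zeta, A_max, A_min, rho)
    if B < 0.0:
        return 0.0
    rhs = q + dt / L * dp
    bcoef = 1.0 + R_visc * dt / L
    a = B * dt / L
    if a == 0.0:
        return rhs / bcoef
    m = abs(rhs)
    qn = (-bcoef + math.sqrt(bcoef * bcoef + 4.0 * a * m)) / (2.0 * a)
    return qn if rhs >= 0.0 else -qn


@njit(cache=True)
def _valve_flow_rate(dp, Q, zeta, A_max, A_min, R_visc, L, rho):
    """dQ/dt from L dQ/dt = dp - B Q|Q| - R_visc Q; (dQ/dt, forced_zero)."""
    B = _valve_bernoulli_B(zeta, A_max, A_min, rho)
    if B < 0.0:
        return 0.0, True
    return (dp - B * Q * abs(Q) - R_visc * Q) / L, False


def venous_valve_step(vs: VenousValveState, dp: float, params: ValveParams,
                      dt: float) -> VenousValveState:
    """Advance opening state and flow of a venous valve by one step ``dt``.

    Opening dynamics follow the graded-diode rate law; the flow obeys the
    Bernoulli orifice relation with inertance. Both use unconditionally
    stable updates (exact exponential for the opening state, backward Euler
    with a closed-form root for the stiff quadratic flow equation).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    z = _valve_zeta_update(vs.zeta, dp, params.K_open, params.K_close,
                           params.dp_open, params.dp_close, dt)
    q = _valve_q_implicit(vs.Q, dp, z, params.A_max, params.A_min,
                          params.R_visc, params.inertance, params.rho, dt)
    return VenousValveState(zeta=z, Q=q)


def valve_steady_flow(dp: float, zeta: float, params: ValveParams) -> float:
    """Steady orifice flow at opening ``zeta``: solves dp = B Q|Q| + R Q."""
    B = _valve_bernoulli_B(zeta, params.A_max, params.A_min, params.rho)
    if B < 0.0:
        return 0.0
    R = params.R_visc
    s = 1.0 if dp >= 0 else -1.0
    m = abs(dp)
    if B == 0.0:
        return s * m / R if R > 0 else 0.0
    if R == 0.0:
        return s * math.sqrt(m / B)
    return s * (-R + math.sqrt(R * R + 4.0 * B * m)) / (2.0 * B)
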