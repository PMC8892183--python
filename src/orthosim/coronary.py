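"""Multiscale coronary circulation: 0D three-layer intramyocardial beds.

Downstream of the 1D coronary vessels, each microcirculatory district is
split into three parallel branches perfusing the subepicardial (SEP),
midwall (MW) and subendocardial (SEN) layers of the ventricular muscle.
Every branch chains an arterial, an intermediate and a venous compliant
compartment (input/output impedances Z_a, Z_v and intra-layer resistances),
whose compliances are referenced to the intramyocardial pressure: a fixed
fraction of the cavity pressure, growing from the subepicardium to the
subendocardium. Systolic compression of the deeper layers is what makes
left-coronary inflow diastole-dominant.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LAYERS = ("subepicardium", "midwall", "subendocardium")
DEFAULT_LAYER_WEIGHTS = {"subepicardium": 1.0 / 6.0,
                         "midwall": 0.5,
                         "subendocardium": 5.0 / 6.0}


@dataclass(frozen=True)
class CoronaryDistrict:
    """Parameters of one three-layer microcirculatory district.

    Resistances mmHg*s/ml, compliances ml/mmHg. ``Z_a``/``Z_v`` are the
    per-layer input/output impedances, ``R_c1``/``R_c2`` the intra-layer
    resistances, ``C_a``/``C_c``/``C_v`` the arterial, intermediate and
    venous layer compliances. ``cavity`` names the pressure source of the
    intramyocardial compression ('lv' or 'rv').
    """

    Z_a: float
    R_c1: float
    R_c2: float
    Z_v: float
    C_a: float
    C_c: float
    C_v: float
    cavity: str = "lv"
    layer_weights: dict = field(
        default_factory=lambda: dict(DEFAULT_LAYER_WEIGHTS))

    def __post_init__(self):
        for name in ("Z_a", "R_c1", "R_c2", "Z_v", "C_a", "C_c", "C_v"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        w = [self.layer_weights[k] for k in LAYERS]
        if not w[0] < w[1] < w[2]:
            raise ValueError("layer weights must increase from subepicardium "
                             "to subendocardium")


def intramyocardial_pressure(p_cavity: float, layer: str,
                             weights: dict | None = None) -> float:
    """Intramyocardial pressure of one layer: w_layer * cavity pressure."""
    w = (weights or DEFAULT_LAYER_WEIGHTS)[layer]
    return w * p_cavity


def district_rates(V_a: np.ndarray, V_c: np.ndarray, V_v: np.ndarray,
                   spec: CoronaryDistrict, p_in: float, p_out: float,
                   p_cavity: float, Vu_a=0.0, Vu_c=0.0, Vu_v=0.0):
    """Volume rates of the 3x3 layer compartments and the layer flows.

    States are per-layer volumes (arterial, intermediate, venous). The layer
    pressures are ``p = (V - Vu)/C + p_im`` and flows follow the resistive
    chain ``p_in -Z_a-> p_a -R_c1-> p_c -R_c2-> p_v -Z_v-> p_out``. Returns
    ``(dVa, dVc, dVv, Q_in_layers, Q_out_layers)``.
    """
    w = np.array([spec.layer_weights[k] for k in LAYERS])
    p_im = w * p_cavity
    p_a = (V_a - Vu_a) / spec.C_a + p_im
    p_c = (V_c - Vu_c) / spec.C_c + p_im
    p_v = (V_v - Vu_v) / spec.C_v + p_im
    q_in = (p_in - p_a) / spec.Z_a
    q_ac = (p_a - p_c) / spec.R_c1
    q_cv = (p_c - p_v) / spec.R_c2
    q_out = (p_v - p_out) / spec.Z_v
    return q_in - q_ac, q_ac - q_cv, q_cv - q_out, q_in, q_out
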