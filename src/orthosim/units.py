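"""Unit conversion helpers.

Internally the 1D solver works in SI (m, m^2, m^3/s, Pa) while the lumped
circulation, heart and all clinical outputs use mmHg / ml / s, the customary
units of hemodynamics. Conversions are centralized here so a single constant
(1 mmHg = 133.322 Pa) is used everywhere.
"""

MMHG_TO_PA = 133.322
PA_TO_MMHG = 1.0 / MMHG_TO_PA

ML_TO_M3 = 1.0e-6
M3_TO_ML = 1.0e6

G_STANDARD = 9.81  # m/s^2


def pa_to_mmhg(p_pa: float) -> float:
    return p_pa * PA_TO_MMHG


def mmhg_to_pa(p_mmhg: float) -> float:
    return p_mmhg * MMHG_TO_PA


def mlps_to_m3ps(q: float) -> float:
    return q * ML_TO_M3


def m3ps_to_mlps(q: float) -> float:
    return q * M3_TO_ML


def hydrostatic_mmhg(rho: float, height_m: float, sin_alpha: float = 1.0,
                     g: float = G_STANDARD) -> float:
    """Hydrostatic pressure of a blood column, in mmHg (Stevino's law)."""
    return rho * g * height_m * sin_alpha * PA_TO_MMHG
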