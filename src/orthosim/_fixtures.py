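"""Small fully-parameterized verification fixtures.

``single_vessel`` and ``symmetric_bifurcation`` are bare 1D configurations
(grids + rest states) for wave-propagation oracles; ``minimal_closed_loop``
is a complete, valid NetworkModel (heart + one artery + one lumped chain)
small enough for fast closed-loop checks.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .arterial_1d import VesselGrid, beta_from_wave_speed


RHO = 1050.0


def _grid(length=0.4, radius=0.01, c0=6.0, n_elements=16, **kw):
    import math
    A0 = math.pi * radius * radius
    beta = beta_from_wave_speed(c0, A0, RHO)
    return VesselGrid(length=length, n_elements=n_elements,
                      A0_prox=A0, A0_dist=A0,
                      beta_prox=beta, beta_dist=beta, rho=RHO, **kw)


@dataclass
class OneDFixture:
    """A handful of vessel grids with topology metadata (no 0D side)."""

    vessels: dict
    compartments: dict = field(default_factory=dict)
    topology: dict = field(default_factory=dict)


def single_vessel(n_elements: int = 16) -> OneDFixture:
    """One uniform vessel; ends may be driven reflective or absorbing."""
    return OneDFixture(vessels={1: _grid(n_elements=n_elements)})


def symmetric_bifurcation() -> OneDFixture:
    """A parent splitting into two identical children."""
    parent = _grid(length=0.3, radius=0.012, c0=5.5, n_elements=12)
    child_kw = dict(length=0.25, radius=0.0085, c0=6.5, n_elements=10)
    return OneDFixture(
        vessels={1: parent, 2: _grid(**child_kw), 3: _grid(**child_kw)},
        topology={1: [2, 3]})


def minimal_closed_loop():
    """Heart + single artery + one arteriole-to-vena-cava chain."""
    from .network import load_network
    doc = dict(
        model_version=1,
        name="minimal_closed_loop",
        blood=dict(density=RHO, viscosity=0.004, total_volume=5700.0),
        numerics=dict(dx=0.05, cfl_safety=0.5, output_dt=0.004,
                      p_init_1d=80.0),
        vessels=[dict(id=1, name="aorta", length=0.4, r_prox=0.012,
                      r_dist=0.010, c0=5.0, z_prox=0.0, parent=None,
                      terminal_bed="upper_abdomen", gamma_visc=0.0,
                      **{"lambda": 0.9})],
        compartments=[
            dict(id="art", kind="arteriole", region="upper_abdomen",
                 R=0.55, C=0.8, z=0.36, volume_fraction=0.03, p_init=85.0,
                 downstream="cap", terminal_of=1),
            dict(id="cap", kind="capillary", region="upper_abdomen",
                 R=0.12, C=2.0, z=0.36, volume_fraction=0.07, p_init=25.0,
                 downstream="venule"),
            dict(id="venule", kind="venule", region="upper_abdomen",
                 R=0.045, C=8.0, z=0.36, volume_fraction=0.13, p_init=13.0,
                 downstream="vein"),
            dict(id="vein", kind="vein", region="upper_abdomen",
                 R=0.025, C=25.0, z=0.20, height=0.16, p_init=9.0,
                 volume_fraction=0.47, downstream="ivc"),
            dict(id="ivc", kind="vena_cava_inferior", region="thorax",
                 R=0.004, C=2.5, z=0.05, height=0.15, p_init=7.3,
                 volume_fraction=0.09, downstream="ra",
                 extravascular="intrathoracic"),
            dict(id="pa", kind="pulmonary_artery", region="thorax",
                 R=0.045, C=4.0, z=0.0, p_init=15.0, volume_fraction=0.045,
                 downstream="pv", extravascular="intrathoracic"),
            dict(id="pv", kind="pulmonary_vein", region="thorax",
                 R=0.018, C=7.0, z=0.0, p_init=9.0, volume_fraction=0.085,
                 downstream="la", extravascular="intrathoracic"),
        ],
        chambers=dict(
            ra=dict(E_max=0.25, E_min=0.12, V_u=10.0, kind="atrium",
                    onset=0.85, duration=0.16, volume_fraction=0.012),
            rv=dict(E_max=0.65, E_min=0.045, V_u=18.0, kind="ventricle",
                    onset=0.0, volume_fraction=0.028),
            la=dict(E_max=0.45, E_min=0.22, V_u=8.0, kind="atrium",
                    onset=0.85, duration=0.16, volume_fraction=0.012),
            lv=dict(E_max=3.0, E_min=0.08, V_u=15.0, kind="ventricle",
                    onset=0.0, volume_fraction=0.028),
        ),
        cardiac_valves=dict(
            aortic={"from": "lv", "to": "root", "A_max": 4.0,
                    "K_open": 60.0, "K_close": 60.0, "R_visc": 0.003,
                    "L": 3.0e-4},
            mitral={"from": "la", "to": "lv", "A_max": 5.0, "K_open": 60.0,
                    "K_close": 60.0, "R_visc": 0.0025, "L": 2.5e-4},
            pulmonic={"from": "rv", "to": "pa", "A_max": 4.5,
                      "K_open": 60.0, "K_close": 60.0, "R_visc": 0.0025,
                      "L": 2.5e-4},
            tricuspid={"from": "ra", "to": "rv", "A_max": 6.0,
                       "K_open": 60.0, "K_close": 60.0, "R_visc": 0.002,
                       "L": 2.0e-4},
        ),
        regulation=dict(effectors=dict(hr=dict(basal=66.0))),
        coronary=dict(enabled=False),
        intrathoracic=dict(p_supine=-4.0, delta=3.0),
        sites=dict(aortic_arch=dict(vessel=1, s=0.1),
                   carotid_sinus=dict(vessel=1, s=0.1)),
    )
    return load_network(doc)
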