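"""Flatten a validated NetworkModel into the kernel's array representation.

The compiled object owns every state and structure array the time stepper
needs, plus name->index maps used by the runner and the analysis layer to
address compartments, chambers, links and measurement sites.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..heart import _vent_shape_peak, SYS_DUR_COEFF, SYS_DUR_EXP
from ..network import NetworkModel, distribute_blood_volume
from ..units import MMHG_TO_PA, G_STANDARD
from . import kernel as K

CHAMBER_ORDER = ("ra", "rv", "la", "lv")
CORONARY_LAYERS = ("sep", "mw", "sen")
DEFAULT_LAYER_W = (1.0 / 6.0, 0.5, 5.0 / 6.0)


@dataclass
class CompiledSim:
    model: NetworkModel
    dt: float
    out_every: int
    output_dt: float

    # 1D
    nel: np.ndarray
    elstart: np.ndarray
    h: np.ndarray
    lam: np.ndarray
    gvisc: np.ndarray
    A0n: np.ndarray
    bn: np.ndarray
    dbdx: np.ndarray
    dpsidx: np.ndarray
    prefv: np.ndarray
    jvessel: np.ndarray
    jnch: np.ndarray
    jchild: np.ndarray
    tvessel: np.ndarray
    tcomp: np.ndarray
    tZc: np.ndarray
    tdz: np.ndarray
    thead: np.ndarray
    vessel_index: dict

    # 0D
    comp_kind: np.ndarray
    comp_C: np.ndarray
    comp_Vu: np.ndarray
    comp_ext: np.ndarray
    comp_pimw: np.ndarray
    comp_tone: np.ndarray
    comp_names: list
    comp_index: dict
    ihead_art: int
    ilegvein: int
    lv_C0: float
    lv_dVmax: float
    ch_idx: np.ndarray
    ch_Emax: np.ndarray
    ch_Emin: np.ndarray
    ch_Vu: np.ndarray
    ch_isvent: np.ndarray
    ch_onset: np.ndarray
    ch_dur: np.ndarray
    ch_ectrl: np.ndarray
    i_lv: int
    i_ra: int
    i_svc: int
    iav_link: int
    lup: np.ndarray
    ldn: np.ndarray
    lR: np.ndarray
    lL: np.ndarray
    lGh: np.ndarray
    lvalve: np.ndarray
    lrctrl: np.ndarray
    link_names: list
    vAmax: np.ndarray
    vAmin: np.ndarray
    vKo: np.ndarray
    vKc: np.ndarray
    vdpo: np.ndarray
    vdpc: np.ndarray
    vRv: np.ndarray
    vLv: np.ndarray
    valve_names: list

    site_node: np.ndarray
    site_vessel: np.ndarray
    site_names: list

    P: np.ndarray

    # mutable state
    A: np.ndarray = None
    Q: np.ndarray = None
    V: np.ndarray = None
    Ql: np.ndarray = None
    zeta: np.ndarray = None
    S: np.ndarray = None
    dAprev: np.ndarray = None

    def total_volume(self) -> float:
        """Blood volume over all domains (ml): 1D integral + 0D + chambers."""
        v1d = 0.0
        for iv in range(len(self.nel)):
            n0 = 2 * self.elstart[iv]
            for e in range(self.nel[iv]):
                a1 = self.A[n0 + 2 * e]
                a2 = self.A[n0 + 2 * e + 1]
                v1d += 0.5 * (a1 + a2) * self.h[iv]
        return v1d * 1e6 + float(np.sum(self.V))

    def node_pressures_mmhg(self) -> np.ndarray:
        return (self.bn * (np.sqrt(self.A) - np.sqrt(self.A0n))) / MMHG_TO_PA


def _resolve_site(model, sim_nel, sim_elstart, vessel_index, spec):
    """Map a fractional site to the first node of its element; recorded
    site values are element means (the conserved P1 quantity)."""
    iv = vessel_index[spec["vessel"]]
    nel = sim_nel[iv]
    s = float(spec["s"])
    e_local = min(max(int(s * nel), 0), nel - 1)
    return 2 * (sim_elstart[iv] + e_local), iv


def compile_model(model: NetworkModel, mode: str = "reduced",
                  tilt: dict | None = None) -> CompiledSim:
    """Build the flat array representation and the initial state.

    ``mode`` selects the spatial resolution of the 1D grid: 'reduced'
    (coarse, desk-scale runs) or 'full' (halved element size).
    """
    rho = model.blood_density
    mu = model.blood_viscosity
    nu = mu / rho
    num = model.numerics
    dx = float(num.get("dx", 0.05))
    if mode == "full":
        dx = dx / 2.0
    chi = float(num.get("chi", 1.1))
    cfl_safety = float(num.get("cfl_safety", 0.5))
    output_dt = float(num.get("output_dt", 0.004))
    p_init_1d = float(num.get("p_init_1d", 80.0)) * MMHG_TO_PA

    # ---- vessel ordering: root first, then by id
    root = model.root_vessel
    order = [root.id] + sorted(v for v in model.vessels if v != root.id)
    vessel_index = {vid: i for i, vid in enumerate(order)}
    nv = len(order)
    nel = np.zeros(nv, dtype=np.int64)
    h = np.zeros(nv)
    lam = np.zeros(nv)
    gvisc = np.zeros(nv)
    prefv = np.zeros(nv)
    for vid, i in vessel_index.items():
        v = model.vessels[vid]
        nel[i] = max(2, int(round(v.length / dx)))
        h[i] = v.length / nel[i]
        lam[i] = v.longitudinal_projection
        gvisc[i] = v.viscoelastic_coeff
    elstart = np.zeros(nv, dtype=np.int64)
    elstart[1:] = np.cumsum(nel)[:-1]
    ntot_el = int(np.sum(nel))
    NN = 2 * ntot_el
    A0n = np.zeros(NN)
    bn = np.zeros(NN)
    dbdx = np.zeros(ntot_el)
    dpsidx = np.zeros(ntot_el)
    for vid, i in vessel_index.items():
        v = model.vessels[vid]
        ne = nel[i]
        for e in range(ne):
            for j, snode in enumerate((e / ne, (e + 1) / ne)):
                gnode = 2 * (elstart[i] + e) + j
                r = v.proximal_radius + (v.distal_radius
                                         - v.proximal_radius) * snode
                A0 = math.pi * r * r
                A0n[gnode] = A0
                # per-vessel beta refers to the distal reference area; the
                # local b = beta/A0 keeps the distal wave speed at c0 and
                # stiffens the narrow end of tapered segments
                bn[gnode] = v.wall_stiffness_beta / A0
        for e in range(ne):
            g1 = 2 * (elstart[i] + e)
            g2 = g1 + 1
            dbdx[elstart[i] + e] = (bn[g2] - bn[g1]) / h[i]
            psi1 = bn[g1] * math.sqrt(A0n[g1])
            psi2 = bn[g2] * math.sqrt(A0n[g2])
            dpsidx[elstart[i] + e] = (psi2 - psi1) / h[i]

    # junctions & terminals
    jlist = [(vessel_index[v.id],
              [vessel_index[c] for c in v.child_ids])
             for v in model.vessels.values() if v.child_ids]
    jlist.sort()
    jvessel = np.array([j[0] for j in jlist], dtype=np.int64)
    jnch = np.array([len(j[1]) for j in jlist], dtype=np.int64)
    maxch = max((len(j[1]) for j in jlist), default=1)
    jchild = np.zeros((max(len(jlist), 1), maxch), dtype=np.int64)
    for k, (_, ch) in enumerate(jlist):
        for m, c in enumerate(ch):
            jchild[k, m] = c

    # ---- 0D state ordering: compartments (config order), coronary layers,
    # then chambers
    comp_names = list(model.compartments.keys())
    coronary_on = bool(model.coronary.get("enabled", True)) \
        and model.coronary
    layer_names = []
    if coronary_on:
        for lay in CORONARY_LAYERS:
            for part in ("a", "c", "v"):
                layer_names.append(f"cor_{lay}_{part}")
    state_names = comp_names + layer_names + list(CHAMBER_ORDER)
    comp_index = {n: i for i, n in enumerate(state_names)}
    nstate = len(state_names)

    comp_kind = np.zeros(nstate, dtype=np.int64)
    comp_C = np.ones(nstate)
    comp_Vu = np.zeros(nstate)
    comp_ext = np.zeros(nstate, dtype=np.int64)
    comp_pimw = np.zeros(nstate)
    comp_tone = np.zeros(nstate, dtype=np.int64)
    ch_idx = np.zeros(nstate, dtype=np.int64)

    ilegvein = -1
    ihead_art = -1
    lv_C0 = 1.0
    lv_dVmax = 1.0
    p_init = np.zeros(nstate)

    for name in comp_names:
        c = model.compartments[name]
        i = comp_index[name]
        comp_C[i] = c.compliance
        comp_ext[i] = {"ambient": K.E_AMBIENT,
                       "intrathoracic": K.E_THORAX,
                       "intracranial": K.E_ICP,
                       "intramyocardial": K.E_IM}[c.extravascular_source]
        p_init[i] = c.p_init
        if c.nonlinear_law:
            comp_kind[i] = K.K_LEGVEIN
            ilegvein = i
            lv_C0 = c.compliance
            lv_dVmax = float(c.nonlinear_law["deltaV_max"])
        if c.kind == "vein" and c.region in (
                "head", "arms", "upper_abdomen", "lower_abdomen", "legs"):
            comp_tone[i] = 1
        if c.kind == "arteriole" and c.region == "head":
            ihead_art = i

    cor = model.coronary if coronary_on else {}
    if coronary_on:
        w = cor.get("layer_weights", list(DEFAULT_LAYER_W))
        pc_init = cor.get("p_init", [80.0, 40.0, 15.0])
        Cs = {"a": float(cor.get("C_a", 0.006)),
              "c": float(cor.get("C_c", 0.02)),
              "v": float(cor.get("C_v", 0.05))}
        for li, lay in enumerate(CORONARY_LAYERS):
            for pi, part in enumerate(("a", "c", "v")):
                i = comp_index[f"cor_{lay}_{part}"]
                comp_C[i] = Cs[part]
                comp_ext[i] = K.E_IM
                comp_pimw[i] = w[li]
                p_init[i] = pc_init[pi]

    ch_Emax = np.zeros(4)
    ch_Emin = np.zeros(4)
    ch_Vu = np.zeros(4)
    ch_isvent = np.zeros(4, dtype=np.int64)
    ch_onset = np.zeros(4)
    ch_dur = np.zeros(4)
    ch_ectrl = np.zeros(4, dtype=np.int64)
    for k, name in enumerate(CHAMBER_ORDER):
        cd = model.chambers[name]
        i = comp_index[name]
        comp_kind[i] = K.K_CHAMBER
        ch_idx[i] = k
        ch_Emax[k] = cd["E_max"]
        ch_Emin[k] = cd["E_min"]
        ch_Vu[k] = cd["V_u"]
        ch_isvent[k] = 1 if cd.get("kind", "ventricle") == "ventricle" else 0
        ch_onset[k] = cd.get("onset", 0.0)
        ch_dur[k] = cd.get("duration", 0.18)
        ch_ectrl[k] = 1 if ch_isvent[k] == 1 else 0
    i_lv = comp_index["lv"]
    i_ra = comp_index["ra"]
    i_svc = comp_index.get("svc", i_ra)

    # ---- links
    zmap = {}
    for name in comp_names:
        zmap[name] = model.compartments[name].z_node
    for name in layer_names:
        zmap[name] = model.coronary.get("z_node", 0.0)
    for name in CHAMBER_ORDER:
        zmap[name] = 0.0

    g_per = rho * G_STANDARD / MMHG_TO_PA  # mmHg per m of column

    links = []       # (name, up, dn, R, L, Gh, valve_name, rctrl)
    valve_names = list(model.cardiac_valves.keys()) + \
        list(model.venous_valves.keys())
    valve_index = {n: i for i, n in enumerate(valve_names)}

    def add_link(name, up, dn, R, L, valve=None, rctrl=0):
        zu = zmap[up]
        zd = zmap[dn] if dn is not None else \
            model.vessels[model.root_vessel.id].z_prox
        Gh = g_per * (zd - zu)
        iu = comp_index[up]
        idn = comp_index[dn] if dn is not None else -1
        links.append((name, iu, idn, R, L, Gh,
                      valve_index[valve] if valve else -1, rctrl))

    for name in comp_names:
        c = model.compartments[name]
        if coronary_on and name == "cor_art":
            continue  # rerouted through the coronary layers below
        dn = c.downstream
        rctrl = 0
        # baroreflex raises arteriolar and capillary resistance of the
        # peripheral beds; cerebral arterioles follow autoregulation instead
        if c.kind in ("arteriole", "capillary") and c.region in (
                "arms", "upper_abdomen", "lower_abdomen", "legs"):
            rctrl = 1
        elif c.kind == "arteriole" and c.region == "head":
            rctrl = 2
        L = c.inertance if c.inertance > 0 else max(2e-4, 1.5e-3
                                                    * c.resistance)
        add_link(f"{name}->{dn}", name, dn, c.resistance, L,
                 valve=c.valve, rctrl=rctrl)

    if coronary_on:
        nlay = len(CORONARY_LAYERS)
        Za = float(cor.get("Z_a", 6.0)) * nlay
        Rc1 = float(cor.get("R_c1", 9.0)) * nlay
        Rc2 = float(cor.get("R_c2", 6.0)) * nlay
        Zv = float(cor.get("Z_v", 3.0)) * nlay
        for lay in CORONARY_LAYERS:
            add_link(f"cor_art->cor_{lay}_a", "cor_art", f"cor_{lay}_a",
                     Za, max(2e-4, 1.5e-3 * Za))
            add_link(f"cor_{lay}_a->c", f"cor_{lay}_a", f"cor_{lay}_c",
                     Rc1, max(2e-4, 1.5e-3 * Rc1))
            add_link(f"cor_{lay}_c->v", f"cor_{lay}_c", f"cor_{lay}_v",
                     Rc2, max(2e-4, 1.5e-3 * Rc2))
            add_link(f"cor_{lay}_v->cor_ven", f"cor_{lay}_v", "cor_ven",
                     Zv, max(2e-4, 1.5e-3 * Zv))

    # cardiac valve links
    iav_link = -1
    for vname, vd in model.cardiac_valves.items():
        frm = vd["from"]
        to = vd.get("to", None)
        dn = None if to in (None, "root") else to
        add_link(f"valve:{vname}", frm, dn, 0.0,
                 float(vd.get("L", 3e-4)), valve=vname)
        if dn is None:
            iav_link = len(links) - 1

    link_names = [l[0] for l in links]
    lup = np.array([l[1] for l in links], dtype=np.int64)
    ldn = np.array([l[2] for l in links], dtype=np.int64)
    lR = np.array([l[3] for l in links])
    lL = np.array([l[4] for l in links])
    lGh = np.array([l[5] for l in links])
    lvalve = np.array([l[6] for l in links], dtype=np.int64)
    lrctrl = np.array([l[7] for l in links], dtype=np.int64)

    nvalve = len(valve_names)
    vAmax = np.zeros(nvalve)
    vAmin = np.zeros(nvalve)
    vKo = np.zeros(nvalve)
    vKc = np.zeros(nvalve)
    vdpo = np.zeros(nvalve)
    vdpc = np.zeros(nvalve)
    vRv = np.zeros(nvalve)
    vLv = np.zeros(nvalve)
    allv = dict(model.cardiac_valves)
    allv.update(model.venous_valves)
    for vname, i in valve_index.items():
        vd = allv[vname]
        vAmax[i] = vd["A_max"]
        vAmin[i] = vd.get("A_min", 0.0)
        vKo[i] = vd.get("K_open", 40.0)
        vKc[i] = vd.get("K_close", 40.0)
        vdpo[i] = vd.get("dp_open", 0.0)
        vdpc[i] = vd.get("dp_close", 0.0)
        vRv[i] = vd.get("R_visc", 0.0)
        vLv[i] = vd.get("L", 3e-4)

    # terminals (after comp_index exists)
    tlist = []
    for v in model.terminal_vessels():
        art = [c for c in model.compartments.values()
               if c.terminal_of == v.id][0]
        iv = vessel_index[v.id]
        A0d = math.pi * v.distal_radius ** 2
        c0d = math.sqrt(v.wall_stiffness_beta / (2.0 * rho * A0d)) \
            * A0d ** 0.25
        Zc = model.raw.get("terminal_impedance_override", {}).get(
            str(v.id), rho * c0d / A0d)
        tdzv = v.z_dist - art.z_node
        ishead = 1 if art.region == "head" else 0
        tlist.append((iv, comp_index[art.id], Zc, tdzv, ishead))
    tvessel = np.array([t[0] for t in tlist], dtype=np.int64)
    tcomp = np.array([t[1] for t in tlist], dtype=np.int64)
    tZc = np.array([t[2] for t in tlist])
    tdz = np.array([t[3] for t in tlist])
    thead = np.array([t[4] for t in tlist], dtype=np.int64)

    # ---- sites (aortic arch and carotid sinus must come first)
    site_specs = dict(model.sites)
    ordered = ["aortic_arch", "carotid_sinus"] + \
        [s for s in site_specs if s not in ("aortic_arch", "carotid_sinus")]
    site_names = [s for s in ordered if s in site_specs]
    site_node = np.zeros(len(site_names), dtype=np.int64)
    site_vessel = np.zeros(len(site_names), dtype=np.int64)
    for k, sname in enumerate(site_names):
        site_node[k], site_vessel[k] = _resolve_site(
            model, nel, elstart, vessel_index, site_specs[sname])

    # ---- P parameter array
    reg = model.regulation
    eff = reg.get("effectors", {})
    aut = reg.get("autoreg", {})
    icp = model.icp
    it_p = model.intrathoracic
    tiltd = dict(model.tilt_default)
    if tilt:
        tiltd.update(tilt)

    P = np.zeros(K.P_LEN)
    P[K.P_NU] = reg.get("nu", 7.0)
    P[K.P_TAUAFF] = reg.get("tau_afferent", 2.0)
    P[K.P_NUCP] = reg.get("nu_cp", 2.0)
    hr = eff.get("hr", {})
    P[K.P_HRBAS] = hr.get("basal", 66.0)
    P[K.P_HRGS] = hr.get("gain_sym", 90.0)
    P[K.P_HRGP] = hr.get("gain_para", 50.0)
    P[K.P_HRTAU] = hr.get("tau", 2.0)
    P[K.P_HRLO] = hr.get("lo", 40.0)
    P[K.P_HRHI] = hr.get("hi", 180.0)
    em = eff.get("emax", {})
    P[K.P_EMAXG] = em.get("gain_sym", 1.4)
    P[K.P_EMAXTAU] = em.get("tau", 3.0)
    ra = eff.get("r_art", {})
    P[K.P_RARTG] = ra.get("gain_sym", 2.0)
    P[K.P_RARTGCP] = ra.get("gain_cp", 0.8)
    P[K.P_RARTTAU] = ra.get("tau", 4.0)
    vu = eff.get("venous_vu", {})
    P[K.P_VUG] = vu.get("gain_sym", 0.12)
    P[K.P_VUGCP] = vu.get("gain_cp", 0.06)
    P[K.P_VUTAU] = vu.get("tau", 8.0)
    cv = eff.get("venous_c", {})
    P[K.P_CVENG] = cv.get("gain_sym", 0.15)
    P[K.P_CVENGCP] = cv.get("gain_cp", 0.08)
    P[K.P_CVENTAU] = cv.get("tau", 8.0)
    P[K.P_AUTG] = aut.get("gain", 8.0)
    P[K.P_AUTTAU] = aut.get("tau", 8.0)
    P[K.P_AUTAMPD] = aut.get("amp_dilation", 2.2)
    P[K.P_AUTAMPC] = aut.get("amp_constriction", 0.6)
    P[K.P_ICPOFF] = icp.get("R_csf_If", 3.2)
    P[K.P_ZDURAL] = icp.get("z_dural", -0.23)
    P[K.P_ZJUG] = icp.get("z_jugular", -0.10)
    P[K.P_PITSUP] = it_p.get("p_supine", -4.0)
    P[K.P_PITDELTA] = it_p.get("delta", 3.0)
    P[K.P_RHO] = rho
    P[K.P_GRAV] = G_STANDARD
    P[K.P_A0TILT] = 0.0
    P[K.P_A1TILT] = 0.0
    P[K.P_TSTART] = 1e30
    P[K.P_TRAMP] = 1.0
    P[K.P_SHAPE] = 0.0
    P[K.P_SCLO] = reg.get("scale_lo", 0.3)
    P[K.P_SCHI] = reg.get("scale_hi", 3.0)
    P[K.P_TAUCBF] = aut.get("tau_cbf", 3.0)
    P[K.P_CAN] = aut.get("C_n", 0.15)
    P[K.P_CHI] = chi
    P[K.P_NUKIN] = nu
    P[K.P_SYSK] = model.chambers.get("lv", {}).get("sys_dur_coeff",
                                                   SYS_DUR_COEFF)
    P[K.P_SYSEXP] = model.chambers.get("lv", {}).get("sys_dur_exp",
                                                     SYS_DUR_EXP)

    # ---- time step from the CFL bound (estimate at elevated pressure)
    dtv = []
    for vid, i in vessel_index.items():
        v = model.vessels[vid]
        A0d = math.pi * v.distal_radius ** 2
        c0 = math.sqrt(v.wall_stiffness_beta / (2.0 * rho * A0d)) \
            * A0d ** 0.25
        cmax = math.sqrt(c0 * c0 + 25000.0 / (2.0 * rho)) + 1.5
        dtv.append(h[i] / (3.0 * cmax))
    dt = cfl_safety * min(dtv)
    dt_cfg = num.get("dt")
    if dt_cfg:
        dt = float(dt_cfg)
    out_every = max(1, int(round(output_dt / dt)))

    sim = CompiledSim(
        model=model, dt=dt, out_every=out_every, output_dt=out_every * dt,
        nel=nel, elstart=elstart, h=h, lam=lam, gvisc=gvisc,
        A0n=A0n, bn=bn, dbdx=dbdx, dpsidx=dpsidx, prefv=prefv,
        jvessel=jvessel, jnch=jnch, jchild=jchild,
        tvessel=tvessel, tcomp=tcomp, tZc=tZc, tdz=tdz, thead=thead,
        vessel_index=vessel_index,
        comp_kind=comp_kind, comp_C=comp_C, comp_Vu=comp_Vu,
        comp_ext=comp_ext, comp_pimw=comp_pimw, comp_tone=comp_tone,
        comp_names=state_names, comp_index=comp_index,
        ihead_art=ihead_art, ilegvein=ilegvein,
        lv_C0=lv_C0, lv_dVmax=lv_dVmax,
        ch_idx=ch_idx, ch_Emax=ch_Emax, ch_Emin=ch_Emin, ch_Vu=ch_Vu,
        ch_isvent=ch_isvent, ch_onset=ch_onset, ch_dur=ch_dur,
        ch_ectrl=ch_ectrl, i_lv=i_lv, i_ra=i_ra, i_svc=i_svc,
        iav_link=iav_link,
        lup=lup, ldn=ldn, lR=lR, lL=lL, lGh=lGh, lvalve=lvalve,
        lrctrl=lrctrl, link_names=link_names,
        vAmax=vAmax, vAmin=vAmin, vKo=vKo, vKc=vKc, vdpo=vdpo, vdpc=vdpc,
        vRv=vRv, vLv=vLv, valve_names=valve_names,
        site_node=site_node, site_vessel=site_vessel, site_names=site_names,
        P=P,
    )
    _initialize_state(sim, p_init, p_init_1d)
    return sim


def _initialize_state(sim: CompiledSim, p_init: np.ndarray,
                      p_init_1d: float):
    model = sim.model
    NN = sim.A0n.shape[0]
    nstate = len(sim.comp_names)
    sim.A = (np.sqrt(sim.A0n) + p_init_1d / sim.bn) ** 2
    sim.Q = np.zeros(NN)
    sim.dAprev = np.zeros(NN)
    sim.Ql = np.zeros(len(sim.lup))
    sim.zeta = np.zeros(len(sim.valve_names))
    for vname in model.venous_valves:
        sim.zeta[sim.valve_names.index(vname)] = 1.0
    for vname, vd in model.cardiac_valves.items():
        if vd["from"] in ("ra", "la"):
            sim.zeta[sim.valve_names.index(vname)] = 1.0

    # 1D blood volume at the initial state
    v1d_ml = 0.0
    for iv in range(len(sim.nel)):
        n0 = 2 * sim.elstart[iv]
        for e in range(sim.nel[iv]):
            v1d_ml += 0.5 * (sim.A[n0 + 2 * e] + sim.A[n0 + 2 * e + 1]) \
                * sim.h[iv]
    v1d_ml *= 1e6

    # coronary layer volumes (fixed small initial charge, V_u = 0)
    p_it0 = sim.P[K.P_PITSUP]
    cvp0 = p_init[sim.i_ra] if p_init[sim.i_ra] > 0 else 7.0
    p_ic0 = sim.P[K.P_ICPOFF] + cvp0
    V = np.zeros(nstate)
    layer_total = 0.0
    for name in sim.comp_names:
        i = sim.comp_index[name]
        if name.startswith("cor_") and name.count("_") == 2:
            V[i] = sim.comp_C[i] * p_init[i]
            layer_total += V[i]

    # distribute the remaining pool by the configured fractions
    fractions = {}
    for name, c in model.compartments.items():
        fractions[name] = c.volume_fraction
    for name in CHAMBER_ORDER:
        fractions[name] = model.chambers[name].get("volume_fraction", 0.0)
    pool = model.total_blood_volume - v1d_ml - layer_total
    vols = distribute_blood_volume(pool, fractions)
    for name, v0 in vols.items():
        V[sim.comp_index[name]] = v0

    # unstressed volumes from the initialization pressures
    for name, c in model.compartments.items():
        i = sim.comp_index[name]
        if c.extravascular_source == "intrathoracic":
            pext = p_it0
        elif c.extravascular_source == "intracranial":
            pext = p_ic0
        elif c.extravascular_source == "intramyocardial":
            pext = 0.0
        else:
            pext = 0.0
        ptm = p_init[i] - pext
        if sim.comp_kind[i] == K.K_LEGVEIN:
            dv = (2.0 * sim.lv_dVmax / math.pi) * math.atan(
                math.pi * sim.lv_C0 * max(ptm, 0.0)
                / (2.0 * sim.lv_dVmax))
            sim.comp_Vu[i] = V[i] - dv
        else:
            sim.comp_Vu[i] = V[i] - sim.comp_C[i] * ptm
    sim.V = V

    # scalar state
    S = np.zeros(K.S_LEN)
    hr0 = sim.P[K.P_HRBAS]
    rr0 = 60.0 / hr0
    S[K.S_RR] = rr0
    S[K.S_TSYS] = sim.P[K.P_SYSK] * rr0 ** sim.P[K.P_SYSEXP]
    S[K.S_PEAK] = _vent_shape_peak(S[K.S_TSYS], rr0)
    S[K.S_HR] = hr0
    S[K.S_EMAXS] = 1.0
    S[K.S_RARTS] = 1.0
    S[K.S_VUS] = 1.0
    S[K.S_CVENS] = 1.0
    S[K.S_PACS] = 90.0
    S[K.S_PRA] = cvp0
    S[K.S_CBF] = 12.0
    S[K.S_PIC] = p_ic0
    S[K.S_PT] = 90.0
    S[K.S_CPT] = cvp0
    S[K.S_CBFREF] = -1.0
    S[K.S_REGON] = 0.0
    S[K.S_CAHEAD] = sim.P[K.P_CAN]
    S[K.S_PTMH] = 85.0
    S[K.S_PTMHN] = -1.0
    S[K.S_PSVC] = p_init[sim.i_svc]
    S[K.S_NSYM] = 0.5
    S[K.S_NPARA] = 0.5
    sim.S = S
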