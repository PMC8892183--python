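"""Compiled time-stepping core of the coupled 1D-0D closed loop.

All state lives in flat numpy arrays prepared by :mod:`orthosim.engine.compile`;
the kernel advances the full system (1D tree, lumped compartments, chambers,
valves, regulation, posture) with a constant time step using the 2-step
explicit Runge-Kutta (Heun) scheme for the bulk mass/momentum states and
exact exponential updates for the stiff relaxation states (valve opening,
effector dynamics, afferent averages).

Unit conventions: 1D arrays in SI (m^2, m^3/s, Pa), 0D arrays in clinical
units (mmHg, ml, s). The interface conversions happen at the aortic valve
and at the terminal couplings.

Scalar state lives in the ``S`` float array and constant parameters in the
``P`` float array; the index constants below document the layout.
"""
import math

import numpy as np
from numba import njit

from ..arterial_1d import (_vessel_rhs, _celerity,
                           _A_from_W_and_Q, _A_from_W_terminal,
                           _junction_newton)
from ..heart import _vent_shape, _vent_shape_peak, _atrial_shape
from ..lumped_0d import (_legvein_p, _valve_zeta_update, _valve_bernoulli_B,
                         _valve_q_implicit)

MMHG = 133.322
ML = 1e-6

# --- S (mutable scalar state) indices -------------------------------------
S_T = 0          # current time, s
S_PHASE = 1      # beat phase in [0,1)
S_RR = 2         # current beat period, s
S_TSYS = 3       # current systolic duration, s
S_PEAK = 4       # double-Hill normalization peak
S_HR = 5         # heart-rate effector, bpm
S_EMAXS = 6      # ventricular contractility scale
S_RARTS = 7      # arteriolar resistance scale
S_VUS = 8        # venous unstressed-volume scale
S_CVENS = 9      # venous compliance scale
S_PACS = 10      # afferent aortic-carotid EMA, mmHg
S_PRA = 11       # afferent right-atrial EMA, mmHg
S_CBF = 12       # cerebral blood flow EMA, ml/s
S_XAUT = 13      # autoregulation filtered error
S_PIC = 14       # intracranial pressure, mmHg
S_PT = 15        # baroreflex target pressure, mmHg
S_CPT = 16       # cardiopulmonary target pressure, mmHg
S_CBFREF = 17    # CBF reference, ml/s
S_REGON = 18     # regulation enabled (0/1)
S_CAHEAD = 19    # cerebral arteriolar compliance, ml/mmHg
S_PTMH = 20      # head arteriolar transmural pressure EMA, mmHg
S_PTMHN = 21     # its captured reference
S_PSVC = 22      # superior vena cava pressure EMA, mmHg
S_NSYM = 23      # last sympathetic activity
S_NPARA = 24
S_NBEAT = 25     # beats elapsed (float count)
S_LEN = 26

# --- P (constant parameter) indices ----------------------------------------
P_NU = 0
P_TAUAFF = 1
P_NUCP = 2
P_HRBAS = 3
P_HRGS = 4
P_HRGP = 5
P_HRTAU = 6
P_HRLO = 7
P_HRHI = 8
P_EMAXG = 9
P_EMAXTAU = 10
P_RARTG = 11
P_RARTGCP = 12
P_RARTTAU = 13
P_VUG = 14
P_VUGCP = 15
P_VUTAU = 16
P_CVENG = 17
P_CVENGCP = 18
P_CVENTAU = 19
P_AUTG = 20
P_AUTTAU = 21
P_AUTAMPD = 22
P_AUTAMPC = 23
P_ICPOFF = 24    # R_csf * I_f, mmHg
P_ZDURAL = 25
P_ZJUG = 26
P_PITSUP = 27
P_PITDELTA = 28
P_RHO = 29
P_GRAV = 30
P_A0TILT = 31    # tilt start angle, rad
P_A1TILT = 32    # tilt end angle, rad
P_TSTART = 33
P_TRAMP = 34
P_SHAPE = 35     # 0 cosine, 1 linear
P_SCLO = 36      # generic effector-scale lower bound
P_SCHI = 37
P_TAUCBF = 38    # CBF averaging time constant
P_CAN = 39       # basal cerebral arteriolar compliance
P_CHI = 40
P_NUKIN = 41     # kinematic viscosity, m^2/s
P_SYSK = 42      # systolic-duration coefficient
P_SYSEXP = 43    # systolic-duration exponent on RR
P_LEN = 44

# compartment kind codes
K_LINEAR = 0
K_LEGVEIN = 1
K_CHAMBER = 2

# extravascular source codes
E_AMBIENT = 0
E_THORAX = 1
E_ICP = 2
E_IM = 3         # intramyocardial: weight * LV cavity pressure


@njit(cache=True)
def _tilt_alpha(t, P):
    t0 = P[P_TSTART]
    tr = P[P_TRAMP]
    a0 = P[P_A0TILT]
    a1 = P[P_A1TILT]
    if t <= t0 or tr <= 0.0:
        return a0 if t <= t0 else a1
    if t >= t0 + tr:
        return a1
    s = (t - t0) / tr
    if P[P_SHAPE] == 1.0:
        w = s
    else:
        w = 0.5 * (1.0 - math.cos(math.pi * s))
    return a0 + (a1 - a0) * w


@njit(cache=True)
def _chamber_E(phase, rr, tsys, peak, Emax, Emin, isvent, onset, dur):
    if isvent == 1:
        tt = (phase - onset) * rr
        if tt <= 0.0:
            e = 0.0
        else:
            e = _vent_shape(tt, tsys) / peak
    else:
        e = _atrial_shape(phase, onset, dur)
    return Emin + (Emax - Emin) * e


@njit(cache=True)
def _pressures(V, p_out, phase, rr, tsys, peak, p_it, p_ic, s_emax, s_vu,
               s_cven, ca_head,
               comp_kind, comp_C, comp_Vu, comp_ext, comp_pimw, comp_tone,
               ihead_art, ilegvein, lv_C0, lv_dVmax,
               ch_idx, ch_Emax, ch_Emin, ch_Vu, ch_isvent, ch_onset, ch_dur,
               ch_ectrl, i_lv):
    """Compartment/chamber pressures from volumes (mmHg), into p_out."""
    n = V.shape[0]
    # chambers first (coronary layers need the LV cavity pressure)
    for i in range(n):
        if comp_kind[i] == K_CHAMBER:
            k = ch_idx[i]
            Em = ch_Emax[k] * (s_emax if ch_ectrl[k] == 1 else 1.0)
            E = _chamber_E(phase, rr, tsys, peak, Em, ch_Emin[k],
                           ch_isvent[k], ch_onset[k], ch_dur[k])
            p_out[i] = E * (V[i] - ch_Vu[k]) + p_it
    p_lv = p_out[i_lv]
    for i in range(n):
        kind = comp_kind[i]
        if kind == K_CHAMBER:
            continue
        if comp_ext[i] == E_THORAX:
            pext = p_it
        elif comp_ext[i] == E_ICP:
            pext = p_ic
        elif comp_ext[i] == E_IM:
            pext = comp_pimw[i] * p_lv
        else:
            pext = 0.0
        if kind == K_LEGVEIN:
            p_out[i] = _legvein_p(V[i], lv_C0 * s_cven,
                                  lv_dVmax, comp_Vu[i] * s_vu) + pext
        else:
            C = comp_C[i]
            Vu = comp_Vu[i]
            if comp_tone[i] == 1:
                C = C * s_cven
                Vu = Vu * s_vu
            if i == ihead_art and ca_head > 0.0:
                C = ca_head
            p_out[i] = (V[i] - Vu) / C + pext
    return p_lv


@njit(cache=True)
def _stage_rhs(A, Q, V, Ql, p0d, t, S, P, zeta, q_av,
               # 1D structure
               nel, elstart, h, lam, gvisc, A0n, bn, dbdx, dpsidx, pvn,
               prefv,
               # junctions
               jvessel, jnch, jchild,
               # terminals
               tvessel, tcomp, tZc, tdz, thead,
               # links
               lup, ldn, lR, lL, lGh, lvalve, lrctrl, lRart_n,
               # valves
               vAmax, vAmin, vRv, vLv,
               # outputs
               dA, dQ, dV, dQl,
               sin_a, p_root_out, q_head_out,
               bAin, bQin, bAout, bQout):
    """One evaluation of the coupled right-hand side.

    ``q_av`` is the aortic-valve flow (ml/s, state Ql of the aortic link),
    passed explicitly because it closes the 1D root boundary. Returns the
    aortic root pressure (mmHg) through p_root_out[0] and the instantaneous
    cerebral inflow (ml/s) through q_head_out[0].
    """
    rho = P[P_RHO]
    chi = P[P_CHI]
    nu = P[P_NUKIN]
    nv = nel.shape[0]
    g_sin = P[P_GRAV] * sin_a

    # ---- 1D boundaries ----
    # root (vessel 0 inlet): prescribed flow from the aortic valve
    i0 = 0
    c_in = _celerity(A[i0], bn[i0], rho)
    Wm = Q[i0] / A[i0] - 4.0 * c_in
    Qroot = q_av * ML
    Ab = _A_from_W_and_Q(Wm, Qroot, bn[i0], rho, A[i0], False)
    bAin[0] = Ab
    bQin[0] = Qroot
    p_root_out[0] = (prefv[0] + bn[i0] * (math.sqrt(Ab)
                                          - math.sqrt(A0n[i0]))) / MMHG

    # junctions
    nj = jvessel.shape[0]
    for ij in range(nj):
        vp = jvessel[ij]
        ip = 2 * (elstart[vp] + nel[vp]) - 1   # last node of parent
        cp = _celerity(A[ip], bn[ip], rho)
        Wp = Q[ip] / A[ip] + 4.0 * cp
        nch = jnch[ij]
        Wc = np.empty(nch)
        bc = np.empty(nch)
        sqA0c = np.empty(nch)
        prefc = np.empty(nch)
        Ac0 = np.empty(nch)
        for k in range(nch):
            vc = jchild[ij, k]
            ic = 2 * elstart[vc]
            cc = _celerity(A[ic], bn[ic], rho)
            Wc[k] = Q[ic] / A[ic] - 4.0 * cc
            bc[k] = bn[ic]
            sqA0c[k] = math.sqrt(A0n[ic])
            prefc[k] = prefv[vc]
            Ac0[k] = A[ic]
        Av, Qv, it, ok = _junction_newton(
            Wp, bn[ip], math.sqrt(A0n[ip]), prefv[vp], A[ip],
            Wc, bc, sqA0c, prefc, Ac0, nch, rho, 1e-10, 50)
        bAout[vp] = Av[0]
        bQout[vp] = Qv[0]
        for k in range(nch):
            vc = jchild[ij, k]
            bAin[vc] = Av[1 + k]
            bQin[vc] = Qv[1 + k]

    # terminals: impedance coupling against arteriolar node pressure
    ntm = tvessel.shape[0]
    q_head = 0.0
    for itq in range(ntm):
        vt = tvessel[itq]
        ie = 2 * (elstart[vt] + nel[vt]) - 1
        ct = _celerity(A[ie], bn[ie], rho)
        Wp = Q[ie] / A[ie] + 4.0 * ct
        # effective back pressure: 0D node + column between terminal end
        # and the regional node position
        p_eff = (p0d[tcomp[itq]] * MMHG
                 + rho * P[P_GRAV] * tdz[itq] * sin_a)
        Ab2, Qb2 = _A_from_W_terminal(Wp, bn[ie], math.sqrt(A0n[ie]),
                                      prefv[vt], p_eff, tZc[itq], rho, A[ie])
        bAout[vt] = Ab2
        bQout[vt] = Qb2
        dV[tcomp[itq]] += Qb2 / ML
        if thead[itq] == 1:
            q_head += Qb2 / ML
    q_head_out[0] = q_head

    # ---- 1D interior ----
    for iv in range(nv):
        n0 = 2 * elstart[iv]
        n1 = 2 * (elstart[iv] + nel[iv])
        e0 = elstart[iv]
        e1 = elstart[iv] + nel[iv]
        FL1, FL2 = _flux_of(bAin[iv], bQin[iv], bn[n0], chi, rho)
        FR1, FR2 = _flux_of(bAout[iv], bQout[iv], bn[n1 - 1], chi, rho)
        _vessel_rhs(A[n0:n1], Q[n0:n1], dA[n0:n1], dQ[n0:n1], h[iv],
                    bn[n0:n1], A0n[n0:n1], dbdx[e0:e1], dpsidx[e0:e1],
                    chi, rho, nu, g_sin * lam[iv], pvn[n0:n1],
                    FL1, FL2, FR1, FR2)

    # ---- 0D links ----
    nl = lup.shape[0]
    for il in range(nl):
        iu = lup[il]
        idn = ldn[il]
        pu = p0d[iu]
        if idn >= 0:
            pd = p0d[idn]
        else:
            pd = p_root_out[0]   # aortic valve into the 1D root
        dp = pu - pd + lGh[il] * sin_a
        qv = Ql[il]
        ivv = lvalve[il]
        if ivv >= 0:
            # valve flows advance with their own implicit update once per
            # step (stiff quadratic resistance); frozen within RK stages
            dQl[il] = 0.0
        else:
            R = lR[il]
            if lrctrl[il] == 1:
                R = R * S[S_RARTS]
            elif lrctrl[il] == 2:
                R = lRart_n[il]  # autoregulated value, precomputed per step
            dQl[il] = (dp - R * qv) / lL[il]
        dV[iu] -= qv
        if idn >= 0:
            dV[idn] += qv
    return 0


@njit(cache=True)
def _flux_of(Ab, Qb, b, chi, rho):
    return Qb, chi * Qb * Qb / Ab + b * Ab ** 1.5 / (3.0 * rho)


@njit(cache=True)
def run_steps(nsteps, dt, out_every,
              # state
              A, Q, V, Ql, zeta, S, dAprev,
              # params
              P,
              # 1D structure
              nel, elstart, h, lam, gvisc, A0n, bn, dbdx, dpsidx, prefv,
              jvessel, jnch, jchild,
              tvessel, tcomp, tZc, tdz, thead,
              # 0D structure
              comp_kind, comp_C, comp_Vu, comp_ext, comp_pimw, comp_tone,
              ihead_art, ilegvein, lv_C0, lv_dVmax,
              ch_idx, ch_Emax, ch_Emin, ch_Vu, ch_isvent, ch_onset, ch_dur,
              ch_ectrl, i_lv, i_ra, i_svc, iav_link, head_art_link,
              site_node, site_vessel,
              lup, ldn, lR, lL, lGh, lvalve, lrctrl,
              vAmax, vAmin, vKo, vKc, vdpo, vdpc, vRv, vLv,
              # records (preallocated, filled every out_every steps)
              rec_t, rec_alpha, rec_hr, rec_nsym, rec_pic, rec_qav, rec_cbf,
              rec_sitep, rec_siteq, rec_compp, rec_compv, rec_eff,
              beat_t, beat_rr,
              nbeat_in):
    """Advance ``nsteps`` steps; returns (status, n_recorded, n_beats).

    status: 0 ok, 1 negative area, 2 non-finite state.
    """
    NN = A.shape[0]
    nstate = V.shape[0]
    nlnk = Ql.shape[0]
    nv = nel.shape[0]

    p0d = np.empty(nstate)
    dA1 = np.empty(NN)
    dQ1 = np.empty(NN)
    dA2 = np.empty(NN)
    dQ2 = np.empty(NN)
    dV1 = np.empty(nstate)
    dV2 = np.empty(nstate)
    dQl1 = np.empty(nlnk)
    dQl2 = np.empty(nlnk)
    A1 = np.empty(NN)
    Q1 = np.empty(NN)
    V1 = np.empty(nstate)
    Qlp = np.empty(nlnk)
    pvn = np.empty(NN)
    bAin = np.empty(nv)
    bQin = np.empty(nv)
    bAout = np.empty(nv)
    bQout = np.empty(nv)
    p_root = np.empty(1)
    q_head = np.empty(1)
    lRart_n = np.empty(nlnk)

    irec = 0
    nbeat = nbeat_in
    rho = P[P_RHO]
    ns = site_node.shape[0]
    acc_cbf = 0.0
    acc_qav = 0.0
    acc_siteq = np.zeros(ns)
    acc_n = 0

    for istep in range(nsteps):
        t = S[S_T]
        alpha = _tilt_alpha(t, P)
        sin_a = math.sin(alpha)
        p_it = P[P_PITSUP] - P[P_PITDELTA] * sin_a
        p_ic = S[S_PIC]
        s_emax = S[S_EMAXS]
        s_vu = S[S_VUS]
        s_cven = S[S_CVENS]
        ca_head = S[S_CAHEAD]

        # viscoelastic pressure correction from the previous step
        for i in range(NN):
            pvn[i] = 0.0
        for iv in range(nv):
            if gvisc[iv] > 0.0:
                n0 = 2 * elstart[iv]
                n1 = 2 * (elstart[iv] + nel[iv])
                for i in range(n0, n1):
                    pvn[i] = gvisc[iv] / (A0n[i] * math.sqrt(A[i])) \
                        * dAprev[i]

        # autoregulated cerebral arteriolar resistance (frozen per step)
        for il in range(nlnk):
            if lrctrl[il] == 2:
                if S[S_REGON] == 1.0 and S[S_PTMHN] > 0.0:
                    vn = P[P_CAN] * S[S_PTMHN]
                    va = ca_head * max(S[S_PTMH], 1e-6)
                    sc = (vn / va) * (vn / va)
                    if sc < 0.2:
                        sc = 0.2
                    elif sc > 5.0:
                        sc = 5.0
                    lRart_n[il] = lR[il] * sc
                else:
                    lRart_n[il] = lR[il]

        # ---- stage 1 ----
        for i in range(nstate):
            dV1[i] = 0.0
        _pressures(V, p0d, S[S_PHASE], S[S_RR], S[S_TSYS], S[S_PEAK],
                   p_it, p_ic, s_emax, s_vu, s_cven, ca_head,
                   comp_kind, comp_C, comp_Vu, comp_ext, comp_pimw,
                   comp_tone, ihead_art, ilegvein, lv_C0, lv_dVmax,
                   ch_idx, ch_Emax, ch_Emin, ch_Vu, ch_isvent, ch_onset,
                   ch_dur, ch_ectrl, i_lv)
        q_av = Ql[iav_link]
        _stage_rhs(A, Q, V, Ql, p0d, t, S, P, zeta, q_av,
                   nel, elstart, h, lam, gvisc, A0n, bn, dbdx, dpsidx, pvn,
                   prefv, jvessel, jnch, jchild,
                   tvessel, tcomp, tZc, tdz, thead,
                   lup, ldn, lR, lL, lGh, lvalve, lrctrl, lRart_n,
                   vAmax, vAmin, vRv, vLv,
                   dA1, dQ1, dV1, dQl1, sin_a, p_root, q_head,
                   bAin, bQin, bAout, bQout)
        p_root_rec = p_root[0]
        q_head_rec = q_head[0]
        p_arch_now = p0d[0]  # placeholder; recomputed below via sites

        ok = True
        for i in range(NN):
            A1[i] = A[i] + dt * dA1[i]
            Q1[i] = Q[i] + dt * dQ1[i]
            if A1[i] <= 0.0:
                ok = False
        if not ok:
            return 1, irec, nbeat
        for i in range(nstate):
            V1[i] = V[i] + dt * dV1[i]
        for i in range(nlnk):
            Qlp[i] = Ql[i] + dt * dQl1[i]

        # ---- stage 2 (at t + dt) ----
        t2 = t + dt
        alpha2 = _tilt_alpha(t2, P)
        sin_a2 = math.sin(alpha2)
        p_it2 = P[P_PITSUP] - P[P_PITDELTA] * sin_a2
        phase2 = S[S_PHASE] + dt / S[S_RR]
        if phase2 >= 1.0:
            phase2 -= 1.0
        for i in range(nstate):
            dV2[i] = 0.0
        _pressures(V1, p0d, phase2, S[S_RR], S[S_TSYS], S[S_PEAK],
                   p_it2, p_ic, s_emax, s_vu, s_cven, ca_head,
                   comp_kind, comp_C, comp_Vu, comp_ext, comp_pimw,
                   comp_tone, ihead_art, ilegvein, lv_C0, lv_dVmax,
                   ch_idx, ch_Emax, ch_Emin, ch_Vu, ch_isvent, ch_onset,
                   ch_dur, ch_ectrl, i_lv)
        q_av2 = Qlp[iav_link]
        _stage_rhs(A1, Q1, V1, Qlp, p0d, t2, S, P, zeta, q_av2,
                   nel, elstart, h, lam, gvisc, A0n, bn, dbdx, dpsidx, pvn,
                   prefv, jvessel, jnch, jchild,
                   tvessel, tcomp, tZc, tdz, thead,
                   lup, ldn, lR, lL, lGh, lvalve, lrctrl, lRart_n,
                   vAmax, vAmin, vRv, vLv,
                   dA2, dQ2, dV2, dQl2, sin_a2, p_root, q_head,
                   bAin, bQin, bAout, bQout)

        # ---- combine ----
        for i in range(NN):
            Anew = A[i] + 0.5 * dt * (dA1[i] + dA2[i])
            dAprev[i] = (Anew - A[i]) / dt
            A[i] = Anew
            Q[i] = Q[i] + 0.5 * dt * (dQ1[i] + dQ2[i])
            if A[i] <= 0.0:
                return 1, irec, nbeat
            if not math.isfinite(A[i]) or not math.isfinite(Q[i]):
                return 2, irec, nbeat
        p_root2 = p_root[0]
        for i in range(nstate):
            V[i] = V[i] + 0.5 * dt * (dV1[i] + dV2[i])
            if not math.isfinite(V[i]):
                return 2, irec, nbeat
        for i in range(nlnk):
            Ql[i] = Ql[i] + 0.5 * dt * (dQl1[i] + dQl2[i])

        # ---- end-of-step updates (exponential integrators) ----
        # recompute pressures at the new state for valves and afferents
        _pressures(V, p0d, phase2, S[S_RR], S[S_TSYS], S[S_PEAK],
                   p_it2, p_ic, s_emax, s_vu, s_cven, ca_head,
                   comp_kind, comp_C, comp_Vu, comp_ext, comp_pimw,
                   comp_tone, ihead_art, ilegvein, lv_C0, lv_dVmax,
                   ch_idx, ch_Emax, ch_Emin, ch_Vu, ch_isvent, ch_onset,
                   ch_dur, ch_ectrl, i_lv)
        for il in range(nlnk):
            ivv = lvalve[il]
            if ivv >= 0:
                iu = lup[il]
                idn = ldn[il]
                pd = p0d[idn] if idn >= 0 else p_root2
                dpv = p0d[iu] - pd + lGh[il] * sin_a2
                zeta[ivv] = _valve_zeta_update(
                    zeta[ivv], dpv, vKo[ivv], vKc[ivv], vdpo[ivv],
                    vdpc[ivv], dt)
                Ql[il] = _valve_q_implicit(
                    Ql[il], dpv, zeta[ivv], vAmax[ivv], vAmin[ivv],
                    vRv[ivv], vLv[ivv], rho, dt)

        # afferent pressures from measurement sites (element means)
        p_arch = 0.5 * (
            _node_pressure(A, bn, A0n, prefv, site_node[0], site_vessel[0])
            + _node_pressure(A, bn, A0n, prefv, site_node[0] + 1,
                             site_vessel[0]))
        p_carotid = 0.5 * (
            _node_pressure(A, bn, A0n, prefv, site_node[1], site_vessel[1])
            + _node_pressure(A, bn, A0n, prefv, site_node[1] + 1,
                             site_vessel[1]))
        p_acs = 0.5 * (p_arch + p_carotid)
        ea = math.exp(-dt / P[P_TAUAFF])
        S[S_PACS] = p_acs + (S[S_PACS] - p_acs) * ea
        S[S_PRA] = p0d[i_ra] + (S[S_PRA] - p0d[i_ra]) * ea
        S[S_PSVC] = p0d[i_svc] + (S[S_PSVC] - p0d[i_svc]) * ea
        ecb = math.exp(-dt / P[P_TAUCBF])
        S[S_CBF] = q_head_rec + (S[S_CBF] - q_head_rec) * ecb
        ptmh = p0d[ihead_art] - 0.0
        S[S_PTMH] = ptmh + (S[S_PTMH] - ptmh) * ea

        if S[S_REGON] == 1.0:
            nsym = 1.0 / (1.0 + (max(S[S_PACS], 1e-6) / S[S_PT])
                          ** P[P_NU])
            npar = 1.0 - nsym
            ncp = 1.0 / (1.0 + (max(S[S_PRA], 1e-6) / S[S_CPT])
                         ** P[P_NUCP])
            cp = ncp - 0.5
            S[S_NSYM] = nsym
            S[S_NPARA] = npar
            # effectors: exact exponential relaxation toward drive
            S[S_HR] = _exp_clamp(S[S_HR],
                                 P[P_HRBAS] + P[P_HRGS] * (nsym - 0.5)
                                 - P[P_HRGP] * (npar - 0.5),
                                 P[P_HRTAU], dt, P[P_HRLO], P[P_HRHI])
            S[S_EMAXS] = _exp_clamp(S[S_EMAXS],
                                    1.0 + P[P_EMAXG] * (nsym - 0.5),
                                    P[P_EMAXTAU], dt, P[P_SCLO], P[P_SCHI])
            S[S_RARTS] = _exp_clamp(S[S_RARTS],
                                    1.0 + P[P_RARTG] * (nsym - 0.5)
                                    + P[P_RARTGCP] * cp,
                                    P[P_RARTTAU], dt, P[P_SCLO], P[P_SCHI])
            S[S_VUS] = _exp_clamp(S[S_VUS],
                                  1.0 - P[P_VUG] * (nsym - 0.5)
                                  - P[P_VUGCP] * cp,
                                  P[P_VUTAU], dt, P[P_SCLO], P[P_SCHI])
            S[S_CVENS] = _exp_clamp(S[S_CVENS],
                                    1.0 - P[P_CVENG] * (nsym - 0.5)
                                    - P[P_CVENGCP] * cp,
                                    P[P_CVENTAU], dt, P[P_SCLO], P[P_SCHI])
            # cerebral autoregulation
            if S[S_CBFREF] > 0.0:
                xinf = P[P_AUTG] * (S[S_CBF] - S[S_CBFREF]) / S[S_CBFREF]
                eaut = math.exp(-dt / P[P_AUTTAU])
                S[S_XAUT] = xinf + (S[S_XAUT] - xinf) * eaut
                x = S[S_XAUT]
                amp = P[P_AUTAMPD] if x < 0.0 else P[P_AUTAMPC]
                S[S_CAHEAD] = P[P_CAN] * (1.0 + amp * math.tanh(-x))

        # intracranial pressure (Davson + continuous collapse switch)
        colhj = (rho * P[P_GRAV] * (P[P_ZJUG] - P[P_ZDURAL]) * sin_a2) / MMHG
        pj = S[S_PSVC] + (rho * P[P_GRAV] * P[P_ZJUG] * sin_a2) / MMHG
        pj_eff = pj if pj > 0.0 else 0.0
        S[S_PIC] = P[P_ICPOFF] + pj_eff - colhj

        # accumulate anti-aliased flow records
        acc_cbf += q_head_rec
        acc_qav += Ql[iav_link]
        for k in range(ns):
            n1s = site_node[k]
            acc_siteq[k] += 0.5 * (Q[n1s] + Q[n1s + 1]) / ML
        acc_n += 1

        # beat bookkeeping
        S[S_PHASE] = S[S_PHASE] + dt / S[S_RR]
        S[S_T] = t + dt
        if S[S_PHASE] >= 1.0:
            S[S_PHASE] -= 1.0
            rr = 60.0 / S[S_HR]
            S[S_RR] = rr
            S[S_TSYS] = P[P_SYSK] * rr ** P[P_SYSEXP]
            S[S_PEAK] = _vent_shape_peak(S[S_TSYS], rr)
            if nbeat < beat_t.shape[0]:
                beat_t[nbeat] = S[S_T]
                beat_rr[nbeat] = rr
            nbeat += 1

        # record
        if istep % out_every == 0:
            if irec < rec_t.shape[0]:
                rec_t[irec] = S[S_T]
                rec_alpha[irec] = alpha2
                rec_hr[irec] = S[S_HR]
                rec_nsym[irec] = S[S_NSYM]
                rec_pic[irec] = S[S_PIC]
                rec_qav[irec] = acc_qav / acc_n
                rec_cbf[irec] = acc_cbf / acc_n
                for k in range(ns):
                    n1s = site_node[k]
                    rec_sitep[irec, k] = 0.5 * (
                        _node_pressure(A, bn, A0n, prefv, n1s,
                                       site_vessel[k])
                        + _node_pressure(A, bn, A0n, prefv, n1s + 1,
                                         site_vessel[k]))
                    rec_siteq[irec, k] = acc_siteq[k] / acc_n
                acc_cbf = 0.0
                acc_qav = 0.0
                for k in range(ns):
                    acc_siteq[k] = 0.0
                acc_n = 0
                for k in range(nstate):
                    rec_compp[irec, k] = p0d[k]
                    rec_compv[irec, k] = V[k]
                rec_eff[irec, 0] = S[S_EMAXS]
                rec_eff[irec, 1] = S[S_RARTS]
                rec_eff[irec, 2] = S[S_VUS]
                rec_eff[irec, 3] = S[S_CVENS]
                rec_eff[irec, 4] = S[S_CAHEAD]
                irec += 1
    return 0, irec, nbeat


@njit(cache=True)
def _exp_clamp(x, xinf, tau, dt, lo, hi):
    x = xinf + (x - xinf) * math.exp(-dt / tau)
    if x < lo:
        x = lo
    elif x > hi:
        x = hi
    return x


@njit(cache=True)
def _node_pressure(A, bn, A0n, prefv, node, vessel):
    return (prefv[vessel]
            + bn[node] * (math.sqrt(A[node]) - math.sqrt(A0n[node]))) / MMHG
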