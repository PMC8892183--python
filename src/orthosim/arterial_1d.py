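"""1D pulse-wave propagation in compliant arteries.

Mass and momentum balance for the cross-sectional area A(x,t) and flow rate
Q(x,t) of an axisymmetric vessel::

    dA/dt + dQ/dx = 0
    dQ/dt + d(chi Q^2/A)/dx + (A/rho) dp/dx = f_visc + g A sin(alpha) lambda

closed by the elastic--viscoelastic tube law::

    p = p_ext + p_ref + beta (sqrt(A) - sqrt(A0)) / A0
              + gamma_visc / (A0 sqrt(A)) * dA/dt

``beta`` (Pa*m) is the elastic wall coefficient, ``gamma_visc`` (Pa*s*m) the
Kelvin--Voigt viscoelastic coefficient, ``chi`` the momentum-correction factor
and ``f_visc = -2(zeta+2) pi nu Q / A`` the wall friction of a flat-parabolic
velocity profile (default zeta = 9, chi = 1.1). ``lambda`` is the signed
projection of the vessel axis on the head--feet body axis (feetward positive),
so a feetward-running vessel gains pressure distally when the body is tilted
by ``alpha`` from the horizontal.

The small-perturbation wave speed of this law is
``c(A) = sqrt(beta sqrt(A) / (2 rho A0))`` i.e. ``c0 = sqrt(beta/(2 rho A0))
A0**(1/4)`` at the reference area, and the Riemann invariants are
``W_pm = Q/A +- 4 c``.

Space discretization is nodal Discontinuous Galerkin with linear (P1)
elements and a local Lax-Friedrichs interface flux; boundary states at vessel
ends are resolved with the method of characteristics (outgoing invariant +
external datum). Time integration (here and in the coupled engine) is the
2-step explicit Runge-Kutta (Heun) scheme.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .units import G_STANDARD

# Flat-parabolic velocity profile constants.
ZETA_PROFILE = 9.0
CHI_DEFAULT = 1.1
FRICTION_COEFF = 2.0 * (ZETA_PROFILE + 2.0) * math.pi  # * nu * Q / A
GAUSS_OFF = 0.5 / math.sqrt(3.0)  # 2-point Gauss offset on [0, 1]


class SolverStateError(RuntimeError):
    """Non-physical solver state (negative area / NaN): blow-up signal."""


class CFLError(RuntimeError):
    """Time step violates the stability bound."""


class JunctionConvergenceError(RuntimeError):
    """Newton iteration at a junction failed to converge."""


# ----------------------------------------------------------------------------
# Wall law and gravity (spec-level operations)
# ----------------------------------------------------------------------------

@dataclass(frozen=True)
class WallLaw:
    """Elastic-viscoelastic tube law of one vessel (uniform properties)."""

    beta: float               # Pa*m
    A0: float                 # m^2
    gamma_visc: float = 0.0   # Pa*s*m
    reference_pressure: float = 0.0  # Pa

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.gamma_visc < 0:
            raise ValueError("gamma_visc must be non-negative")
        if self.A0 <= 0:
            raise ValueError("A0 must be positive")


@dataclass(frozen=True)
class GravityContext:
    """Orientation data entering the axial gravity source term."""

    tilt_angle_alpha: float          # rad, 0 = supine
    longitudinal_projection: float   # in [-1, 1], feetward positive
    orientation_gamma: float = 0.0   # rad, kept for bookkeeping
    g: float = G_STANDARD

    def __post_init__(self):
        if not 0.0 <= self.tilt_angle_alpha <= math.pi / 2 + 1e-12:
            raise ValueError("tilt angle must lie in [0, pi/2]")
        if abs(self.longitudinal_projection) > 1.0 + 1e-12:
            raise ValueError("|longitudinal_projection| must be <= 1")


@njit(cache=True)
def _elastic_pressure(A, b, sqrtA0):
    return b * (math.sqrt(A) - sqrtA0)


@njit(cache=True)
def _celerity(A, b, rho):
    # c^2 = b*sqrt(A) / (2 rho), with b = beta/A0
    return math.sqrt(b * math.sqrt(A) / (2.0 * rho))


def wall_pressure(A: float, law: WallLaw, dA_dt: float = 0.0,
                  p_ext: float = 0.0) -> float:
    """Intraluminal pressure (Pa) from the tube law.

    ``p = p_ext + p_ref + beta (sqrt A - sqrt A0)/A0 + gamma/(A0 sqrt A) dA/dt``
    """
    if A <= 0:
        raise SolverStateError("non-positive area in wall law")
    b = law.beta / law.A0
    p = p_ext + law.reference_pressure + _elastic_pressure(
        A, b, math.sqrt(law.A0))
    if law.gamma_visc != 0.0 and dA_dt != 0.0:
        p += law.gamma_visc / (law.A0 * math.sqrt(A)) * dA_dt
    return p


def wave_speed(A: float, law: WallLaw, rho: float) -> float:
    """Local small-perturbation wave speed c(A) in m/s."""
    if A <= 0:
        raise SolverStateError("non-positive area")
    return _celerity(A, law.beta / law.A0, rho)


def beta_from_wave_speed(c0: float, A0: float, rho: float) -> float:
    """Elastic coefficient beta (Pa*m) giving reference wave speed c0."""
    return 2.0 * rho * c0 * c0 * A0 / math.sqrt(A0)


def axial_gravity_term(ctx: GravityContext, A: float, rho: float) -> float:
    """Axial momentum source of gravity, as force per unit length (N/m).

    ``rho g A sin(alpha) lambda`` with lambda feetward-positive: a
    feetward-running vessel is pushed distally (pressure grows toward the
    feet) when tilted; the sign flips for headward vessels and the term
    vanishes supine (alpha = 0), where gravity acts perpendicular to the
    body's long axis.
    """
    return (rho * ctx.g * A * math.sin(ctx.tilt_angle_alpha)
            * ctx.longitudinal_projection)


# ----------------------------------------------------------------------------
# Discretized vessel
# ----------------------------------------------------------------------------

@dataclass
class VesselGrid:
    """P1-DG discretization of a single (possibly tapered) vessel.

    Nodal values live at the two end points of every element (discontinuous
    between elements). ``A0`` and ``b = beta/A0`` vary linearly along the
    vessel to represent tapering.
    """

    length: float
    n_elements: int
    A0_prox: float
    A0_dist: float
    beta_prox: float
    beta_dist: float
    rho: float
    gamma_visc: float = 0.0
    chi: float = CHI_DEFAULT
    nu: float = 3.8e-6          # kinematic viscosity m^2/s
    reference_pressure: float = 0.0
    longitudinal_projection: float = 0.0

    h: float = field(init=False)
    x: np.ndarray = field(init=False)
    A0: np.ndarray = field(init=False)
    b: np.ndarray = field(init=False)
    dbdx: np.ndarray = field(init=False)
    dpsidx: np.ndarray = field(init=False)

    def __post_init__(self):
        if self.n_elements < 1:
            raise ValueError("need at least one element")
        self.h = self.length / self.n_elements
        n = 2 * self.n_elements
        # nodal coordinates: element e spans [e*h, (e+1)*h]
        xe = np.repeat(np.arange(self.n_elements) * self.h, 2)
        xe[1::2] += self.h
        self.x = xe
        s = self.x / self.length if self.length > 0 else np.zeros(n)
        A0 = self.A0_prox + (self.A0_dist - self.A0_prox) * s
        beta = self.beta_prox + (self.beta_dist - self.beta_prox) * s
        self.A0 = A0
        self.b = beta / A0
        psi = self.b * np.sqrt(A0)
        self.dbdx = np.empty(self.n_elements)
        self.dpsidx = np.empty(self.n_elements)
        for e in range(self.n_elements):
            self.dbdx[e] = (self.b[2 * e + 1] - self.b[2 * e]) / self.h
            self.dpsidx[e] = (psi[2 * e + 1] - psi[2 * e]) / self.h

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_elements

    def initial_state(self, p_init: float = 0.0) -> "VesselState":
        """Rest state at uniform transmural pressure ``p_init`` (Pa)."""
        sqA = np.sqrt(self.A0) + (p_init - self.reference_pressure) / self.b
        if np.any(sqA <= 0):
            raise SolverStateError("initial pressure collapses the vessel")
        return VesselState(A=sqA ** 2, Q=np.zeros(self.n_nodes), time=0.0)

    def celerity(self, A: np.ndarray) -> np.ndarray:
        return np.sqrt(self.b * np.sqrt(A) / (2.0 * self.rho))

    def pressure(self, A: np.ndarray, dA_dt: np.ndarray | None = None,
                 p_ext: float = 0.0) -> np.ndarray:
        p = (p_ext + self.reference_pressure
             + self.b * (np.sqrt(A) - np.sqrt(self.A0)))
        if dA_dt is not None and self.gamma_visc != 0.0:
            p = p + self.gamma_visc / (self.A0 * np.sqrt(A)) * dA_dt
        return p

    def max_stable_dt(self, A: np.ndarray, Q: np.ndarray,
                      safety: float = 0.9) -> float:
        lam = np.abs(Q / A) + self.celerity(A)
        # P1 DG + RK2: dt <= h / ((2p+1) max|lambda|), p = 1
        return safety * self.h / (3.0 * float(np.max(lam)))

    def volume(self, A: np.ndarray) -> float:
        """integral A dx by element trapezoid (exact for P1 nodal data)."""
        return float(np.sum((A[0::2] + A[1::2]) * 0.5 * self.h))


@dataclass
class VesselState:
    A: np.ndarray
    Q: np.ndarray
    time: float = 0.0
    dA_dt: np.ndarray | None = None

    def check(self):
        if not np.all(np.isfinite(self.A)) or not np.all(np.isfinite(self.Q)):
            raise SolverStateError("non-finite vessel state")
        if np.any(self.A <= 0):
            raise SolverStateError("negative or zero area")


# ----------------------------------------------------------------------------
# Numba core: single-vessel semidiscrete RHS
# ----------------------------------------------------------------------------

@njit(cache=True)
def _vessel_rhs(A, Q, dA, dQ, h, b, A0, dbdx, dpsidx, chi, rho, nu,
                sin_alpha_g_lam, pvisc, FL1, FL2, FR1, FR2):
    """Nodal P1-DG right-hand side for one vessel.

    ``FL*``/``FR*`` are the boundary fluxes (mass, momentum) at the proximal
    and distal vessel ends, already resolved by characteristics. ``pvisc`` is
    the nodal viscoelastic pressure correction (Pa) from the previous step
    (operator splitting), whose axial gradient is added to the momentum
    source. ``sin_alpha_g_lam = g*sin(alpha)*lambda``.
    """
    n_el = A.shape[0] // 2
    # physical fluxes at nodes
    for e in range(n_el):
        i1 = 2 * e
        i2 = i1 + 1
        # interface fluxes
        if e == 0:
            f1L = FL1
            f2L = FL2
        else:
            jm = i1 - 1  # right node of previous element
            f1L, f2L = _lf_flux(A[jm], Q[jm], b[jm], A[i1], Q[i1], b[i1],
                                chi, rho)
        if e == n_el - 1:
            f1R = FR1
            f2R = FR2
        else:
            jp = i2 + 1
            f1R, f2R = _lf_flux(A[i2], Q[i2], b[i2], A[jp], Q[jp], b[jp],
                                chi, rho)
        F1_1 = Q[i1]
        F1_2 = Q[i2]
        # volume terms by 2-point Gauss quadrature on the P1 interpolants;
        # the geometric (taper) source enters in rest-balanced delta form,
        # so a vessel at A = A0(x), Q = 0 is a discrete equilibrium exactly
        F0_1 = b[i1] * A0[i1] ** 1.5 / (3.0 * rho)
        F0_2 = b[i2] * A0[i2] ** 1.5 / (3.0 * rho)
        dpv = (pvisc[i2] - pvisc[i1]) / h
        dferr = 0.0     # Gauss sum of F2 - F0
        sq1 = 0.0       # Gauss sum of S2 * psi1
        sq2 = 0.0
        for ig in range(2):
            xi = 0.5 - GAUSS_OFF if ig == 0 else 0.5 + GAUSS_OFF
            Ax = A[i1] + (A[i2] - A[i1]) * xi
            Qx = Q[i1] + (Q[i2] - Q[i1]) * xi
            bx = b[i1] + (b[i2] - b[i1]) * xi
            A0x = A0[i1] + (A0[i2] - A0[i1]) * xi
            dferr += (chi * Qx * Qx / Ax
                      + bx * (Ax ** 1.5 - A0x ** 1.5) / (3.0 * rho))
            S2x = (-FRICTION_COEFF * nu * Qx / Ax
                   + Ax * sin_alpha_g_lam
                   - (2.0 / (3.0 * rho)) * (Ax ** 1.5 - A0x ** 1.5)
                   * dbdx[e]
                   + ((Ax - A0x) / rho) * dpsidx[e]
                   - (Ax / rho) * dpv)
            sq1 += S2x * (1.0 - xi)
            sq2 += S2x * xi
        r1m = -(F1_1 + F1_2) / 2.0 + f1L
        r2m = (F1_1 + F1_2) / 2.0 - f1R
        r1q = -dferr / 2.0 + (f2L - F0_1) + (h / 2.0) * sq1
        r2q = dferr / 2.0 - (f2R - F0_2) + (h / 2.0) * sq2
        dA[i1] = (4.0 * r1m - 2.0 * r2m) / h
        dA[i2] = (-2.0 * r1m + 4.0 * r2m) / h
        dQ[i1] = (4.0 * r1q - 2.0 * r2q) / h
        dQ[i2] = (-2.0 * r1q + 4.0 * r2q) / h


@njit(cache=True)
def _lf_flux(Al, Ql, bl, Ar, Qr, br, chi, rho):
    """Local Lax-Friedrichs numerical flux between element faces."""
    cl = _celerity(Al, bl, rho)
    cr = _celerity(Ar, br, rho)
    sl = abs(Ql / Al) + cl
    sr = abs(Qr / Ar) + cr
    smax = sl if sl > sr else sr
    F1l = Ql
    F1r = Qr
    F2l = chi * Ql * Ql / Al + bl * Al ** 1.5 / (3.0 * rho)
    F2r = chi * Qr * Qr / Ar + br * Ar ** 1.5 / (3.0 * rho)
    f1 = 0.5 * (F1l + F1r) - 0.5 * smax * (Ar - Al)
    f2 = 0.5 * (F2l + F2r) - 0.5 * smax * (Qr - Ql)
    return f1, f2


@njit(cache=True)
def _phys_flux(A, Q, b, chi, rho):
    return Q, chi * Q * Q / A + b * A ** 1.5 / (3.0 * rho)


# ----------------------------------------------------------------------------
# Characteristic boundary resolution (numba scalar solvers)
# ----------------------------------------------------------------------------

@njit(cache=True)
def _A_from_W_and_Q(W, Q, b, rho, A_guess, outgoing_plus):
    """Solve for A given the outgoing invariant and a prescribed flow.

    outgoing_plus=True: W = u + 4c known (outlet); u(A) = W - 4 c(A).
    outgoing_plus=False: W = u - 4c known (inlet);  u(A) = W + 4 c(A).
    Solves A*u(A) = Q by damped Newton.
    """
    k = math.sqrt(b / (2.0 * rho))
    sgn = -4.0 if outgoing_plus else 4.0
    A = A_guess
    for _ in range(60):
        c = k * A ** 0.25
        u = W + sgn * c
        g = A * u - Q
        dg = u + sgn * 0.25 * c  # d(Au)/dA = u + A * sgn * c/(4A)
        if dg == 0.0:
            break
        step = g / dg
        if step > 0.5 * A:
            step = 0.5 * A
        elif step < -0.5 * A:
            step = -0.5 * A
        A -= step
        if A <= 0.0:
            A = 1e-12
        if abs(step) < 1e-14 * A + 1e-30:
            break
    return A


@njit(cache=True)
def _A_from_W_terminal(Wp, b, sqrtA0, p_ref, p_ext0d, Zc, rho, A_guess):
    """Outlet coupled to a terminal impedance Zc (Pa s/m^3).

    Q = (p(A) - p_ext0d)/Zc together with u = Wp - 4c(A).
    """
    k = math.sqrt(b / (2.0 * rho))
    A = A_guess
    for _ in range(60):
        c = k * A ** 0.25
        u = Wp - 4.0 * c
        p = p_ref + b * (math.sqrt(A) - sqrtA0)
        g = A * u - (p - p_ext0d) / Zc
        dg = u - c - b / (2.0 * math.sqrt(A)) / Zc
        if dg == 0.0:
            break
        step = g / dg
        if step > 0.5 * A:
            step = 0.5 * A
        elif step < -0.5 * A:
            step = -0.5 * A
        A -= step
        if A <= 0.0:
            A = 1e-12
        if abs(step) < 1e-14 * A + 1e-30:
            break
    c = k * A ** 0.25
    Q = A * (Wp - 4.0 * c)
    return A, Q


@njit(cache=True)
def _A_from_closed_end(W_out, b, rho):
    """Zero-flow end: u = 0, so 4 c(A) = +-W_out; closed-form A."""
    c = abs(W_out) / 4.0
    sqA = 2.0 * rho * c * c / b
    return sqA * sqA


@njit(cache=True)
def _junction_newton(Wp, bp, sqA0p, prefp, Ap0,
                     Wc, bc, sqA0c, prefc, Ac0, nchild, rho, tol, maxit):
    """Mass + total-pressure conservation at a 1-parent/n-children junction.

    Unknowns: parent outlet area and each child inlet area. Parent velocity
    from its outgoing forward invariant, child velocities from their outgoing
    backward invariants. Returns (areas, flows, n_iterations, converged).
    """
    n = nchild + 1
    Av = np.empty(n)
    Av[0] = Ap0
    for i in range(nchild):
        Av[i + 1] = Ac0[i]
    J = np.empty((n, n))
    f = np.empty(n)
    kp = math.sqrt(bp / (2.0 * rho))
    converged = False
    it = 0
    for it in range(maxit):
        cp = kp * Av[0] ** 0.25
        up = Wp - 4.0 * cp
        Qp = Av[0] * up
        ptp = prefp + bp * (math.sqrt(Av[0]) - sqA0p) + 0.5 * rho * up * up
        # residuals
        qsum = 0.0
        for i in range(nchild):
            kc = math.sqrt(bc[i] / (2.0 * rho))
            cc = kc * Av[i + 1] ** 0.25
            uc = Wc[i] + 4.0 * cc
            qsum += Av[i + 1] * uc
        f[0] = Qp - qsum
        for i in range(nchild):
            kc = math.sqrt(bc[i] / (2.0 * rho))
            cc = kc * Av[i + 1] ** 0.25
            uc = Wc[i] + 4.0 * cc
            ptc = (prefc[i] + bc[i] * (math.sqrt(Av[i + 1]) - sqA0c[i])
                   + 0.5 * rho * uc * uc)
            f[i + 1] = ptp - ptc
        scale = abs(Qp) + 1e-8
        ok = abs(f[0]) <= tol * scale
        pscale = abs(ptp) + 1e3
        for i in range(nchild):
            if abs(f[i + 1]) > tol * pscale:
                ok = False
        if ok:
            converged = True
            break
        # Jacobian
        for r in range(n):
            for s in range(n):
                J[r, s] = 0.0
        J[0, 0] = up - cp
        for i in range(nchild):
            kc = math.sqrt(bc[i] / (2.0 * rho))
            cc = kc * Av[i + 1] ** 0.25
            uc = Wc[i] + 4.0 * cc
            J[0, i + 1] = -(uc + cc)
            J[i + 1, 0] = (rho * cp / Av[0]) * (cp - up)
            J[i + 1, i + 1] = -(rho * cc / Av[i + 1]) * (cc + uc)
        # solve J dx = -f (Gaussian elimination, tiny system)
        dx = np.empty(n)
        M = J.copy()
        rhs = -f.copy()
        for col in range(n):
            piv = col
            big = abs(M[col, col])
            for r in range(col + 1, n):
                if abs(M[r, col]) > big:
                    big = abs(M[r, col])
                    piv = r
            if big == 0.0:
                return Av, np.zeros(n), it, False
            if piv != col:
                for s in range(n):
                    tmp = M[col, s]
                    M[col, s] = M[piv, s]
                    M[piv, s] = tmp
                tmp = rhs[col]
                rhs[col] = rhs[piv]
                rhs[piv] = tmp
            for r in range(col + 1, n):
                fac = M[r, col] / M[col, col]
                for s in range(col, n):
                    M[r, s] -= fac * M[col, s]
                rhs[r] -= fac * rhs[col]
        for r in range(n - 1, -1, -1):
            acc = rhs[r]
            for s in range(r + 1, n):
                acc -= M[r, s] * dx[s]
            dx[r] = acc / M[r, r]
        for r in range(n):
            step = dx[r]
            lim = 0.4 * Av[r]
            if step > lim:
                step = lim
            elif step < -lim:
                step = -lim
            Av[r] += step
            if Av[r] <= 0.0:
                Av[r] = 1e-12
    Qv = np.empty(n)
    cp = kp * Av[0] ** 0.25
    Qv[0] = Av[0] * (Wp - 4.0 * cp)
    for i in range(nchild):
        kc = math.sqrt(bc[i] / (2.0 * rho))
        cc = kc * Av[i + 1] ** 0.25
        Qv[i + 1] = Av[i + 1] * (Wc[i] + 4.0 * cc)
    return Av, Qv, it, converged


# ----------------------------------------------------------------------------
# Python-facing operations
# ----------------------------------------------------------------------------

def characteristic_boundary(grid: VesselGrid, state: VesselState, side: str,
                            kind: str, datum: float = 0.0,
                            p_ext0d: float = 0.0,
                            Zc: float = 0.0) -> tuple[float, float]:
    """Resolve well-posed (A, Q) at a vessel end by characteristics.

    The outgoing Riemann invariant is extrapolated from the boundary node and
    combined with the external datum:

    - ``kind='flow'``: prescribed boundary flow (e.g. from the aortic valve);
      ``datum`` is Q in m^3/s.
    - ``kind='pressure'``: prescribed pressure (Pa) at the end.
    - ``kind='closed'``: zero flow (full reflection).
    - ``kind='absorbing'``: incoming invariant frozen at its rest value
      (non-reflecting).
    - ``kind='impedance'``: terminal resistance ``Zc`` (Pa s/m^3) against the
      0D pressure ``p_ext0d`` (Pa).
    """
    A, Q = state.A, state.Q
    if side == "inlet":
        i = 0
        b = grid.b[0]
        A0n = grid.A0[0]
        c = _celerity(A[i], b, grid.rho)
        W = Q[i] / A[i] - 4.0 * c          # outgoing backward invariant
        outgoing_plus = False
    elif side == "outlet":
        i = grid.n_nodes - 1
        b = grid.b[i]
        A0n = grid.A0[i]
        c = _celerity(A[i], b, grid.rho)
        W = Q[i] / A[i] + 4.0 * c          # outgoing forward invariant
        outgoing_plus = True
    else:
        raise ValueError("side must be 'inlet' or 'outlet'")

    if kind == "flow":
        Ab = _A_from_W_and_Q(W, datum, b, grid.rho, A[i], outgoing_plus)
        return Ab, datum
    if kind == "closed":
        Ab = _A_from_closed_end(W, b, grid.rho)
        return Ab, 0.0
    if kind == "pressure":
        sqA = math.sqrt(A0n) + (datum - grid.reference_pressure) / b
        if sqA <= 0:
            raise SolverStateError("prescribed pressure collapses the vessel")
        Ab = sqA * sqA
        cb = _celerity(Ab, b, grid.rho)
        ub = W - 4.0 * cb if outgoing_plus else W + 4.0 * cb
        return Ab, Ab * ub
    if kind == "absorbing":
        c0 = _celerity(A0n, b, grid.rho)
        W_in = -4.0 * c0 if outgoing_plus else 4.0 * c0
        if outgoing_plus:
            ub = 0.5 * (W + W_in)
            cb = (W - W_in) / 8.0
        else:
            ub = 0.5 * (W_in + W)
            cb = (W_in - W) / 8.0
        sqA = 2.0 * grid.rho * cb * cb / b
        Ab = sqA * sqA
        return Ab, Ab * ub
    if kind == "impedance":
        if side != "outlet":
            raise ValueError("impedance coupling applies to the outlet")
        Ab, Qb = _A_from_W_terminal(W, b, math.sqrt(A0n),
                                    grid.reference_pressure, p_ext0d, Zc,
                                    grid.rho, A[i])
        return Ab, Qb
    raise ValueError(f"unknown boundary kind {kind!r}")


def junction_solve(parent: tuple[VesselGrid, VesselState],
                   children: list[tuple[VesselGrid, VesselState]],
                   rho: float | None = None, tol: float = 1e-10,
                   max_iter: int = 50):
    """Couple a parent outlet to child inlets by mass and total-pressure
    conservation plus the outgoing characteristic of every vessel.

    Returns ``(A_parent, Q_parent), [(A_child, Q_child), ...]``.
    """
    pg, ps = parent
    rho = pg.rho if rho is None else rho
    ip = pg.n_nodes - 1
    cp = _celerity(ps.A[ip], pg.b[ip], rho)
    Wp = ps.Q[ip] / ps.A[ip] + 4.0 * cp
    nch = len(children)
    Wc = np.empty(nch)
    bc = np.empty(nch)
    sqA0c = np.empty(nch)
    prefc = np.empty(nch)
    Ac0 = np.empty(nch)
    for k, (cg, cs) in enumerate(children):
        cc = _celerity(cs.A[0], cg.b[0], rho)
        Wc[k] = cs.Q[0] / cs.A[0] - 4.0 * cc
        bc[k] = cg.b[0]
        sqA0c[k] = math.sqrt(cg.A0[0])
        prefc[k] = cg.reference_pressure
        Ac0[k] = cs.A[0]
    Av, Qv, it, ok = _junction_newton(
        Wp, pg.b[ip], math.sqrt(pg.A0[ip]), pg.reference_pressure, ps.A[ip],
        Wc, bc, sqA0c, prefc, Ac0, nch, rho, tol, max_iter)
    if not ok:
        raise JunctionConvergenceError(
            f"junction Newton did not converge in {max_iter} iterations "
            f"(last residual mass defect {Qv[0] - np.sum(Qv[1:]):.3e} m^3/s)")
    return (Av[0], Qv[0]), [(Av[1 + k], Qv[1 + k]) for k in range(nch)]


def advance_vessel(grid: VesselGrid, state: VesselState, dt: float,
                   alpha: float = 0.0,
                   inlet=("closed", 0.0), outlet=("closed", 0.0),
                   check_cfl: bool = True) -> VesselState:
    """Advance a single vessel one time step (2-step RK / Heun).

    ``inlet``/``outlet`` are ``(kind, datum)`` pairs understood by
    :func:`characteristic_boundary`. Used by the verification fixtures; the
    coupled engine advances all vessels and 0D compartments together.
    """
    state.check()
    if check_cfl:
        dt_max = grid.max_stable_dt(state.A, state.Q, safety=1.0)
        if dt > dt_max:
            raise CFLError(
                f"dt={dt:g} exceeds stability bound {dt_max:g} s for this "
                f"vessel (h={grid.h:g} m); reduce dt")
    sin_g_lam = (G_STANDARD * math.sin(alpha)
                 * grid.longitudinal_projection)
    dA_prev = (state.dA_dt if state.dA_dt is not None
               else np.zeros(grid.n_nodes))
    pvisc = (grid.gamma_visc / (grid.A0 * np.sqrt(state.A)) * dA_prev
             if grid.gamma_visc else np.zeros(grid.n_nodes))

    def rhs(A, Q):
        AbL, QbL = characteristic_boundary(
            grid, VesselState(A, Q), "inlet", inlet[0], *_bd_args(inlet))
        AbR, QbR = characteristic_boundary(
            grid, VesselState(A, Q), "outlet", outlet[0], *_bd_args(outlet))
        FL1, FL2 = _phys_flux(AbL, QbL, grid.b[0], grid.chi, grid.rho)
        FR1, FR2 = _phys_flux(AbR, QbR, grid.b[-1], grid.chi, grid.rho)
        dA = np.empty_like(A)
        dQ = np.empty_like(Q)
        _vessel_rhs(A, Q, dA, dQ, grid.h, grid.b, grid.A0, grid.dbdx,
                    grid.dpsidx, grid.chi, grid.rho, grid.nu, sin_g_lam,
                    pvisc, FL1, FL2, FR1, FR2)
        return dA, dQ

    dA1, dQ1 = rhs(state.A, state.Q)
    A1 = state.A + dt * dA1
    Q1 = state.Q + dt * dQ1
    if np.any(A1 <= 0):
        raise SolverStateError("negative area after predictor step")
    dA2, dQ2 = rhs(A1, Q1)
    A_new = state.A + 0.5 * dt * (dA1 + dA2)
    Q_new = state.Q + 0.5 * dt * (dQ1 + dQ2)
    new = VesselState(A=A_new, Q=Q_new, time=state.time + dt,
                      dA_dt=(A_new - state.A) / dt)
    new.check()
    return new


def _bd_args(bd):
    """Normalize boundary spec tuples to characteristic_boundary args."""
    kind = bd[0]
    if kind == "impedance":
        # (kind, p_ext0d_pa, Zc)
        return (0.0, bd[1], bd[2])
    datum = bd[1] if len(bd) > 1 else 0.0
    return (datum,)
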