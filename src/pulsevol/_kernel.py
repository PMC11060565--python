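"""Numba-compiled numerical core of the 0-1D model.

Everything here operates on a *flattened* representation of the coupled model
(plain float64/int64 arrays, CGS units) so the whole time-stepping loop stays
inside compiled code.  The public modules (`pulse_wave_solver`,
`terminal_windkessel`, `elastance_heart`, `simulation`) wrap these functions;
they are not part of the user-facing API.

Governing 1D equations (per vessel, parabolic velocity profile):

    dA/dt + dQ/dx = 0
    dQ/dt + d/dx(Q^2/A + B) = -8 pi nu Q/A + S_geo

with the pressure-integral flux ``B = f sqrt(A0 A) / rho`` induced by the
tube law ``P = P0 + f (1 - sqrt(A0/A))`` and the geometric source

    S_geo = (1/rho) (2 sqrt(A0 A) - A) df/dx + (f sqrt(A)/(rho sqrt(A0))) dA0/dx

so that the rest state A = A0(x), Q = 0 is an exact equilibrium.  The scheme
is the two-step (Richtmyer) Lax-Wendroff variant with sources evaluated at
half points.  Boundary and junction closures use the characteristic
(Riemann-invariant) form of the system:

    W+ = u - 4c  constant along dx/dt = u + c   (outgoing at distal ends)
    W- = u + 4c  constant along dx/dt = u - c   (outgoing at proximal ends)

with the local wave speed ``c = sqrt(f/(2 rho) * sqrt(A0/A))``.

Heart phases are encoded as integers:
0 filling, 1 isovolumic contraction, 2 ejection, 3 aortic valve closing,
4 isovolumic relaxation.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# heart parameter vector layout (CGS)
HP_EMAX, HP_EMIN, HP_TM, HP_A, HP_B, HP_T, HP_V0, HP_VMAX, HP_PLA, \
    HP_RLA, HP_LLA, HP_RLV, HP_LLV, HP_VBBAR = range(14)

# heart state vector layout
HS_VLV, HS_QLA, HS_QLV, HS_VB, HS_TSTAR = range(5)

PH_FILLING, PH_ISOCONTRACT, PH_EJECTION, PH_CLOSING, PH_ISORELAX = range(5)

_EIGHT_PI = 8.0 * np.pi


# ---------------------------------------------------------------------------
# local relations
# ---------------------------------------------------------------------------

@njit(cache=True)
def press(A, A0, f, P0):
    return P0 + f * (1.0 - np.sqrt(A0 / A))


@njit(cache=True)
def dpress(A, A0, f):
    # dP/dA
    return 0.5 * f * np.sqrt(A0) / A ** 1.5


@njit(cache=True)
def wspeed(A, A0, f, rho):
    return np.sqrt(0.5 * f / rho * np.sqrt(A0 / A))


@njit(cache=True)
def flux_q(A, Q, A0, f, rho):
    return Q * Q / A + f * np.sqrt(A0 * A) / rho


@njit(cache=True)
def source_q(A, Q, A0, f, dA0, df, rho, nu):
    fric = -_EIGHT_PI * nu * Q / A
    geo = (2.0 * np.sqrt(A0 * A) - A) * df / rho \
        + f * np.sqrt(A / A0) * dA0 / rho
    return fric + geo


# ---------------------------------------------------------------------------
# interior Lax-Wendroff (Richtmyer) step for one segment
# ---------------------------------------------------------------------------

@njit(cache=True)
def lw_interior(A, Q, An, Qn, i0, n, h0, dx, dt,
                A0n, fn, A0h, fh, dA0h, dfh, rho, nu):
    """Advance interior nodes [i0+1, i0+n-2] of one segment.

    ``A, Q`` are global node arrays at time t; results go to ``An, Qn``.
    Half-point geometry lives in ``A0h..dfh`` starting at offset ``h0``
    (length n-1 for this segment).  Boundary nodes are left untouched.
    """
    lam = dt / dx
    # half-point predictor: U_{i+1/2}^{n+1/2} for i = 0..n-2
    Ah = np.empty(n - 1)
    Qh = np.empty(n - 1)
    for i in range(n - 1):
        g = i0 + i
        a_l, a_r = A[g], A[g + 1]
        q_l, q_r = Q[g], Q[g + 1]
        fq_l = flux_q(a_l, q_l, A0n[g], fn[g], rho)
        fq_r = flux_q(a_r, q_r, A0n[g + 1], fn[g + 1], rho)
        am = 0.5 * (a_l + a_r)
        qm = 0.5 * (q_l + q_r)
        s = source_q(am, qm, A0h[h0 + i], fh[h0 + i],
                     dA0h[h0 + i], dfh[h0 + i], rho, nu)
        Ah[i] = am - 0.5 * lam * (q_r - q_l)
        Qh[i] = qm - 0.5 * lam * (fq_r - fq_l) + 0.5 * dt * s
    # corrector on interior nodes
    for i in range(1, n - 1):
        g = i0 + i
        fq_r = flux_q(Ah[i], Qh[i], A0h[h0 + i], fh[h0 + i], rho)
        fq_l = flux_q(Ah[i - 1], Qh[i - 1], A0h[h0 + i - 1], fh[h0 + i - 1], rho)
        s_r = source_q(Ah[i], Qh[i], A0h[h0 + i], fh[h0 + i],
                       dA0h[h0 + i], dfh[h0 + i], rho, nu)
        s_l = source_q(Ah[i - 1], Qh[i - 1], A0h[h0 + i - 1], fh[h0 + i - 1],
                       dA0h[h0 + i - 1], dfh[h0 + i - 1], rho, nu)
        An[g] = A[g] - lam * (Qh[i] - Qh[i - 1])
        Qn[g] = Q[g] - lam * (fq_r - fq_l) + 0.5 * dt * (s_r + s_l)


# ---------------------------------------------------------------------------
# characteristic extrapolation (foot interpolation at old time level)
# ---------------------------------------------------------------------------

@njit(cache=True)
def foot_w_plus(A, Q, iend, A0n, fn, rho, nu, dx, dt):
    """Outgoing invariant W+ = u - 4c carried to a distal end (node iend).

    Quadratic interpolation at the characteristic foot, plus the friction
    source integrated along the characteristic (du/dt = -8 pi nu u / A),
    which would otherwise bias the boundary flux systematically.
    """
    u2 = Q[iend] / A[iend]
    c2 = wspeed(A[iend], A0n[iend], fn[iend], rho)
    u1 = Q[iend - 1] / A[iend - 1]
    c1 = wspeed(A[iend - 1], A0n[iend - 1], fn[iend - 1], rho)
    u0 = Q[iend - 2] / A[iend - 2]
    c0 = wspeed(A[iend - 2], A0n[iend - 2], fn[iend - 2], rho)
    th = (u2 + c2) * dt / dx
    if th > 1.0:
        th = 1.0
    w2 = u2 - 4.0 * c2
    w1 = u1 - 4.0 * c1
    w0 = u0 - 4.0 * c0
    w = w2 + th * (w1 - w2) + 0.5 * th * (th - 1.0) * (w0 - 2.0 * w1 + w2)
    uf = u2 + th * (u1 - u2)
    af = A[iend] + th * (A[iend - 1] - A[iend])
    return w - dt * _EIGHT_PI * nu * uf / af


@njit(cache=True)
def foot_w_minus(A, Q, i0, A0n, fn, rho, nu, dx, dt):
    """Outgoing invariant W- = u + 4c carried to a proximal end (node i0)."""
    u0 = Q[i0] / A[i0]
    c0 = wspeed(A[i0], A0n[i0], fn[i0], rho)
    u1 = Q[i0 + 1] / A[i0 + 1]
    c1 = wspeed(A[i0 + 1], A0n[i0 + 1], fn[i0 + 1], rho)
    u2 = Q[i0 + 2] / A[i0 + 2]
    c2 = wspeed(A[i0 + 2], A0n[i0 + 2], fn[i0 + 2], rho)
    th = (c0 - u0) * dt / dx
    if th > 1.0:
        th = 1.0
    if th < 0.0:
        th = 0.0
    w0 = u0 + 4.0 * c0
    w1 = u1 + 4.0 * c1
    w2 = u2 + 4.0 * c2
    w = w0 + th * (w1 - w0) + 0.5 * th * (th - 1.0) * (w2 - 2.0 * w1 + w0)
    uf = u0 + th * (u1 - u0)
    af = A[i0] + th * (A[i0 + 1] - A[i0])
    return w - dt * _EIGHT_PI * nu * uf / af


# ---------------------------------------------------------------------------
# boundary closures
# ---------------------------------------------------------------------------

@njit(cache=True)
def inlet_area(Aguess, Qimp, wminus, A0, f, rho):
    """Solve Qimp/A + 4 c(A) = W- for the inlet area (monotone Newton)."""
    A = Aguess
    for _ in range(50):
        c = wspeed(A, A0, f, rho)
        g = Qimp / A + 4.0 * c - wminus
        gp = -Qimp / (A * A) - c / A
        step = g / gp
        An = A - step
        if An < 0.1 * A:
            An = 0.1 * A
        elif An > 10.0 * A:
            An = 10.0 * A
        if abs(An - A) < 1e-14 * A:
            A = An
            break
        A = An
    return A


@njit(cache=True)
def terminal_closure(Aold, wplus, A0, f, P0, rho,
                     R1, R2, CT, PT, Pend, Qend, dt):
    """Couple the outgoing characteristic to the Windkessel update.

    Returns (A, Q, P) at the terminal node at t+dt.  The Windkessel relation
    is the explicit-Euler update of
    R1 R2 C dQ/dt = R2 C dP/dt + (P - PT) - (R1+R2) Q with dQ/dt
    finite-differenced between the old and new end flows.
    """
    relax = dt / (R2 * CT) * ((R1 + R2) * Qend - (Pend - PT))
    A = Aold
    for _ in range(50):
        c = wspeed(A, A0, f, rho)
        u = wplus + 4.0 * c
        Qn = A * u
        Pwk = Pend + R1 * (Qn - Qend) + relax
        h = press(A, A0, f, P0) - Pwk
        hp = dpress(A, A0, f) - R1 * (wplus + 3.0 * c)
        An = A - h / hp
        if An < 0.1 * A:
            An = 0.1 * A
        elif An > 10.0 * A:
            An = 10.0 * A
        if abs(An - A) < 1e-14 * A:
            A = An
            break
        A = An
    c = wspeed(A, A0, f, rho)
    Qn = A * (wplus + 4.0 * c)
    Pn = Pend + R1 * (Qn - Qend) + relax
    return A, Qn, Pn


@njit(cache=True)
def junction_newton(Ap0, A10, A20, wp, w1, w2,
                    A0p, fp, A01, f1, A02, f2, P0, rho, tol, maxit):
    """Solve the bifurcation interface system.

    Unknowns: areas (Ap, A1, A2) at the parent distal end and the two daughter
    proximal ends.  Flows follow from the outgoing characteristics
    ``Qp = Ap (wp + 4 cp)``, ``Qi = Ai (wi - 4 ci)``; the residuals enforce
    pressure continuity (twice) and mass conservation.  Returns
    (Ap, Qp, A1, Q1, A2, Q2, converged).
    """
    Ap, A1, A2 = Ap0, A10, A20
    ok = False
    for _ in range(maxit):
        cp = wspeed(Ap, A0p, fp, rho)
        c1 = wspeed(A1, A01, f1, rho)
        c2 = wspeed(A2, A02, f2, rho)
        Qp = Ap * (wp + 4.0 * cp)
        Q1 = A1 * (w1 - 4.0 * c1)
        Q2 = A2 * (w2 - 4.0 * c2)
        Pp = press(Ap, A0p, fp, P0)
        P1 = press(A1, A01, f1, P0)
        P2 = press(A2, A02, f2, P0)
        F1 = Pp - P1
        F2 = Pp - P2
        F3 = Qp - Q1 - Q2
        # residual scales: characteristic magnitudes, not the (possibly ~0)
        # local values, so the tolerance is attainable in double precision
        pscale = abs(Pp) + 1.0
        qscale = Ap * cp + A1 * c1 + A2 * c2
        if abs(F1) < tol * pscale and abs(F2) < tol * pscale and abs(F3) < tol * qscale:
            ok = True
            break
        dPp = dpress(Ap, A0p, fp)
        dP1 = dpress(A1, A01, f1)
        dP2 = dpress(A2, A02, f2)
        dQp = wp + 3.0 * cp
        dQ1 = w1 - 3.0 * c1
        dQ2 = w2 - 3.0 * c2
        # Newton system J dx = F with J = [[dPp,-dP1,0],[dPp,0,-dP2],[dQp,-dQ1,-dQ2]]
        a11, a12, a13, b1 = dPp, -dP1, 0.0, F1
        a21, a22, a23, b2 = dPp, 0.0, -dP2, F2
        a31, a32, a33, b3 = dQp, -dQ1, -dQ2, F3
        # eliminate column 1 (a11 != 0 since dPp > 0)
        m = a21 / a11
        a22 -= m * a12
        a23 -= m * a13
        b2 -= m * b1
        m = a31 / a11
        a32 -= m * a12
        a33 -= m * a13
        b3 -= m * b1
        # eliminate column 2
        if abs(a22) < 1e-300:
            break
        m = a32 / a22
        a33 -= m * a23
        b3 -= m * b2
        if abs(a33) < 1e-300:
            break
        x3 = b3 / a33
        x2 = (b2 - a23 * x3) / a22
        x1 = (b1 - a12 * x2 - a13 * x3) / a11
        Ap_n = Ap - x1
        A1_n = A1 - x2
        A2_n = A2 - x3
        if Ap_n < 0.1 * Ap:
            Ap_n = 0.1 * Ap
        if A1_n < 0.1 * A1:
            A1_n = 0.1 * A1
        if A2_n < 0.1 * A2:
            A2_n = 0.1 * A2
        Ap, A1, A2 = Ap_n, A1_n, A2_n
    cp = wspeed(Ap, A0p, fp, rho)
    c1 = wspeed(A1, A01, f1, rho)
    c2 = wspeed(A2, A02, f2, rho)
    return Ap, Ap * (wp + 4.0 * cp), A1, A1 * (w1 - 4.0 * c1), \
        A2, A2 * (w2 - 4.0 * c2), ok


# ---------------------------------------------------------------------------
# elastance left ventricle
# ---------------------------------------------------------------------------

@njit(cache=True)
def activation(t, tm, a, b):
    """Dimensionless activation: a sin(pi t/tm) - b sin(2 pi t/tm) on [0, tm), else 0."""
    if t < tm:
        return a * np.sin(np.pi * t / tm) - b * np.sin(2.0 * np.pi * t / tm)
    return 0.0


@njit(cache=True)
def elastance_cgs(t, hp):
    phi = activation(t, hp[HP_TM], hp[HP_A], hp[HP_B])
    return hp[HP_EMIN] * (1.0 - phi) + hp[HP_EMAX] * phi


@njit(cache=True)
def _heart_rhs(phase, V, Qla, Qlv, t, Pa, hp):
    E = elastance_cgs(t, hp)
    Plv = E * (V - hp[HP_V0])
    dV = 0.0
    dQla = 0.0
    dQlv = 0.0
    if phase == PH_FILLING:
        dQla = (hp[HP_PLA] - Plv - hp[HP_RLA] * Qla) / hp[HP_LLA]
        dV = Qla
    elif phase == PH_EJECTION or phase == PH_CLOSING:
        dQlv = (Plv - Pa - hp[HP_RLV] * Qlv) / hp[HP_LLV]
        dV = -Qlv
    return dV, dQla, dQlv


@njit(cache=True)
def heart_rk4(phase, hs, hp, Pa, t, dt):
    """One classical RK4 step of the active-phase ODEs; no transition checks.

    Mutates ``hs`` in place (volume, mitral and aortic flow).
    """
    V, Qla, Qlv = hs[HS_VLV], hs[HS_QLA], hs[HS_QLV]
    k1v, k1a, k1l = _heart_rhs(phase, V, Qla, Qlv, t, Pa, hp)
    k2v, k2a, k2l = _heart_rhs(phase, V + 0.5 * dt * k1v, Qla + 0.5 * dt * k1a,
                               Qlv + 0.5 * dt * k1l, t + 0.5 * dt, Pa, hp)
    k3v, k3a, k3l = _heart_rhs(phase, V + 0.5 * dt * k2v, Qla + 0.5 * dt * k2a,
                               Qlv + 0.5 * dt * k2l, t + 0.5 * dt, Pa, hp)
    k4v, k4a, k4l = _heart_rhs(phase, V + dt * k3v, Qla + dt * k3a,
                               Qlv + dt * k3l, t + dt, Pa, hp)
    hs[HS_VLV] = V + dt / 6.0 * (k1v + 2.0 * k2v + 2.0 * k3v + k4v)
    hs[HS_QLA] = Qla + dt / 6.0 * (k1a + 2.0 * k2a + 2.0 * k3a + k4a)
    hs[HS_QLV] = Qlv + dt / 6.0 * (k1l + 2.0 * k2l + 2.0 * k3l + k4l)


@njit(cache=True)
def heart_step(phase, hs, hp, Pa, t, dt):
    """RK4 advance + valve state-machine transition checks.

    Returns the (possibly new) phase.  Mitral valve closes when the ventricle
    reaches its maximal volume (or, as a robustness guard, if mitral flow
    would reverse); aortic valve opens when LV pressure exceeds root pressure,
    begins closing at the first backflow and shuts fully once the accumulated
    backflow volume exceeds the allowance.
    """
    qlv_old = hs[HS_QLV]
    heart_rk4(phase, hs, hp, Pa, t, dt)
    t_new = t + dt
    E = elastance_cgs(t_new if t_new < hp[HP_T] else t_new - hp[HP_T], hp)
    Plv = E * (hs[HS_VLV] - hp[HP_V0])
    if phase == PH_FILLING:
        if hs[HS_VLV] > hp[HP_VMAX] or hs[HS_QLA] < 0.0:
            hs[HS_QLA] = 0.0
            return PH_ISOCONTRACT
    elif phase == PH_ISOCONTRACT:
        if Plv > Pa:
            hs[HS_QLV] = 0.0
            return PH_EJECTION
    elif phase == PH_EJECTION:
        if hs[HS_QLV] < 0.0:
            hs[HS_VB] = 0.0
            hs[HS_TSTAR] = t_new
            return PH_CLOSING
    elif phase == PH_CLOSING:
        q0 = qlv_old if qlv_old < 0.0 else 0.0
        q1 = hs[HS_QLV] if hs[HS_QLV] < 0.0 else 0.0
        hs[HS_VB] += -0.5 * (q0 + q1) * dt
        if hs[HS_VB] > hp[HP_VBBAR]:
            hs[HS_QLV] = 0.0
            return PH_ISORELAX
    else:  # PH_ISORELAX
        if Plv < hp[HP_PLA]:
            hs[HS_QLA] = 0.0
            return PH_FILLING
    return phase


# ---------------------------------------------------------------------------
# full-model cycle driver
# ---------------------------------------------------------------------------

@njit(cache=True)
def run_one_cycle(A, Q, An, Qn,
                  off, nn, hoff, dxs,
                  A0n, fn, A0h, fh, dA0h, dfh,
                  jparent, jd1, jd2,
                  tseg, wR1, wR2, wCT, wPT, wPend, wQend,
                  hs, phase0, hp,
                  rho, nu, P0, dt, nsteps, site_node,
                  site_p, q_root, p_root, vlv_tr,
                  rec_stride, Arec, Qrec):
    """Advance the coupled model through one full cardiac cycle.

    State arrays (A, Q, Windkessel states, heart state) are updated in place.
    Per-step traces of site pressure, imposed root flow, root pressure and LV
    volume are written to the provided arrays; if ``rec_stride > 0`` the full
    node state is snapshotted every ``rec_stride`` steps into Arec/Qrec.
    Returns (phase, V_in, V_out_total, ok); ok=False flags a Newton failure
    or non-physical state.
    """
    nseg = off.shape[0] - 1
    njun = jparent.shape[0]
    nterm = tseg.shape[0]
    phase = phase0
    v_in = 0.0
    v_out = 0.0
    ok = True
    q_imp_old = hs[HS_QLV] if (phase == PH_EJECTION or phase == PH_CLOSING) else 0.0
    for k in range(nsteps):
        t = k * dt
        # interior update, all segments
        for s in range(nseg):
            lw_interior(A, Q, An, Qn, off[s], nn[s], hoff[s], dxs[s], dt,
                        A0n, fn, A0h, fh, dA0h, dfh, rho, nu)
        # bifurcations
        for j in range(njun):
            sp, s1, s2 = jparent[j], jd1[j], jd2[j]
            ip = off[sp] + nn[sp] - 1
            i1 = off[s1]
            i2 = off[s2]
            wp = foot_w_plus(A, Q, ip, A0n, fn, rho, nu, dxs[sp], dt)
            w1 = foot_w_minus(A, Q, i1, A0n, fn, rho, nu, dxs[s1], dt)
            w2 = foot_w_minus(A, Q, i2, A0n, fn, rho, nu, dxs[s2], dt)
            Ap, Qp, A1, Q1, A2, Q2, conv = junction_newton(
                A[ip], A[i1], A[i2], wp, w1, w2,
                A0n[ip], fn[ip], A0n[i1], fn[i1], A0n[i2], fn[i2],
                P0, rho, 1e-12, 40)
            if not conv:
                ok = False
            An[ip], Qn[ip] = Ap, Qp
            An[i1], Qn[i1] = A1, Q1
            An[i2], Qn[i2] = A2, Q2
        # terminal Windkessels
        for m in range(nterm):
            s = tseg[m]
            ie = off[s] + nn[s] - 1
            wpl = foot_w_plus(A, Q, ie, A0n, fn, rho, nu, dxs[s], dt)
            At, Qt, Pt = terminal_closure(A[ie], wpl, A0n[ie], fn[ie], P0, rho,
                                          wR1[m], wR2[m], wCT[m], wPT[m],
                                          wPend[m], wQend[m], dt)
            An[ie], Qn[ie] = At, Qt
            v_out += 0.5 * (wQend[m] + Qt) * dt
            wPend[m], wQend[m] = Pt, Qt
        # heart: root pressure from current (old-time) solution, then RK4 + valves
        i_root = off[0]
        Pa = press(A[i_root], A0n[i_root], fn[i_root], P0)
        phase = heart_step(phase, hs, hp, Pa, t, dt)
        q_imp = hs[HS_QLV] if (phase == PH_EJECTION or phase == PH_CLOSING) else 0.0
        # root inlet closure
        wm = foot_w_minus(A, Q, i_root, A0n, fn, rho, nu, dxs[0], dt)
        Ain = inlet_area(A[i_root], q_imp, wm, A0n[i_root], fn[i_root], rho)
        An[i_root], Qn[i_root] = Ain, q_imp
        v_in += 0.5 * (q_imp_old + q_imp) * dt
        q_imp_old = q_imp
        # commit
        for g in range(A.shape[0]):
            A[g] = An[g]
            Q[g] = Qn[g]
        if hs[HS_VLV] <= 0.0 or not np.isfinite(A[i_root]):
            ok = False
            return phase, v_in, v_out, ok
        # traces
        site_p[k] = press(A[site_node], A0n[site_node], fn[site_node], P0)
        q_root[k] = q_imp
        p_root[k] = press(A[i_root], A0n[i_root], fn[i_root], P0)
        vlv_tr[k] = hs[HS_VLV]
        if rec_stride > 0 and k % rec_stride == 0:
            r = k // rec_stride
            for g in range(A.shape[0]):
                Arec[r, g] = A[g]
                Qrec[r, g] = Q[g]
    return phase, v_in, v_out, ok


@njit(cache=True)
def tree_volume(A, off, nn, dxs):
    """Total blood volume of the 1D domain (trapezoid over each segment)."""
    v = 0.0
    for s in range(off.shape[0] - 1):
        i0, n = off[s], nn[s]
        acc = 0.5 * (A[i0] + A[i0 + n - 1])
        for i in range(1, n - 1):
            acc += A[i0 + i]
        v += acc * dxs[s]
    return v
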