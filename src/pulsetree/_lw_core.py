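"""Compiled inner loop of the 1-D haemodynamics solver.

Everything here operates on flat float64 arrays laid out vessel-by-vessel
(``off[i]`` is the first grid index of vessel i, ``nn[i]`` its point count)
so the whole network advances in one compiled call per time step.

State is (A, q) per grid point.  The interior update is the two-step
(Richtmyer) Lax-Wendroff scheme in conservation form

    U_t + F(U)_x = S(U),   U = (A, q),
    F = (q,  q^2/A + (4/3rho) f sqrt(A0 A)),
    S = (0, -2 pi nu R q / (delta A) + G),

where f(x) = Eh/r0 is the wall stiffness, R = sqrt(A/pi) and G collects the
geometric source terms produced by writing the pressure gradient of a tapered
vessel in conservation form.  Boundary points are closed with outgoing
Riemann-invariant extrapolation (W+- = u -+ 4c, c = sqrt(2f/3rho)(A0/A)^(1/4))
combined with the physical condition: prescribed inflow at the root, pressure
continuity + mass conservation at junctions (Newton), and the structured-tree
convolution p - p0 = z (*) q at terminals (Newton).
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_CFL = 1
STATUS_NEG_AREA = 2
STATUS_JUNCTION = 3
STATUS_INLET = 4
STATUS_OUTLET = 5

_SQRT_PI = np.sqrt(np.pi)


@njit(cache=True)
def _wavespeed(A, A0, f, rho):
    # sqrt(2f/3rho) * (A0/A)^(1/4); nested sqrt beats a float power
    return np.sqrt(2.0 * f / (3.0 * rho)) * np.sqrt(np.sqrt(A0 / A))


@njit(cache=True)
def _pressure(A, A0, f, p0):
    return p0 + (4.0 / 3.0) * f * (1.0 - np.sqrt(A0 / A))


@njit(cache=True)
def _dpdA(A, A0, f):
    return (2.0 / 3.0) * f * np.sqrt(A0) / (A * np.sqrt(A))


@njit(cache=True)
def _flux2(A, q, A0s, f, rho):
    # A0s = sqrt(A0); momentum flux q^2/A + B with B = (4/3rho) f sqrt(A0 A)
    return q * q / A + (4.0 / (3.0 * rho)) * f * A0s * np.sqrt(A)


@njit(cache=True)
def _source2(A, q, A0s, f, fr, drdx, rho, nu, delta):
    # friction (Stokes layer) + geometric taper/stiffness-gradient terms
    fric = -2.0 * np.pi * nu * np.sqrt(A / np.pi) * q / (delta * A)
    geo = (4.0 / (3.0 * rho)) * (
        2.0 * np.sqrt(A) * (_SQRT_PI * f + A0s * fr) - A * fr
    ) * drdx
    return fric + geo


@njit(cache=True)
def lw_interior(A, q, An, qn, A0s, f, fr, drdx, A0sh, fh, frh, drdxh,
                dt, dx, rho, nu, delta, Ah, qh):
    """Richtmyer two-step update of interior points 1..N-2 of one vessel.

    A, q: time-n state (length N); An, qn: output arrays (only 1..N-2 set).
    Geometry arrays with an ``h`` suffix live on the N-1 half points; Ah, qh
    are caller-provided scratch buffers of length >= N-1.
    """
    N = A.shape[0]
    for j in range(N - 1):
        F2a = _flux2(A[j], q[j], A0s[j], f[j], rho)
        F2b = _flux2(A[j + 1], q[j + 1], A0s[j + 1], f[j + 1], rho)
        S2a = _source2(A[j], q[j], A0s[j], f[j], fr[j], drdx[j], rho, nu, delta)
        S2b = _source2(A[j + 1], q[j + 1], A0s[j + 1], f[j + 1], fr[j + 1],
                       drdx[j + 1], rho, nu, delta)
        Ah[j] = 0.5 * (A[j] + A[j + 1]) - 0.5 * dt / dx * (q[j + 1] - q[j])
        qh[j] = (0.5 * (q[j] + q[j + 1]) - 0.5 * dt / dx * (F2b - F2a)
                 + 0.25 * dt * (S2a + S2b))
        if Ah[j] <= 0.0:
            return STATUS_NEG_AREA
    for j in range(1, N - 1):
        F2l = _flux2(Ah[j - 1], qh[j - 1], A0sh[j - 1], fh[j - 1], rho)
        F2r = _flux2(Ah[j], qh[j], A0sh[j], fh[j], rho)
        S2l = _source2(Ah[j - 1], qh[j - 1], A0sh[j - 1], fh[j - 1], frh[j - 1],
                       drdxh[j - 1], rho, nu, delta)
        S2r = _source2(Ah[j], qh[j], A0sh[j], fh[j], frh[j], drdxh[j], rho, nu, delta)
        An[j] = A[j] - dt / dx * (qh[j] - qh[j - 1])
        qn[j] = q[j] - dt / dx * (F2r - F2l) + 0.5 * dt * (S2l + S2r)
        if An[j] <= 0.0:
            return STATUS_NEG_AREA
    return STATUS_OK


@njit(cache=True)
def _foot_state(A, q, A0, f, fr, drdx, o, N, dx, xf, rho, nu, delta):
    """Interpolate the time-n state and geometry at position xf.

    Returns (u, c, src_common, cxe) where src_common = phi_fric - p_x^e/rho
    and cxe = dc/dx at fixed A; together these give the rate of change of the
    Riemann invariants W+- = u -+ 4c along their characteristics,
    dW+-/dt = src_common -+ 4 cxe (u +- c), which is nonzero for tapered,
    frictional vessels and must be integrated along the extrapolation path.
    """
    s = xf / dx
    j = int(s)
    if j < 0:
        j = 0
    if j > N - 2:
        j = N - 2
    w = s - j
    if w < 0.0:
        w = 0.0
    if w > 1.0:
        w = 1.0
    Af = (1.0 - w) * A[o + j] + w * A[o + j + 1]
    qf = (1.0 - w) * q[o + j] + w * q[o + j + 1]
    A0f = (1.0 - w) * A0[o + j] + w * A0[o + j + 1]
    ff = (1.0 - w) * f[o + j] + w * f[o + j + 1]
    frf = (1.0 - w) * fr[o + j] + w * fr[o + j + 1]
    drf = (1.0 - w) * drdx[o + j] + w * drdx[o + j + 1]
    u = qf / Af
    c = _wavespeed(Af, A0f, ff, rho)
    r0f = np.sqrt(A0f / np.pi)
    fx = frf * drf                      # d(Eh/r0)/dx
    A0x_over_A0 = 2.0 * drf / r0f       # dA0/dx / A0
    sq = np.sqrt(A0f / Af)
    pxe = (4.0 / 3.0) * (fx * (1.0 - sq) - ff * 0.5 * A0x_over_A0 * sq)
    cxe = c * (0.5 * fx / ff + 0.25 * A0x_over_A0)
    fric = -2.0 * np.pi * nu * np.sqrt(Af / np.pi) * u / (delta * Af)
    return u, c, fric - pxe / rho, cxe


@njit(cache=True)
def _outgoing_plus(A, q, A0, f, fr, drdx, o, N, dx, dt, rho, nu, delta):
    """W+ = u - 4c carried to the vessel outlet at t^{n+1} (with sources)."""
    L = (N - 1) * dx
    ib = o + N - 1
    u = q[ib] / A[ib]
    c = _wavespeed(A[ib], A0[ib], f[ib], rho)
    lam = u + c
    uf = u
    cf = c
    src = 0.0
    cxe = 0.0
    for _ in range(2):
        xf = L - lam * dt
        if xf < 0.0:
            xf = 0.0
        uf, cf, src, cxe = _foot_state(A, q, A0, f, fr, drdx, o, N, dx, xf, rho, nu, delta)
        lam = 0.5 * (u + c + uf + cf)
    xf = L - lam * dt
    if xf < 0.0:
        xf = 0.0
    uf, cf, src, cxe = _foot_state(A, q, A0, f, fr, drdx, o, N, dx, xf, rho, nu, delta)
    return uf - 4.0 * cf + dt * (src - 4.0 * cxe * lam)


@njit(cache=True)
def _outgoing_minus(A, q, A0, f, fr, drdx, o, N, dx, dt, rho, nu, delta):
    """W- = u + 4c carried to the vessel inlet at t^{n+1} (with sources)."""
    u = q[o] / A[o]
    c = _wavespeed(A[o], A0[o], f[o], rho)
    lam = u - c
    uf = u
    cf = c
    src = 0.0
    cxe = 0.0
    for _ in range(2):
        xf = -lam * dt
        if xf > (N - 1) * dx:
            xf = (N - 1) * dx
        if xf < 0.0:
            xf = 0.0
        uf, cf, src, cxe = _foot_state(A, q, A0, f, fr, drdx, o, N, dx, xf, rho, nu, delta)
        lam = 0.5 * (u - c + uf - cf)
    xf = -lam * dt
    if xf > (N - 1) * dx:
        xf = (N - 1) * dx
    if xf < 0.0:
        xf = 0.0
    uf, cf, src, cxe = _foot_state(A, q, A0, f, fr, drdx, o, N, dx, xf, rho, nu, delta)
    return uf + 4.0 * cf + dt * (src + 4.0 * cxe * lam)


@njit(cache=True)
def _inlet_solve(qin, Wm, Ag, A0b, fb, rho):
    """Scalar Newton for A at the root inlet: u A = qin, u = Wm - 4c(A)."""
    A = Ag
    for _ in range(40):
        c = _wavespeed(A, A0b, fb, rho)
        u = Wm - 4.0 * c
        g = A * u - qin
        dg = u + c  # d(Au)/dA with du/dA = c/A
        if dg == 0.0:
            return -1.0
        step = g / dg
        A -= step
        if A <= 0.0:
            A = 0.1 * (A + step)  # damped fallback keeps A positive
        if abs(g) <= 1e-12 * (abs(qin) + 1.0):
            return A
    if abs(A * (Wm - 4.0 * _wavespeed(A, A0b, fb, rho)) - qin) <= 1e-9 * (abs(qin) + 1.0):
        return A
    return -1.0


@njit(cache=True)
def _outlet_solve(Wp, z0, H, Ag, A0b, fb, rho, p0):
    """Scalar Newton for A at a terminal outlet.

    Conditions: u = Wp + 4c(A) (outgoing characteristic) and the convolution
    closure p(A) - p0 = z0 * A u + H (H = contribution of past flows).
    """
    A = Ag
    scale = (4.0 / 3.0) * fb
    for _ in range(60):
        c = _wavespeed(A, A0b, fb, rho)
        u = Wp + 4.0 * c
        g = _pressure(A, A0b, fb, p0) - p0 - z0 * A * u - H
        dg = _dpdA(A, A0b, fb) - z0 * (u - c)  # d(Au)/dA = u - c (du/dA=-c/A)
        if dg == 0.0:
            return -1.0
        step = g / dg
        A -= step
        if A <= 0.0:
            A = 0.1 * (A + step)
        if abs(g) <= 1e-12 * scale:
            return A
    c = _wavespeed(A, A0b, fb, rho)
    if abs(_pressure(A, A0b, fb, p0) - p0 - z0 * A * (Wp + 4.0 * c) - H) <= 1e-8 * scale:
        return A
    return -1.0


@njit(cache=True)
def _junction_solve(Wp, Wm1, Wm2, two, Ap0, Ad10, Ad20,
                    A0p, fp, A01, f1, A02, f2, rho, out):
    """Newton solve of the junction conditions at t^{n+1}.

    Unknowns: areas at the parent outlet and daughter inlets; velocities are
    slaved to the outgoing invariants u_p = Wp + 4c, u_di = Wmi - 4c.
    Residuals: mass q_p - sum q_di (scaled) and pressure continuity (scaled).
    Writes (Ap, qp, A1, q1, A2, q2) into ``out``; returns True on convergence.
    """
    Ap = Ap0
    A1 = Ad10
    A2 = Ad20
    pscale = (4.0 / 3.0) * fp
    for _ in range(30):
        cp = _wavespeed(Ap, A0p, fp, rho)
        up = Wp + 4.0 * cp
        c1 = _wavespeed(A1, A01, f1, rho)
        u1 = Wm1 - 4.0 * c1
        qsum = u1 * A1
        if two:
            c2 = _wavespeed(A2, A02, f2, rho)
            u2 = Wm2 - 4.0 * c2
            qsum += u2 * A2
        r0 = up * Ap - qsum
        r1 = _pressure(Ap, A0p, fp, 0.0) - _pressure(A1, A01, f1, 0.0)
        qref = abs(up * Ap) + abs(qsum) + 1.0
        if two:
            r2 = _pressure(Ap, A0p, fp, 0.0) - _pressure(A2, A02, f2, 0.0)
            # 3x3 Newton via Cramer
            a00 = up - cp          # d(up*Ap)/dAp, dup/dAp = -cp/Ap
            a01 = -(u1 + c1)
            a02 = -(u2 + c2)
            a10 = _dpdA(Ap, A0p, fp)
            a11 = -_dpdA(A1, A01, f1)
            a20 = a10
            a22 = -_dpdA(A2, A02, f2)
            det = a00 * a11 * a22 - a01 * a10 * a22 - a02 * a11 * a20
            if det == 0.0:
                return False
            dAp = (r0 * a11 * a22 - a01 * r1 * a22 - a02 * a11 * r2) / det
            dA1 = (a00 * r1 * a22 - r0 * a10 * a22 + a02 * (a10 * r2 - a20 * r1)) / det
            dA2 = (a00 * a11 * r2 - a01 * (a10 * r2 - a20 * r1) - r0 * a11 * a20) / det
            A2 -= dA2
            if A2 <= 0.0:
                A2 = 0.1 * (A2 + dA2)
        else:
            a00 = up - cp
            a01 = -(u1 + c1)
            a10 = _dpdA(Ap, A0p, fp)
            a11 = -_dpdA(A1, A01, f1)
            det = a00 * a11 - a01 * a10
            if det == 0.0:
                return False
            dAp = (r0 * a11 - a01 * r1) / det
            dA1 = (a00 * r1 - a10 * r0) / det
            r2 = 0.0
        Ap -= dAp
        A1 -= dA1
        if Ap <= 0.0:
            Ap = 0.1 * (Ap + dAp)
        if A1 <= 0.0:
            A1 = 0.1 * (A1 + dA1)
        if (abs(r0) <= 1e-10 * qref and abs(r1) <= 1e-10 * pscale
                and abs(r2) <= 1e-10 * pscale):
            cp = _wavespeed(Ap, A0p, fp, rho)
            up = Wp + 4.0 * cp
            c1 = _wavespeed(A1, A01, f1, rho)
            u1 = Wm1 - 4.0 * c1
            out[0] = Ap
            out[1] = up * Ap
            out[2] = A1
            out[3] = u1 * A1
            if two:
                c2 = _wavespeed(A2, A02, f2, rho)
                u2 = Wm2 - 4.0 * c2
                out[4] = A2
                out[5] = u2 * A2
            return True
    return False


@njit(cache=True)
def step_network(A, q, An, qn, off, nn, dxv,
                 A0, A0s, f, fr, drdx, A0sh, fh, frh, drdxh, offh,
                 parents, child1, child2, root, term_idx, term_z0, term_hist,
                 hist_pos, kern, qin_next,
                 dt, rho, nu, delta, p0, Ah, qh):
    """Advance the whole network one time step.  Returns (status, where).

    term_hist is a circular buffer of outlet flows per terminal with current
    write position hist_pos (holding time-n values); kern rows are the
    time-domain impedance kernels.
    """
    nv = off.shape[0]
    n_t = kern.shape[1]

    # CFL check on the time-n state
    for i in range(nv):
        o = off[i]
        N = nn[i]
        for j in range(N):
            a = A[o + j]
            if a <= 0.0:
                return STATUS_NEG_AREA, i
            sp = abs(q[o + j] / a) + _wavespeed(a, A0[o + j], f[o + j], rho)
            if sp * dt / dxv[i] > 1.0:
                return STATUS_CFL, i

    # interior points
    for i in range(nv):
        o = off[i]
        oh = offh[i]
        N = nn[i]
        st = lw_interior(A[o:o + N], q[o:o + N], An[o:o + N], qn[o:o + N],
                         A0s[o:o + N], f[o:o + N], fr[o:o + N], drdx[o:o + N],
                         A0sh[oh:oh + N - 1], fh[oh:oh + N - 1],
                         frh[oh:oh + N - 1], drdxh[oh:oh + N - 1],
                         dt, dxv[i], rho, nu, delta, Ah, qh)
        if st != STATUS_OK:
            return st, i

    # root inlet: prescribed flow + outgoing W-
    o = off[root]
    N = nn[root]
    Wm = _outgoing_minus(A, q, A0, f, fr, drdx, o, N, dxv[root], dt, rho, nu, delta)
    Ain = _inlet_solve(qin_next, Wm, A[o], A0[o], f[o], rho)
    if Ain <= 0.0:
        return STATUS_INLET, root
    An[o] = Ain
    qn[o] = qin_next

    # junctions
    out = np.empty(6)
    for p in range(nv):
        c1 = child1[p]
        if c1 < 0:
            continue
        c2 = child2[p]
        two = c2 >= 0
        op = off[p]
        Np = nn[p]
        ip = op + Np - 1
        Wp = _outgoing_plus(A, q, A0, f, fr, drdx, op, Np, dxv[p], dt, rho, nu, delta)
        o1 = off[c1]
        Wm1 = _outgoing_minus(A, q, A0, f, fr, drdx, o1, nn[c1], dxv[c1], dt, rho, nu, delta)
        if two:
            o2 = off[c2]
            Wm2 = _outgoing_minus(A, q, A0, f, fr, drdx, o2, nn[c2], dxv[c2], dt, rho, nu, delta)
            A2g = A[o2]
            A02 = A0[o2]
            f2 = f[o2]
        else:
            o2 = 0
            Wm2 = 0.0
            A2g = 1.0
            A02 = 1.0
            f2 = 1.0
        ok = _junction_solve(Wp, Wm1, Wm2, two, A[ip], A[o1], A2g,
                             A0[ip], f[ip], A0[o1], f[o1], A02, f2, rho, out)
        if not ok:
            return STATUS_JUNCTION, p
        An[ip] = out[0]
        qn[ip] = out[1]
        An[o1] = out[2]
        qn[o1] = out[3]
        if two:
            An[o2] = out[4]
            qn[o2] = out[5]

    # terminal outlets: structured-tree convolution
    n_term = term_idx.shape[0]
    _ = parents  # reserved for diagnostics
    for k in range(n_term):
        i = term_idx[k]
        o = off[i]
        N = nn[i]
        ib = o + N - 1
        Wp = _outgoing_plus(A, q, A0, f, fr, drdx, o, N, dxv[i], dt, rho, nu, delta)
        # history part of the cyclic convolution: sum_{m>=1} z_m q_{s+1-m}
        H = 0.0
        for m in range(1, n_t):
            idx = hist_pos + 1 - m
            idx = idx % n_t
            H += kern[k, m] * term_hist[k, idx]
        Ab = _outlet_solve(Wp, term_z0[k], H, A[ib], A0[ib], f[ib], rho, p0)
        if Ab <= 0.0:
            return STATUS_OUTLET, i
        An[ib] = Ab
        c = _wavespeed(Ab, A0[ib], f[ib], rho)
        qn[ib] = (Wp + 4.0 * c) * Ab
        term_hist[k, (hist_pos + 1) % n_t] = qn[ib]

    return STATUS_OK, -1


@njit(cache=True)
def run_cycle(A, q, An, qn, off, nn, dxv,
              A0, A0s, f, fr, drdx, A0sh, fh, frh, drdxh, offh,
              parents, child1, child2, root, term_idx, term_z0, term_hist,
              hist_pos, kern, qin,
              dt, rho, nu, delta, p0, A_buf, q_buf):
    """Advance one full cardiac cycle (n_t steps), recording every step.

    Returns (status, where, step, hist_pos).  qin holds the prescribed root
    inflow per step of the cycle; A_buf/q_buf are (n_t, P) recording buffers.
    The state arrays A, q are updated in place to the end-of-cycle state.
    """
    n_t = kern.shape[1]
    nmax = 0
    for i in range(nn.shape[0]):
        if nn[i] > nmax:
            nmax = nn[i]
    Ah = np.empty(nmax)
    qh = np.empty(nmax)
    for s in range(n_t):
        status, where = step_network(
            A, q, An, qn, off, nn, dxv,
            A0, A0s, f, fr, drdx, A0sh, fh, frh, drdxh, offh,
            parents, child1, child2, root, term_idx, term_z0, term_hist,
            hist_pos, kern, qin[(s + 1) % n_t],
            dt, rho, nu, delta, p0, Ah, qh)
        if status != STATUS_OK:
            return status, where, s, hist_pos
        for i in range(A.shape[0]):
            A[i] = An[i]
            q[i] = qn[i]
            A_buf[s, i] = An[i]
            q_buf[s, i] = qn[i]
        hist_pos = (hist_pos + 1) % n_t
    return STATUS_OK, -1, n_t - 1, hist_pos
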