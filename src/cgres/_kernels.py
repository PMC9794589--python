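"""JIT-compiled numerical kernels: energy terms, restraint penalties,
proton placement and MD integrators, all with hand-coded analytic
gradients with respect to the Cα and SC site coordinates.

Everything here operates on plain float64/int32 arrays; the typed
wrapper modules (energy, restraints, sampling) pack their dataclasses
into the argument tuple consumed by :func:`total_force`.  Hot loops are
written with scalar arithmetic and preallocated workspaces: these
kernels sit inside the MD integrator and run millions of times.

Gradient bookkeeping: quantities that depend on a residue's local
bisector frame (proton positions) carry 3x12 Jacobians with respect to
the four local points (prev-Cα slot, Cα, next-Cα slot, SC); the slots
of terminal residues map onto virtual neighbors that are linear
combinations of real Cα positions, handled by :func:`_scatter12`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_LN2 = 0.6931471805599453
_KB = 1.987204259e-3
_ACC = 4.184e-4


# ---------------------------------------------------------------------------
# geometric primitives
# ---------------------------------------------------------------------------

@njit(cache=True)
def _lncosh(x):
    ax = abs(x)
    return ax + np.log1p(np.exp(-2.0 * ax)) - _LN2


@njit(cache=True)
def _angle_into(A, B, C, G):
    """Angle at vertex B; gradients w.r.t. A, B, C into rows of G (3,3)."""
    ux = A[0] - B[0]
    uy = A[1] - B[1]
    uz = A[2] - B[2]
    vx = C[0] - B[0]
    vy = C[1] - B[1]
    vz = C[2] - B[2]
    nu = np.sqrt(ux * ux + uy * uy + uz * uz)
    nv = np.sqrt(vx * vx + vy * vy + vz * vz)
    ux /= nu
    uy /= nu
    uz /= nu
    vx /= nv
    vy /= nv
    vz /= nv
    c = ux * vx + uy * vy + uz * vz
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    s = np.sqrt(1.0 - c * c)
    th = np.arccos(c)
    # clamped near the (anti)parallel singularity: keeps forces bounded
    # at the cost of gradient accuracy within ~0.01 rad of it
    if s < 1e-2:
        s = 1e-2
    f1 = 1.0 / (nu * s)
    f2 = 1.0 / (nv * s)
    G[0, 0] = (c * ux - vx) * f1
    G[0, 1] = (c * uy - vy) * f1
    G[0, 2] = (c * uz - vz) * f1
    G[2, 0] = (c * vx - ux) * f2
    G[2, 1] = (c * vy - uy) * f2
    G[2, 2] = (c * vz - uz) * f2
    G[1, 0] = -G[0, 0] - G[2, 0]
    G[1, 1] = -G[0, 1] - G[2, 1]
    G[1, 2] = -G[0, 2] - G[2, 2]
    return th


@njit(cache=True)
def _angle_grad(A, B, C):
    """Angle at vertex B and its gradients (allocating convenience API)."""
    G = np.empty((3, 3))
    th = _angle_into(A, B, C, G)
    return th, G[0].copy(), G[1].copy(), G[2].copy()


@njit(cache=True)
def _dih_into(A, B, C, D, G):
    """Right-handed dihedral over 4 points; gradients into rows of G (4,3).

    Returns (phi, ok); ok=False flags a degenerate (collinear)
    configuration, for which phi=0 and all gradients are zeroed.
    """
    b1x = B[0] - A[0]
    b1y = B[1] - A[1]
    b1z = B[2] - A[2]
    b2x = C[0] - B[0]
    b2y = C[1] - B[1]
    b2z = C[2] - B[2]
    b3x = D[0] - C[0]
    b3y = D[1] - C[1]
    b3z = D[2] - C[2]
    n1x = b1y * b2z - b1z * b2y
    n1y = b1z * b2x - b1x * b2z
    n1z = b1x * b2y - b1y * b2x
    n2x = b2y * b3z - b2z * b3y
    n2y = b2z * b3x - b2x * b3z
    n2z = b2x * b3y - b2y * b3x
    nb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
    m1 = n1x * n1x + n1y * n1y + n1z * n1z
    m2 = n2x * n2x + n2y * n2y + n2z * n2z
    if m1 < 1e-18 or m2 < 1e-18 or nb2 < 1e-12:
        for i in range(4):
            G[i, 0] = 0.0
            G[i, 1] = 0.0
            G[i, 2] = 0.0
        return 0.0, False
    x = n1x * n2x + n1y * n2y + n1z * n2z
    crx = n1y * n2z - n1z * n2y
    cry = n1z * n2x - n1x * n2z
    crz = n1x * n2y - n1y * n2x
    y = (crx * b2x + cry * b2y + crz * b2z) / nb2
    phi = np.arctan2(y, x)
    # clamp |n|² near collinearity so dihedral forces stay bounded
    if m1 < 1e-2:
        m1 = 1e-2
    if m2 < 1e-2:
        m2 = 1e-2
    fa = -nb2 / m1
    fd = nb2 / m2
    gax = fa * n1x
    gay = fa * n1y
    gaz = fa * n1z
    gdx = fd * n2x
    gdy = fd * n2y
    gdz = fd * n2z
    t = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
    s = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
    G[0, 0] = gax
    G[0, 1] = gay
    G[0, 2] = gaz
    G[3, 0] = gdx
    G[3, 1] = gdy
    G[3, 2] = gdz
    G[1, 0] = -(1.0 + t) * gax + s * gdx
    G[1, 1] = -(1.0 + t) * gay + s * gdy
    G[1, 2] = -(1.0 + t) * gaz + s * gdz
    G[2, 0] = t * gax - (1.0 + s) * gdx
    G[2, 1] = t * gay - (1.0 + s) * gdy
    G[2, 2] = t * gaz - (1.0 + s) * gdz
    return phi, True


@njit(cache=True)
def _dihedral_grad(A, B, C, D):
    """Dihedral and gradients (allocating convenience API)."""
    G = np.empty((4, 3))
    phi, ok = _dih_into(A, B, C, D, G)
    return phi, G[0].copy(), G[1].copy(), G[2].copy(), G[3].copy(), ok


# ---------------------------------------------------------------------------
# local bisector frame with Jacobians (workspace version)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _proj_scaled(x, y, z, r, P):
    """P = (I − ûûᵀ)/r for the unit vector (x, y, z)."""
    P[0, 0] = (1.0 - x * x) / r
    P[0, 1] = (-x * y) / r
    P[0, 2] = (-x * z) / r
    P[1, 0] = P[0, 1]
    P[1, 1] = (1.0 - y * y) / r
    P[1, 2] = (-y * z) / r
    P[2, 0] = P[0, 2]
    P[2, 1] = P[1, 2]
    P[2, 2] = (1.0 - z * z) / r


@njit(cache=True)
def _frame_ws(A, B, C, F, Jb, Je1, Je2, T):
    """Bisector frame (b̂, ê1, ê2) with 3x12 Jacobians, workspace form.

    F (3,3) receives b̂, ê1, ê2 as rows; Jb/Je1/Je2 (3,12) their
    Jacobians w.r.t. the local slots (A, B, C, S); T (8,3,3) scratch.
    The frame never depends on S; those columns are zeroed.
    """
    Pu = T[0]
    Pv = T[1]
    Pb = T[2]
    JbA = T[3]
    JbB = T[4]
    JbC = T[5]
    Pe = T[6]
    M = T[7]
    ux = A[0] - B[0]
    uy = A[1] - B[1]
    uz = A[2] - B[2]
    vx = C[0] - B[0]
    vy = C[1] - B[1]
    vz = C[2] - B[2]
    r1 = np.sqrt(ux * ux + uy * uy + uz * uz)
    r2 = np.sqrt(vx * vx + vy * vy + vz * vz)
    ux /= r1
    uy /= r1
    uz /= r1
    vx /= r2
    vy /= r2
    vz /= r2
    _proj_scaled(ux, uy, uz, r1, Pu)
    _proj_scaled(vx, vy, vz, r2, Pv)
    bx = ux + vx
    by = uy + vy
    bz = uz + vz
    nb = np.sqrt(bx * bx + by * by + bz * bz)
    degenerate = nb < 1e-8
    if degenerate:
        # straight angle: bisector undefined; arbitrary normal (u × x̂,
        # falling back to u × ŷ) with a frozen (zero) Jacobian
        bx, by, bz = 0.0, uz, -uy
        nb = np.sqrt(bx * bx + by * by + bz * bz)
        if nb < 1e-8:
            bx, by, bz = -uz, 0.0, ux  # u × (0,1,0)
            nb = np.sqrt(bx * bx + by * by + bz * bz)
    bx /= nb
    by /= nb
    bz /= nb
    F[0, 0] = bx
    F[0, 1] = by
    F[0, 2] = bz
    if degenerate:
        for a in range(3):
            for k in range(12):
                Jb[a, k] = 0.0
    else:
        # clamp the normalization scale near the straight-angle
        # degeneracy so restraint forces stay bounded (positions remain
        # exact; only the Jacobian is regularized in this region)
        nb_j = nb if nb > 0.05 else 0.05
        _proj_scaled(bx, by, bz, nb_j, Pb)
        # Jbraw blocks: A -> Pu, B -> -(Pu+Pv), C -> Pv; Jb = Pb @ blocks
        for a in range(3):
            for b_ in range(3):
                sA = 0.0
                sC = 0.0
                for c_ in range(3):
                    sA += Pb[a, c_] * Pu[c_, b_]
                    sC += Pb[a, c_] * Pv[c_, b_]
                JbA[a, b_] = sA
                JbC[a, b_] = sC
                JbB[a, b_] = -sA - sC
        for a in range(3):
            for b_ in range(3):
                Jb[a, b_] = JbA[a, b_]
                Jb[a, 3 + b_] = JbB[a, b_]
                Jb[a, 6 + b_] = JbC[a, b_]
                Jb[a, 9 + b_] = 0.0
    # e1_raw = u − (u·b̂) b̂
    ub = ux * bx + uy * by + uz * bz
    e1x = ux - ub * bx
    e1y = uy - ub * by
    e1z = uz - ub * bz
    ne1 = np.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
    if ne1 < 1e-8:
        # u parallel to b̂ (degenerate); arbitrary normal b̂ × ẑ
        e1x, e1y, e1z = by, -bx, 0.0
        ne1 = np.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
        if ne1 < 1e-8:
            e1x, e1y, e1z = -bz, 0.0, bx
            ne1 = np.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
        e1x /= ne1
        e1y /= ne1
        e1z /= ne1
        for a in range(3):
            for k in range(12):
                Je1[a, k] = 0.0
    else:
        e1x /= ne1
        e1y /= ne1
        e1z /= ne1
        ne1_j = ne1 if ne1 > 0.05 else 0.05
        _proj_scaled(e1x, e1y, e1z, ne1_j, Pe)
        # d(e1raw)[:,k] = Ju[:,k] − dub[k]·b̂ − ub·Jb[:,k]
        # Ju blocks: A -> Pu, B -> -Pu, C/S -> 0
        # dub[k] = b̂ᵀ Ju[:,k] + uᵀ Jb[:,k]
        for k in range(12):
            blk = k // 3
            col = k % 3
            jux = 0.0
            juy = 0.0
            juz = 0.0
            if blk == 0:
                jux = Pu[0, col]
                juy = Pu[1, col]
                juz = Pu[2, col]
            elif blk == 1:
                jux = -Pu[0, col]
                juy = -Pu[1, col]
                juz = -Pu[2, col]
            dub = (
                bx * jux + by * juy + bz * juz
                + ux * Jb[0, k] + uy * Jb[1, k] + uz * Jb[2, k]
            )
            rx = jux - dub * bx - ub * Jb[0, k]
            ry = juy - dub * by - ub * Jb[1, k]
            rz = juz - dub * bz - ub * Jb[2, k]
            Je1[0, k] = Pe[0, 0] * rx + Pe[0, 1] * ry + Pe[0, 2] * rz
            Je1[1, k] = Pe[1, 0] * rx + Pe[1, 1] * ry + Pe[1, 2] * rz
            Je1[2, k] = Pe[2, 0] * rx + Pe[2, 1] * ry + Pe[2, 2] * rz
    F[1, 0] = e1x
    F[1, 1] = e1y
    F[1, 2] = e1z
    # ê2 = b̂ × ê1
    e2x = by * e1z - bz * e1y
    e2y = bz * e1x - bx * e1z
    e2z = bx * e1y - by * e1x
    F[2, 0] = e2x
    F[2, 1] = e2y
    F[2, 2] = e2z
    for k in range(12):
        dbx = Jb[0, k]
        dby = Jb[1, k]
        dbz = Jb[2, k]
        dex = Je1[0, k]
        dey = Je1[1, k]
        dez = Je1[2, k]
        Je2[0, k] = dby * e1z - dbz * e1y + by * dez - bz * dey
        Je2[1, k] = dbz * e1x - dbx * e1z + bz * dex - bx * dez
        Je2[2, k] = dbx * e1y - dby * e1x + bx * dey - by * dex
    _ = M  # scratch reserved
    return 0


@njit(cache=True)
def _scatter12(g12, i, n, gca, gsc):
    """Add a residue-local 12-dim gradient into the global arrays."""
    if i == 0:
        # prev slot is the virtual point ca0 + ca1 - ca2
        for a in range(3):
            gca[0, a] += g12[a]
            gca[1, a] += g12[a]
            gca[2, a] -= g12[a]
    else:
        for a in range(3):
            gca[i - 1, a] += g12[a]
    for a in range(3):
        gca[i, a] += g12[3 + a]
    if i == n - 1:
        # next slot is the virtual point ca_{n-1} + ca_{n-2} - ca_{n-3}
        for a in range(3):
            gca[n - 1, a] += g12[6 + a]
            gca[n - 2, a] += g12[6 + a]
            gca[n - 3, a] -= g12[6 + a]
    else:
        for a in range(3):
            gca[i + 1, a] += g12[6 + a]
    for a in range(3):
        gsc[i, a] += g12[9 + a]


@njit(cache=True)
def _proton_ws(ca, sc, i, cls, hn_c, ha_c, pad, p, J, Abuf, Cbuf, F, Jb, Je1, Je2, T):
    """Proton position p (3,) and Jacobian J (3,12) using workspaces.

    cls: 0 amide H, 1 Hα, 2 side-chain pseudo-proton (pad Å beyond SC).
    """
    n = ca.shape[0]
    B = ca[i]
    S = sc[i]
    if cls == 2:
        wx = S[0] - B[0]
        wy = S[1] - B[1]
        wz = S[2] - B[2]
        r = np.sqrt(wx * wx + wy * wy + wz * wz)
        if r > 1e-8:
            # p = S + pad·û ; J = pad·(I−ûûᵀ)/r·[0,−I,0,I] + I on S block
            _proj_scaled(wx / r, wy / r, wz / r, r, T[0])
            p[0] = S[0] + pad * wx / r
            p[1] = S[1] + pad * wy / r
            p[2] = S[2] + pad * wz / r
            for a in range(3):
                for b_ in range(3):
                    m = pad * T[0][a, b_]
                    J[a, b_] = 0.0
                    J[a, 3 + b_] = -m
                    J[a, 6 + b_] = 0.0
                    J[a, 9 + b_] = m
                J[a, 9 + a] += 1.0
            return
    # need the frame
    if i == 0:
        for a in range(3):
            Abuf[a] = ca[0, a] + ca[1, a] - ca[2, a]
            Cbuf[a] = ca[1, a]
    elif i == n - 1:
        for a in range(3):
            Abuf[a] = ca[n - 2, a]
            Cbuf[a] = ca[n - 1, a] + ca[n - 2, a] - ca[n - 3, a]
    else:
        for a in range(3):
            Abuf[a] = ca[i - 1, a]
            Cbuf[a] = ca[i + 1, a]
    _frame_ws(Abuf, B, Cbuf, F, Jb, Je1, Je2, T)
    if cls == 2:
        # glycine: SC at Cα; pad points away from the backbone (−b̂)
        for a in range(3):
            p[a] = S[a] - pad * F[0, a]
            for k in range(12):
                J[a, k] = -pad * Jb[a, k]
            J[a, 9 + a] += 1.0
        return
    c0 = hn_c[0] if cls == 0 else ha_c[0]
    c1 = hn_c[1] if cls == 0 else ha_c[1]
    c2 = hn_c[2] if cls == 0 else ha_c[2]
    for a in range(3):
        p[a] = B[a] + c0 * F[0, a] + c1 * F[1, a] + c2 * F[2, a]
        for k in range(12):
            J[a, k] = c0 * Jb[a, k] + c1 * Je1[a, k] + c2 * Je2[a, k]
        J[a, 3 + a] += 1.0


@njit(cache=True)
def proton_one(ca, sc, i, cls, hn_c, ha_c, pad):
    """Estimated proton position of residue i and its 3x12 Jacobian.

    cls: 0 amide H, 1 Hα, 2 side-chain pseudo-proton.  Allocating
    convenience API around :func:`_proton_ws`.
    """
    p = np.zeros(3)
    J = np.zeros((3, 12))
    Abuf = np.empty(3)
    Cbuf = np.empty(3)
    F = np.empty((3, 3))
    Jb = np.empty((3, 12))
    Je1 = np.empty((3, 12))
    Je2 = np.empty((3, 12))
    T = np.empty((8, 3, 3))
    _proton_ws(ca, sc, i, cls, hn_c, ha_c, pad, p, J, Abuf, Cbuf, F, Jb, Je1, Je2, T)
    return p, J


# ---------------------------------------------------------------------------
# restraint penalty primitives
# ---------------------------------------------------------------------------

@njit(cache=True)
def vcont(d, dl, du, A, sig, kap):
    """Flat-bottom distance penalty and its d-derivative.

    Zero on [dl, du]; quartic-ratio walls of height A with transition
    thickness sig; for kap > 0 the outer asymptote gains slope A*kap
    (log-cosh form), mildly guiding large violations.
    """
    if d >= dl and d <= du:
        return 0.0, 0.0
    if d < dl:
        D = d - dl
    else:
        D = d - du
    D2 = D * D
    D3 = D2 * D
    D4 = D2 * D2
    s4 = sig ** 4
    den = s4 + D4
    q = D4 / den
    qp = 4.0 * s4 * D3 / (den * den)
    if kap != 0.0:
        L = _lncosh(D)
        T = np.tanh(D)
        V = A * q * (1.0 + kap * L)
        dV = A * (qp * (1.0 + kap * L) + q * kap * T)
    else:
        V = A * q
        dV = A * qp
    return V, dV


@njit(cache=True)
def angular_flatbottom(x, xl, xu):
    """Periodic flat-bottom angular penalty and its x-derivative.

    Zero on the (mod 2π) band [xl, xu]; quartic growth
    (1/4)(|δ| − half-width)^4 outside, with δ the wrapped offset from
    the band center.  2π-periodic and C¹-continuous.
    """
    two_pi = 2.0 * np.pi
    width = (xu - xl) % two_pi
    half = 0.5 * width
    mid = xl + half
    delta = (x - mid + np.pi) % two_pi - np.pi
    ad = abs(delta)
    ex = ad - half
    if ex <= 0.0:
        return 0.0, 0.0
    V = 0.25 * ex ** 4
    dV = ex ** 3 * (1.0 if delta >= 0.0 else -1.0)
    return V, dV


@njit(cache=True)
def ambiguous_logexp(vals, alpha, fast):
    """Log-sum-exp soft minimum over member penalties.

    V = −(1/α) ln Σ exp(−α V_i), evaluated with a max-shift; when
    ``fast`` the members whose shifted argument cannot change V by more
    than ~1e−9 are skipped.  Returns (V, member weights dV/dV_i).
    """
    m = vals.shape[0]
    vmin = vals[0]
    for i in range(1, m):
        if vals[i] < vmin:
            vmin = vals[i]
    cut = np.log(m) + 20.723265836946411  # ln(m / 1e-9)
    S = 0.0
    w = np.zeros(m)
    for i in range(m):
        a = alpha * (vals[i] - vmin)
        if fast and a > cut:
            continue
        e = np.exp(-a)
        w[i] = e
        S += e
    V = vmin - np.log(S) / alpha
    for i in range(m):
        w[i] /= S
    return V, w


# ---------------------------------------------------------------------------
# force-field terms (simplified stand-in forms)
# ---------------------------------------------------------------------------

# ff scalar parameter vector layout
S_EPS_SCP = 0
S_SIG_SCP = 1
S_PP_EPS = 2
S_PP_SIG = 3
S_MU2 = 4
S_K_THETA = 5
S_THETA0 = 6
S_K_ALPHA = 7
S_ALPHA0 = 8
S_K_BETA = 9
S_BETA0 = 10
S_K_BOND = 11
S_D0_BOND = 12
S_K_BSC = 13
S_A_CORR = 14
S_SIG_CORR = 15
S_A_TURN = 16
S_RSOFT2 = 17
N_SCAL = 18

# term indices
T_SCSC = 0
T_SCP = 1
T_PPVDW = 2
T_PPEL = 3
T_TOR = 4
T_B = 5
T_ROT = 6
T_BOND = 7
T_SSBOND = 8
T_CORR3 = 9
T_TURN3 = 10
N_TERMS = 11


@njit(cache=True)
def ff_energy(ca, sc, tidx, sc_eps, sc_sig, b0, scal, tor_c, pref):
    """Simplified coarse-grained energy: term values and total gradient.

    Returns (terms, gca, gsc) with terms the *raw* per-term energies in
    the canonical order; gradients include the effective prefactors
    ``pref`` (weight × temperature factor) so that the total energy is
    Σ pref·terms and (gca, gsc) is its exact gradient.
    """
    n = ca.shape[0]
    terms = np.zeros(N_TERMS)
    gca = np.zeros((n, 3))
    gsc = np.zeros((n, 3))
    rsoft2 = scal[S_RSOFT2]
    G3 = np.empty((3, 3))
    G3b = np.empty((3, 3))
    G4 = np.empty((4, 3))
    Q = np.empty(3)

    # --- SC-SC pairs (6-12 with minimum at σ, mixing rules) -------------
    c_scsc = pref[T_SCSC]
    for i in range(n):
        ei = sc_eps[tidx[i]]
        si = sc_sig[tidx[i]]
        xi = sc[i, 0]
        yi = sc[i, 1]
        zi = sc[i, 2]
        for j in range(i + 1, n):
            eps = np.sqrt(ei * sc_eps[tidx[j]])
            sig = 0.5 * (si + sc_sig[tidx[j]])
            wx = xi - sc[j, 0]
            wy = yi - sc[j, 1]
            wz = zi - sc[j, 2]
            s2 = wx * wx + wy * wy + wz * wz + rsoft2
            xq = sig * sig / s2
            x3 = xq * xq * xq
            x6 = x3 * x3
            terms[T_SCSC] += eps * (x6 - 2.0 * x3)
            c = 2.0 * c_scsc * 6.0 * eps * (x3 - x6) / s2
            gsc[i, 0] += c * wx
            gsc[i, 1] += c * wy
            gsc[i, 2] += c * wz
            gsc[j, 0] -= c * wx
            gsc[j, 1] -= c * wy
            gsc[j, 2] -= c * wz

    # --- SC-p excluded volume (repulsive r^-6) --------------------------
    eps_sp = scal[S_EPS_SCP]
    sig_sp2 = scal[S_SIG_SCP] * scal[S_SIG_SCP]
    c_scp = pref[T_SCP]
    for i in range(n):
        xi = sc[i, 0]
        yi = sc[i, 1]
        zi = sc[i, 2]
        for j in range(n - 1):
            if j == i or j == i - 1:
                continue
            px = 0.5 * (ca[j, 0] + ca[j + 1, 0])
            py = 0.5 * (ca[j, 1] + ca[j + 1, 1])
            pz = 0.5 * (ca[j, 2] + ca[j + 1, 2])
            wx = xi - px
            wy = yi - py
            wz = zi - pz
            s2 = wx * wx + wy * wy + wz * wz + rsoft2
            xq = sig_sp2 / s2
            x3 = xq * xq * xq
            terms[T_SCP] += eps_sp * x3
            c = 2.0 * c_scp * (-3.0) * eps_sp * x3 / s2
            gsc[i, 0] += c * wx
            gsc[i, 1] += c * wy
            gsc[i, 2] += c * wz
            gca[j, 0] -= 0.5 * c * wx
            gca[j, 1] -= 0.5 * c * wy
            gca[j, 2] -= 0.5 * c * wz
            gca[j + 1, 0] -= 0.5 * c * wx
            gca[j + 1, 1] -= 0.5 * c * wy
            gca[j + 1, 2] -= 0.5 * c * wz

    # --- peptide-peptide VdW, dipolar electrostatics, correlation -------
    pp_eps = scal[S_PP_EPS]
    pp_sig2 = scal[S_PP_SIG] * scal[S_PP_SIG]
    mu2 = scal[S_MU2]
    a_corr = scal[S_A_CORR]
    sigc2 = scal[S_SIG_CORR] * scal[S_SIG_CORR]
    c_vdw = pref[T_PPVDW]
    c_el = pref[T_PPEL] * mu2
    c_co = pref[T_CORR3] * a_corr
    for i in range(n - 1):
        pix = 0.5 * (ca[i, 0] + ca[i + 1, 0])
        piy = 0.5 * (ca[i, 1] + ca[i + 1, 1])
        piz = 0.5 * (ca[i, 2] + ca[i + 1, 2])
        bix = ca[i + 1, 0] - ca[i, 0]
        biy = ca[i + 1, 1] - ca[i, 1]
        biz = ca[i + 1, 2] - ca[i, 2]
        nbi = np.sqrt(bix * bix + biy * biy + biz * biz)
        uix = bix / nbi
        uiy = biy / nbi
        uiz = biz / nbi
        for j in range(i + 2, n - 1):
            pjx = 0.5 * (ca[j, 0] + ca[j + 1, 0])
            pjy = 0.5 * (ca[j, 1] + ca[j + 1, 1])
            pjz = 0.5 * (ca[j, 2] + ca[j + 1, 2])
            rvx = pjx - pix
            rvy = pjy - piy
            rvz = pjz - piz
            r2 = rvx * rvx + rvy * rvy + rvz * rvz
            # VdW (soft-core)
            s2 = r2 + rsoft2
            xq = pp_sig2 / s2
            x3 = xq * xq * xq
            x6 = x3 * x3
            terms[T_PPVDW] += pp_eps * (x6 - 2.0 * x3)
            c = 2.0 * c_vdw * 6.0 * pp_eps * (x3 - x6) / s2
            hx = 0.5 * c * rvx
            hy = 0.5 * c * rvy
            hz = 0.5 * c * rvz
            gca[i, 0] -= hx
            gca[i, 1] -= hy
            gca[i, 2] -= hz
            gca[i + 1, 0] -= hx
            gca[i + 1, 1] -= hy
            gca[i + 1, 2] -= hz
            gca[j, 0] += hx
            gca[j, 1] += hy
            gca[j, 2] += hz
            gca[j + 1, 0] += hx
            gca[j + 1, 1] += hy
            gca[j + 1, 2] += hz
            # dipole-dipole and alignment correlation
            bjx = ca[j + 1, 0] - ca[j, 0]
            bjy = ca[j + 1, 1] - ca[j, 1]
            bjz = ca[j + 1, 2] - ca[j, 2]
            nbj = np.sqrt(bjx * bjx + bjy * bjy + bjz * bjz)
            ujx = bjx / nbj
            ujy = bjy / nbj
            ujz = bjz / nbj
            r = np.sqrt(r2)
            r3 = r2 * r
            r5 = r3 * r2
            r7 = r5 * r2
            ab = uix * ujx + uiy * ujy + uiz * ujz
            ar = uix * rvx + uiy * rvy + uiz * rvz
            br = ujx * rvx + ujy * rvy + ujz * rvz
            terms[T_PPEL] += mu2 * (ab / r3 - 3.0 * ar * br / r5)
            kp = pref[T_PPEL] * mu2
            dex = kp * (-3.0 * ab / r5 * rvx - 3.0 * (uix * br + ujx * ar) / r5 + 15.0 * ar * br / r7 * rvx)
            dey = kp * (-3.0 * ab / r5 * rvy - 3.0 * (uiy * br + ujy * ar) / r5 + 15.0 * ar * br / r7 * rvy)
            dez = kp * (-3.0 * ab / r5 * rvz - 3.0 * (uiz * br + ujz * ar) / r5 + 15.0 * ar * br / r7 * rvz)
            duix = kp * (ujx / r3 - 3.0 * br * rvx / r5)
            duiy = kp * (ujy / r3 - 3.0 * br * rvy / r5)
            duiz = kp * (ujz / r3 - 3.0 * br * rvz / r5)
            dujx = kp * (uix / r3 - 3.0 * ar * rvx / r5)
            dujy = kp * (uiy / r3 - 3.0 * ar * rvy / r5)
            dujz = kp * (uiz / r3 - 3.0 * ar * rvz / r5)
            # correlation stand-in: a_corr (û_i·û_j)² (σ_c²/s2)³
            if a_corr != 0.0:
                s2c = r2 + rsoft2
                xcq = sigc2 / s2c
                xc3 = xcq * xcq * xcq
                terms[T_CORR3] += a_corr * ab * ab * xc3
                crv = c_co * ab * ab * (-3.0 * xc3 / s2c) * 2.0
                dex2 = crv * rvx
                dey2 = crv * rvy
                dez2 = crv * rvz
                duix += c_co * 2.0 * ab * xc3 * ujx
                duiy += c_co * 2.0 * ab * xc3 * ujy
                duiz += c_co * 2.0 * ab * xc3 * ujz
                dujx += c_co * 2.0 * ab * xc3 * uix
                dujy += c_co * 2.0 * ab * xc3 * uiy
                dujz += c_co * 2.0 * ab * xc3 * uiz
                dex += dex2
                dey += dey2
                dez += dez2
            # project dE/dû through (I − ûûᵀ)/|b|
            di = duix * uix + duiy * uiy + duiz * uiz
            dj = dujx * ujx + dujy * ujy + dujz * ujz
            pux = (duix - di * uix) / nbi
            puy = (duiy - di * uiy) / nbi
            puz = (duiz - di * uiz) / nbi
            pvx = (dujx - dj * ujx) / nbj
            pvy = (dujy - dj * ujy) / nbj
            pvz = (dujz - dj * ujz) / nbj
            gca[i, 0] += -0.5 * dex - pux
            gca[i, 1] += -0.5 * dey - puy
            gca[i, 2] += -0.5 * dez - puz
            gca[i + 1, 0] += -0.5 * dex + pux
            gca[i + 1, 1] += -0.5 * dey + puy
            gca[i + 1, 2] += -0.5 * dez + puz
            gca[j, 0] += 0.5 * dex - pvx
            gca[j, 1] += 0.5 * dey - pvy
            gca[j, 2] += 0.5 * dez - pvz
            gca[j + 1, 0] += 0.5 * dex + pvx
            gca[j + 1, 1] += 0.5 * dey + pvy
            gca[j + 1, 2] += 0.5 * dez + pvz

    # --- torsional (Fourier in γ, sinθ-damped) --------------------------
    nc = tor_c.shape[0]
    w_tor = pref[T_TOR]
    for k in range(n - 3):
        th1 = _angle_into(ca[k], ca[k + 1], ca[k + 2], G3)
        th2 = _angle_into(ca[k + 1], ca[k + 2], ca[k + 3], G3b)
        ga, ok = _dih_into(ca[k], ca[k + 1], ca[k + 2], ca[k + 3], G4)
        s1 = np.sin(th1)
        s2_ = np.sin(th2)
        c1 = np.cos(th1)
        c2 = np.cos(th2)
        F = 0.0
        dF = 0.0
        for m in range(nc):
            F += tor_c[m] * np.cos((m + 1) * ga)
            dF -= tor_c[m] * (m + 1) * np.sin((m + 1) * ga)
        terms[T_TOR] += s1 * s2_ * F
        cth1 = w_tor * c1 * s2_ * F
        cth2 = w_tor * s1 * c2 * F
        cga = w_tor * s1 * s2_ * dF
        for a in range(3):
            gca[k, a] += cth1 * G3[0, a] + cga * G4[0, a]
            gca[k + 1, a] += cth1 * G3[1, a] + cth2 * G3b[0, a] + cga * G4[1, a]
            gca[k + 2, a] += cth1 * G3[2, a] + cth2 * G3b[1, a] + cga * G4[2, a]
            gca[k + 3, a] += cth2 * G3b[2, a] + cga * G4[3, a]

    # --- virtual-bond-angle term + local turn correlation ---------------
    k_th = scal[S_K_THETA]
    th0 = scal[S_THETA0]
    a_turn = scal[S_A_TURN]
    for i in range(1, n - 1):
        th = _angle_into(ca[i - 1], ca[i], ca[i + 1], G3)
        dth = th - th0
        terms[T_B] += 0.5 * k_th * dth * dth
        c = pref[T_B] * k_th * dth
        # turn correlation: û_i·û_{i+1} = −cos θ ⇒ V = −a_turn sinθ cosθ
        if a_turn != 0.0:
            terms[T_TURN3] += -a_turn * np.sin(th) * np.cos(th)
            c += pref[T_TURN3] * (-a_turn) * np.cos(2.0 * th)
        for a in range(3):
            gca[i - 1, a] += c * G3[0, a]
            gca[i, a] += c * G3[1, a]
            gca[i + 1, a] += c * G3[2, a]

    # --- side-chain rotamer term (harmonic in ᾶ, β̃) --------------------
    k_al = scal[S_K_ALPHA]
    al0 = scal[S_ALPHA0]
    k_be = scal[S_K_BETA]
    be0 = scal[S_BETA0]
    for i in range(1, n - 1):
        if b0[tidx[i]] <= 0.0:
            continue
        Q[0] = 0.5 * (ca[i - 1, 0] + ca[i + 1, 0])
        Q[1] = 0.5 * (ca[i - 1, 1] + ca[i + 1, 1])
        Q[2] = 0.5 * (ca[i - 1, 2] + ca[i + 1, 2])
        th = _angle_into(Q, ca[i], sc[i], G3)
        da = th - al0
        terms[T_ROT] += 0.5 * k_al * da * da
        c = pref[T_ROT] * k_al * da
        for a in range(3):
            gca[i - 1, a] += 0.5 * c * G3[0, a]
            gca[i + 1, a] += 0.5 * c * G3[0, a]
            gca[i, a] += c * G3[1, a]
            gsc[i, a] += c * G3[2, a]
        be, ok = _dih_into(ca[i - 1], ca[i], Q, sc[i], G4)
        if ok:
            db = (be - be0 + np.pi) % (2.0 * np.pi) - np.pi
            terms[T_ROT] += 0.5 * k_be * db * db
            c = pref[T_ROT] * k_be * db
            for a in range(3):
                gca[i - 1, a] += c * (G4[0, a] + 0.5 * G4[2, a])
                gca[i, a] += c * G4[1, a]
                gca[i + 1, a] += c * 0.5 * G4[2, a]
                gsc[i, a] += c * G4[3, a]

    # --- bond terms ------------------------------------------------------
    k_bd = scal[S_K_BOND]
    d0 = scal[S_D0_BOND]
    k_bs = scal[S_K_BSC]
    for i in range(n - 1):
        wx = ca[i + 1, 0] - ca[i, 0]
        wy = ca[i + 1, 1] - ca[i, 1]
        wz = ca[i + 1, 2] - ca[i, 2]
        r = np.sqrt(wx * wx + wy * wy + wz * wz)
        dd = r - d0
        terms[T_BOND] += 0.5 * k_bd * dd * dd
        c = pref[T_BOND] * k_bd * dd / r
        gca[i + 1, 0] += c * wx
        gca[i + 1, 1] += c * wy
        gca[i + 1, 2] += c * wz
        gca[i, 0] -= c * wx
        gca[i, 1] -= c * wy
        gca[i, 2] -= c * wz
    for i in range(n):
        wx = sc[i, 0] - ca[i, 0]
        wy = sc[i, 1] - ca[i, 1]
        wz = sc[i, 2] - ca[i, 2]
        bref = b0[tidx[i]]
        if bref <= 0.0:
            # zero-offset site (glycine): smooth harmonic tether
            r2 = wx * wx + wy * wy + wz * wz
            terms[T_BOND] += 0.5 * k_bs * r2
            c = pref[T_BOND] * k_bs
        else:
            r = np.sqrt(wx * wx + wy * wy + wz * wz)
            dd = r - bref
            terms[T_BOND] += 0.5 * k_bs * dd * dd
            c = pref[T_BOND] * k_bs * dd / r
        gsc[i, 0] += c * wx
        gsc[i, 1] += c * wy
        gsc[i, 2] += c * wz
        gca[i, 0] -= c * wx
        gca[i, 1] -= c * wy
        gca[i, 2] -= c * wz

    # T_SSBOND stub: 0
    return terms, gca, gsc


# ---------------------------------------------------------------------------
# NMR restraint kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def nmr_angular_energy(ca, kind, idx, xl, xu, gca, weight_theta, weight_gamma):
    """Angular flat-bottom penalties on θ/γ; adds weighted gradient in place.

    Returns (V_theta, V_gamma) raw block sums.
    """
    vth = 0.0
    vga = 0.0
    G3 = np.empty((3, 3))
    G4 = np.empty((4, 3))
    K_ = kind.shape[0]
    for r in range(K_):
        i = idx[r]
        if kind[r] == 0:
            th = _angle_into(ca[i - 1], ca[i], ca[i + 1], G3)
            V, dV = angular_flatbottom(th, xl[r], xu[r])
            vth += V
            c = weight_theta * dV
            if c != 0.0:
                for a in range(3):
                    gca[i - 1, a] += c * G3[0, a]
                    gca[i, a] += c * G3[1, a]
                    gca[i + 1, a] += c * G3[2, a]
        else:
            ga, ok = _dih_into(ca[i - 1], ca[i], ca[i + 1], ca[i + 2], G4)
            V, dV = angular_flatbottom(ga, xl[r], xu[r])
            vga += V
            c = weight_gamma * dV
            if ok and c != 0.0:
                for a in range(3):
                    gca[i - 1, a] += c * G4[0, a]
                    gca[i, a] += c * G4[1, a]
                    gca[i + 1, a] += c * G4[2, a]
                    gca[i + 2, a] += c * G4[3, a]
    return vth, vga


@njit(cache=True)
def nmr_distance_energy(
    ca, sc, uq_res, uq_cls, mem_p1, mem_p2,
    gs, m_dl, m_du, m_A, m_sig, m_kap, g_alpha,
    hn_c, ha_c, pads, tidx, weight, fast,
    gca, gsc, group_v,
):
    """Grouped (ambiguous) interproton distance penalties.

    Proton positions come from the local-frame estimator; gradients are
    chained through the proton Jacobians and added (×weight) in place.
    Fills ``group_v`` with per-group penalties; returns the raw sum.
    """
    U = uq_res.shape[0]
    n = ca.shape[0]
    pos = np.empty((U, 3))
    jac = np.empty((U, 3, 12))
    Abuf = np.empty(3)
    Cbuf = np.empty(3)
    T = np.empty((8, 3, 3))
    # one bisector frame per residue, shared by its backbone protons
    need = np.zeros(n, dtype=np.uint8)
    for u in range(U):
        i = uq_res[u]
        if uq_cls[u] != 2:
            need[i] = 1
        else:
            wx = sc[i, 0] - ca[i, 0]
            wy = sc[i, 1] - ca[i, 1]
            wz = sc[i, 2] - ca[i, 2]
            if wx * wx + wy * wy + wz * wz < 1e-16:
                need[i] = 1
    FA = np.empty((n, 3, 3))
    FJb = np.empty((n, 3, 12))
    FJe1 = np.empty((n, 3, 12))
    FJe2 = np.empty((n, 3, 12))
    for i in range(n):
        if need[i] == 0:
            continue
        if i == 0:
            for a in range(3):
                Abuf[a] = ca[0, a] + ca[1, a] - ca[2, a]
                Cbuf[a] = ca[1, a]
        elif i == n - 1:
            for a in range(3):
                Abuf[a] = ca[n - 2, a]
                Cbuf[a] = ca[n - 1, a] + ca[n - 2, a] - ca[n - 3, a]
        else:
            for a in range(3):
                Abuf[a] = ca[i - 1, a]
                Cbuf[a] = ca[i + 1, a]
        _frame_ws(Abuf, ca[i], Cbuf, FA[i], FJb[i], FJe1[i], FJe2[i], T)
    for u in range(U):
        i = uq_res[u]
        cls = uq_cls[u]
        pad = pads[tidx[i]]
        p = pos[u]
        J = jac[u]
        if cls == 2:
            wx = sc[i, 0] - ca[i, 0]
            wy = sc[i, 1] - ca[i, 1]
            wz = sc[i, 2] - ca[i, 2]
            r = np.sqrt(wx * wx + wy * wy + wz * wz)
            if r > 1e-8:
                _proj_scaled(wx / r, wy / r, wz / r, r, T[0])
                p[0] = sc[i, 0] + pad * wx / r
                p[1] = sc[i, 1] + pad * wy / r
                p[2] = sc[i, 2] + pad * wz / r
                for a in range(3):
                    for b_ in range(3):
                        m_ = pad * T[0][a, b_]
                        J[a, b_] = 0.0
                        J[a, 3 + b_] = -m_
                        J[a, 6 + b_] = 0.0
                        J[a, 9 + b_] = m_
                    J[a, 9 + a] += 1.0
            else:
                for a in range(3):
                    p[a] = sc[i, a] - pad * FA[i, 0, a]
                    for k in range(12):
                        J[a, k] = -pad * FJb[i, a, k]
                    J[a, 9 + a] += 1.0
        else:
            c0 = hn_c[0] if cls == 0 else ha_c[0]
            c1 = hn_c[1] if cls == 0 else ha_c[1]
            c2 = hn_c[2] if cls == 0 else ha_c[2]
            for a in range(3):
                p[a] = ca[i, a] + c0 * FA[i, 0, a] + c1 * FA[i, 1, a] + c2 * FA[i, 2, a]
                for k in range(12):
                    J[a, k] = c0 * FJb[i, a, k] + c1 * FJe1[i, a, k] + c2 * FJe2[i, a, k]
                J[a, 3 + a] += 1.0
    G = gs.shape[0] - 1
    total = 0.0
    M = mem_p1.shape[0]
    dmem = np.empty(M)
    vmem = np.empty(M)
    dvm = np.empty(M)
    g12 = np.empty(12)
    for m in range(M):
        wx = pos[mem_p1[m], 0] - pos[mem_p2[m], 0]
        wy = pos[mem_p1[m], 1] - pos[mem_p2[m], 1]
        wz = pos[mem_p1[m], 2] - pos[mem_p2[m], 2]
        dmem[m] = np.sqrt(wx * wx + wy * wy + wz * wz)
    for g in range(G):
        lo = gs[g]
        hi = gs[g + 1]
        nm = hi - lo
        for m in range(lo, hi):
            V, dV = vcont(dmem[m], m_dl[m], m_du[m], m_A[m], m_sig[m], m_kap[m])
            vmem[m] = V
            dvm[m] = dV
        if nm == 1:
            Vg = vmem[lo]
            group_v[g] = Vg
            total += Vg
            if dvm[lo] != 0.0:
                _accum_pair_grad(
                    pos, jac, uq_res, mem_p1[lo], mem_p2[lo], dmem[lo],
                    weight * dvm[lo], n, gca, gsc, g12,
                )
            continue
        Vg, wts = ambiguous_logexp(vmem[lo:hi].copy(), g_alpha[g], fast)
        group_v[g] = Vg
        total += Vg
        for m in range(lo, hi):
            c = wts[m - lo] * dvm[m]
            if c != 0.0:
                _accum_pair_grad(
                    pos, jac, uq_res, mem_p1[m], mem_p2[m], dmem[m],
                    weight * c, n, gca, gsc, g12,
                )
    return total


@njit(cache=True)
def _accum_pair_grad(pos, jac, uq_res, u1, u2, d, coef, n, gca, gsc, g12):
    """Scatter coef * d(distance)/d(sites) for a proton pair."""
    if d < 1e-12:
        return
    wx = (pos[u1, 0] - pos[u2, 0]) / d
    wy = (pos[u1, 1] - pos[u2, 1]) / d
    wz = (pos[u1, 2] - pos[u2, 2]) / d
    for k in range(12):
        g12[k] = coef * (wx * jac[u1, 0, k] + wy * jac[u1, 1, k] + wz * jac[u1, 2, k])
    _scatter12(g12, uq_res[u1], n, gca, gsc)
    for k in range(12):
        g12[k] = -coef * (wx * jac[u2, 0, k] + wy * jac[u2, 1, k] + wz * jac[u2, 2, k])
    _scatter12(g12, uq_res[u2], n, gca, gsc)


# ---------------------------------------------------------------------------
# XL-MS restraint kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def xl_statistical(d, a, b, c, sig, A, rt):
    """Cα-distance statistical crosslink potential W(d) and derivative."""
    s2 = sig * sig
    s4 = s2 * s2
    e = np.exp(-d * d / (2.0 * s2))
    shape = b * (d ** 4 / s4) * e
    arg = a + shape + c
    W = -A * rt * np.log(arg)
    dshape = b * e * (4.0 * d ** 3 / s4 - d ** 5 / (s4 * s2))
    dW = -A * rt * dshape / arg
    return W, dW


@njit(cache=True)
def xl_vd(d, wa, wk, wd0, nw):
    """Multi-well smooth-min distance potential (harmonic smooth-min)."""
    S = 0.0
    for i in range(nw):
        w = wa[i] + 0.5 * wk[i] * (d - wd0[i]) ** 2
        S += 1.0 / w
    V = 1.0 / S
    dV = 0.0
    for i in range(nw):
        w = wa[i] + 0.5 * wk[i] * (d - wd0[i]) ** 2
        wp = wk[i] * (d - wd0[i])
        dV += wp / (w * w)
    dV *= V * V
    return V, dV


@njit(cache=True)
def xl_vtheta(th, a0, av, bv, nt):
    V = a0
    dV = 0.0
    for m in range(nt):
        V += av[m] * np.cos((m + 1) * th) + bv[m] * np.sin((m + 1) * th)
        dV += (m + 1) * (-av[m] * np.sin((m + 1) * th) + bv[m] * np.cos((m + 1) * th))
    return V, dV


@njit(cache=True)
def xl_vgamma(ga, th1, th2, v0, cv, ng):
    """Dihedral crosslink term with sin^j damping; → v0 as sinθ → 0."""
    s1 = np.sin(th1)
    s2 = np.sin(th2)
    c1 = np.cos(th1)
    c2 = np.cos(th2)
    V = v0
    dVg = 0.0
    dV1 = 0.0
    dV2 = 0.0
    p1 = 1.0
    p2 = 1.0
    for m in range(ng):
        j = m + 1
        p1 *= s1
        p2 *= s2
        cj = np.cos(j * ga)
        sj = np.sin(j * ga)
        V += cv[m] * p1 * p2 * cj
        dVg -= cv[m] * p1 * p2 * j * sj
        # d(s^j)/dθ = j·s^(j−1)·cosθ
        if s1 > 1e-12:
            dV1 += cv[m] * j * (p1 / s1) * c1 * p2 * cj
        elif j == 1:
            dV1 += cv[m] * c1 * p2 * cj
        if s2 > 1e-12:
            dV2 += cv[m] * j * (p2 / s2) * c2 * p1 * cj
        elif j == 1:
            dV2 += cv[m] * c2 * p1 * cj
    return V, dVg, dV1, dV2


@njit(cache=True)
def _anchor(ca_i, sc_i, mode, val, M):
    """Anchor point X on the Cα→SC axis; fills the 3x3 map M.

    mode 0: X = Cα + f·(SC−Cα) (fraction f=val).
    mode 1: X = Cα + t·û (absolute offset t=val Å).
    Gradients map as gCα += gX − M·gX, gSC += M·gX with M = f·I
    (mode 0) or t(I−ûûᵀ)/r (mode 1).
    """
    X = np.empty(3)
    if mode == 0:
        f = val
        for a in range(3):
            for b in range(3):
                M[a, b] = 0.0
            M[a, a] = f
            X[a] = ca_i[a] + f * (sc_i[a] - ca_i[a])
    else:
        wx = sc_i[0] - ca_i[0]
        wy = sc_i[1] - ca_i[1]
        wz = sc_i[2] - ca_i[2]
        r = np.sqrt(wx * wx + wy * wy + wz * wz)
        ux = wx / r
        uy = wy / r
        uz = wz / r
        X[0] = ca_i[0] + val * ux
        X[1] = ca_i[1] + val * uy
        X[2] = ca_i[2] + val * uz
        _proj_scaled(ux, uy, uz, r / val, M)
    return X


@njit(cache=True)
def xlms_energy(
    ca, sc,
    xf_i, xf_j, xf_site, xf_dl, xf_du, xf_A, xf_sig,
    xs_i, xs_j, xs_a, xs_b, xs_c, xs_sig, xs_A, rt,
    xm_i, xm_j, xm_mode, xm_vi, xm_vj, xm_p,
    mdw_a, mdw_k, mdw_d0, mdw_n,
    mth_a0, mth_a, mth_b, mth_n,
    mg_v0, mg_c, mg_n,
    weight, gca, gsc, per_v,
):
    """All three crosslink restraint families; gradient added in place.

    per_v collects per-restraint energies in order (flat-bottom,
    statistical, MD-derived); returns the raw total.
    """
    total = 0.0
    idx = 0
    G3 = np.empty((3, 3))
    G3b = np.empty((3, 3))
    G4 = np.empty((4, 3))
    Mi = np.empty((3, 3))
    Mj = np.empty((3, 3))
    # flat-bottom family (κ = 0)
    for r in range(xf_i.shape[0]):
        i = xf_i[r]
        j = xf_j[r]
        if xf_site[r] == 0:
            w = ca[i] - ca[j]
        else:
            w = sc[i] - sc[j]
        d = np.sqrt(w[0] ** 2 + w[1] ** 2 + w[2] ** 2)
        V, dV = vcont(d, xf_dl[r], xf_du[r], xf_A[r], xf_sig[r], 0.0)
        per_v[idx] = V
        idx += 1
        total += V
        if dV != 0.0 and d > 1e-12:
            c = weight * dV / d
            for a in range(3):
                if xf_site[r] == 0:
                    gca[i, a] += c * w[a]
                    gca[j, a] -= c * w[a]
                else:
                    gsc[i, a] += c * w[a]
                    gsc[j, a] -= c * w[a]
    # statistical family
    for r in range(xs_i.shape[0]):
        i = xs_i[r]
        j = xs_j[r]
        w = ca[i] - ca[j]
        d = np.sqrt(w[0] ** 2 + w[1] ** 2 + w[2] ** 2)
        V, dV = xl_statistical(d, xs_a[r], xs_b[r], xs_c[r], xs_sig[r], xs_A[r], rt)
        per_v[idx] = V
        idx += 1
        total += V
        c = weight * dV / d
        for a in range(3):
            gca[i, a] += c * w[a]
            gca[j, a] -= c * w[a]
    # MD-derived anchor-geometry family
    for r in range(xm_i.shape[0]):
        i = xm_i[r]
        j = xm_j[r]
        p = xm_p[r]
        Xi = _anchor(ca[i], sc[i], xm_mode[r], xm_vi[r], Mi)
        Xj = _anchor(ca[j], sc[j], xm_mode[r], xm_vj[r], Mj)
        P1 = ca[i]
        P4 = ca[j]
        gP1 = np.zeros(3)
        gP2 = np.zeros(3)
        gP3 = np.zeros(3)
        gP4 = np.zeros(3)
        V = 0.0
        # three distance wells: d_Xi = |P1−Xi|, d_Xj = |P4−Xj|, d_XiXj
        for leg in range(3):
            if leg == 0:
                wv = Xi - P1
            elif leg == 1:
                wv = Xj - P4
            else:
                wv = Xj - Xi
            d = np.sqrt(wv[0] ** 2 + wv[1] ** 2 + wv[2] ** 2)
            if d < 1e-12:
                continue
            Vd, dVd = xl_vd(d, mdw_a[p, leg], mdw_k[p, leg], mdw_d0[p, leg], mdw_n[p, leg])
            V += Vd
            u = wv / d
            if leg == 0:
                for a in range(3):
                    gP2[a] += dVd * u[a]
                    gP1[a] -= dVd * u[a]
            elif leg == 1:
                for a in range(3):
                    gP3[a] += dVd * u[a]
                    gP4[a] -= dVd * u[a]
            else:
                for a in range(3):
                    gP3[a] += dVd * u[a]
                    gP2[a] -= dVd * u[a]
        # bond angles at the anchors
        th1 = _angle_into(P1, Xi, Xj, G3)
        Vt1, dVt1 = xl_vtheta(th1, mth_a0[p, 0], mth_a[p, 0], mth_b[p, 0], mth_n[p, 0])
        th2 = _angle_into(Xi, Xj, P4, G3b)
        Vt2, dVt2 = xl_vtheta(th2, mth_a0[p, 1], mth_a[p, 1], mth_b[p, 1], mth_n[p, 1])
        V += Vt1 + Vt2
        for a in range(3):
            gP1[a] += dVt1 * G3[0, a]
            gP2[a] += dVt1 * G3[1, a] + dVt2 * G3b[0, a]
            gP3[a] += dVt1 * G3[2, a] + dVt2 * G3b[1, a]
            gP4[a] += dVt2 * G3b[2, a]
        # dihedral of the Cα_i⋯X_i⋯X_j⋯Cα_j moiety
        ga_, ok = _dih_into(P1, Xi, Xj, P4, G4)
        Vg, dVg, dV1, dV2 = xl_vgamma(ga_, th1, th2, mg_v0[p], mg_c[p], mg_n[p])
        V += Vg
        for a in range(3):
            gP1[a] += dV1 * G3[0, a]
            gP2[a] += dV1 * G3[1, a] + dV2 * G3b[0, a]
            gP3[a] += dV1 * G3[2, a] + dV2 * G3b[1, a]
            gP4[a] += dV2 * G3b[2, a]
        if ok:
            for a in range(3):
                gP1[a] += dVg * G4[0, a]
                gP2[a] += dVg * G4[1, a]
                gP3[a] += dVg * G4[2, a]
                gP4[a] += dVg * G4[3, a]
        per_v[idx] = V
        idx += 1
        total += V
        # map anchor gradients to sites: gCα += (I−M)gX, gSC += M gX
        for a in range(3):
            mi = Mi[a, 0] * gP2[0] + Mi[a, 1] * gP2[1] + Mi[a, 2] * gP2[2]
            mj = Mj[a, 0] * gP3[0] + Mj[a, 1] * gP3[1] + Mj[a, 2] * gP3[2]
            gca[i, a] += weight * (gP1[a] + gP2[a] - mi)
            gsc[i, a] += weight * mi
            gca[j, a] += weight * (gP4[a] + gP3[a] - mj)
            gsc[j, a] += weight * mj
    return total


# ---------------------------------------------------------------------------
# SAXS restraint kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def saxs_occupancy(ca, rc, nsat):
    """Clamped neighbor occupancy x_i ∈ [0,1] per residue.

    Counts residues j with |Cα_i−Cα_j| < rc, excluding sequence
    neighbors ±1, saturating at nsat.
    """
    n = ca.shape[0]
    x = np.zeros(n)
    rc2 = rc * rc
    for i in range(n):
        cnt = 0
        for j in range(n):
            if j == i or j == i - 1 or j == i + 1:
                continue
            wx = ca[i, 0] - ca[j, 0]
            wy = ca[i, 1] - ca[j, 1]
            wz = ca[i, 2] - ca[j, 2]
            if wx * wx + wy * wy + wz * wz < rc2:
                cnt += 1
        xi = cnt / nsat
        x[i] = 1.0 if xi > 1.0 else xi
    return x


@njit(cache=True)
def saxs_r0(x, rho, sig_min, sig_max):
    """Effective kernel radius r°_i = ρ_i + σmax + (σmin−σmax)(x_i+1)/2."""
    n = x.shape[0]
    r0 = np.empty(n)
    for i in range(n):
        r0[i] = rho[i] + sig_max + (sig_min - sig_max) * (x[i] + 1.0) * 0.5
    return r0


@njit(cache=True)
def saxs_pcalc(ca, r0, rk, dr):
    """Log-normal pair-distance distribution P^calc on bin centers rk.

    Returns (p, S, A): normalized probability, raw kernel sums and the
    normalizer A = Δr·ΣS.
    """
    n = ca.shape[0]
    M = rk.shape[0]
    S = np.zeros(M)
    lnrk = np.log(rk)
    for i in range(n):
        for j in range(i):
            wx = ca[i, 0] - ca[j, 0]
            wy = ca[i, 1] - ca[j, 1]
            wz = ca[i, 2] - ca[j, 2]
            rij = np.sqrt(wx * wx + wy * wy + wz * wz)
            sij = (r0[i] + r0[j]) / rij
            lnr = np.log(rij)
            inv2s2 = 1.0 / (2.0 * sij * sij)
            for k in range(M):
                u = lnr - lnrk[k]
                S[k] += np.exp(-u * u * inv2s2)
    A = 0.0
    for k in range(M):
        A += S[k]
    A *= dr
    p = S / A
    return p, S, A


@njit(cache=True)
def saxs_energy_grad(ca, r0, rk, dr, pexp, eps_floor, weight, gca):
    """Cross-entropy SAXS penalty and its Cα gradient (added in place).

    The occupancy-dependent radii r0 are treated as locally constant
    (they are a clamped discrete count).  Returns the raw penalty.
    """
    n = ca.shape[0]
    M = rk.shape[0]
    p, S, A = saxs_pcalc(ca, r0, rk, dr)
    V = 0.0
    cexp = 0.0
    coef = np.zeros(M)
    for k in range(M):
        if p[k] > eps_floor:
            V -= dr * pexp[k] * np.log(p[k])
            cexp += dr * pexp[k]
            coef[k] = -dr * pexp[k] / S[k]
        else:
            V -= dr * pexp[k] * np.log(eps_floor)
    for k in range(M):
        coef[k] += cexp * dr / A
    lnrk = np.log(rk)
    for i in range(n):
        for j in range(i):
            wx = ca[i, 0] - ca[j, 0]
            wy = ca[i, 1] - ca[j, 1]
            wz = ca[i, 2] - ca[j, 2]
            rij = np.sqrt(wx * wx + wy * wy + wz * wz)
            sij = (r0[i] + r0[j]) / rij
            lnr = np.log(rij)
            s2 = sij * sij
            g = 0.0
            for k in range(M):
                u = lnr - lnrk[k]
                e = np.exp(-u * u / (2.0 * s2))
                # de/dr_ij includes the σ_ij(r_ij) dependence
                g += coef[k] * (-e * (u + u * u) / (s2 * rij))
            c = weight * g / rij
            gca[i, 0] += c * wx
            gca[i, 1] += c * wy
            gca[i, 2] += c * wz
            gca[j, 0] -= c * wx
            gca[j, 1] -= c * wy
            gca[j, 2] -= c * wz
    return V


# ---------------------------------------------------------------------------
# combined potential
# ---------------------------------------------------------------------------

@njit(cache=True)
def total_force(ca, sc, args):
    """Restrained potential V = U + Σ w·V_block and its gradient.

    Returns (V, gca, gsc, blocks) with blocks the raw (unweighted)
    values [U, Vθ, Vγ, V_dist, V_xlms, V_saxs].
    """
    (
        tidx, sc_eps, sc_sig, b0, scal, tor_c, pref,
        ang_kind, ang_idx, ang_xl, ang_xu,
        uq_res, uq_cls, mem_p1, mem_p2,
        gs, m_dl, m_du, m_A, m_sig, m_kap, g_alpha,
        hn_c, ha_c, pads, fast,
        xf_i, xf_j, xf_site, xf_dl, xf_du, xf_A, xf_sig,
        xs_i, xs_j, xs_a, xs_b, xs_c, xs_sig, xs_A, rt,
        xm_i, xm_j, xm_mode, xm_vi, xm_vj, xm_p,
        mdw_a, mdw_k, mdw_d0, mdw_n,
        mth_a0, mth_a, mth_b, mth_n,
        mg_v0, mg_c, mg_n,
        sx_rho, sx_smin, sx_smax, sx_rc, sx_nsat, sx_rk, sx_dr, sx_pexp, sx_eps,
        rw,
    ) = args
    terms, gca, gsc = ff_energy(ca, sc, tidx, sc_eps, sc_sig, b0, scal, tor_c, pref)
    blocks = np.zeros(6)
    U = 0.0
    for t in range(N_TERMS):
        U += pref[t] * terms[t]
    blocks[0] = U
    if ang_kind.shape[0] > 0:
        vth, vga = nmr_angular_energy(ca, ang_kind, ang_idx, ang_xl, ang_xu, gca, rw[0], rw[1])
        blocks[1] = vth
        blocks[2] = vga
    if gs.shape[0] > 1:
        gv = np.zeros(gs.shape[0] - 1)
        blocks[3] = nmr_distance_energy(
            ca, sc, uq_res, uq_cls, mem_p1, mem_p2,
            gs, m_dl, m_du, m_A, m_sig, m_kap, g_alpha,
            hn_c, ha_c, pads, tidx, rw[2], fast, gca, gsc, gv,
        )
    nxl = xf_i.shape[0] + xs_i.shape[0] + xm_i.shape[0]
    if nxl > 0:
        pv = np.zeros(nxl)
        blocks[4] = xlms_energy(
            ca, sc,
            xf_i, xf_j, xf_site, xf_dl, xf_du, xf_A, xf_sig,
            xs_i, xs_j, xs_a, xs_b, xs_c, xs_sig, xs_A, rt,
            xm_i, xm_j, xm_mode, xm_vi, xm_vj, xm_p,
            mdw_a, mdw_k, mdw_d0, mdw_n,
            mth_a0, mth_a, mth_b, mth_n,
            mg_v0, mg_c, mg_n,
            rw[3], gca, gsc, pv,
        )
    if sx_rk.shape[0] > 0:
        x = saxs_occupancy(ca, sx_rc, sx_nsat)
        r0 = saxs_r0(x, sx_rho, sx_smin, sx_smax)
        blocks[5] = saxs_energy_grad(ca, r0, sx_rk, sx_dr, sx_pexp, sx_eps, rw[4], gca)
    V = blocks[0] + rw[0] * blocks[1] + rw[1] * blocks[2] + rw[2] * blocks[3] \
        + rw[3] * blocks[4] + rw[4] * blocks[5]
    return V, gca, gsc, blocks


# ---------------------------------------------------------------------------
# MD integrators
# ---------------------------------------------------------------------------

@njit(cache=True)
def kinetic_energy(vca, vsc, mca, msc):
    ke = 0.0
    n = vca.shape[0]
    for i in range(n):
        ke += mca[i] * (vca[i, 0] ** 2 + vca[i, 1] ** 2 + vca[i, 2] ** 2)
        ke += msc[i] * (vsc[i, 0] ** 2 + vsc[i, 1] ** 2 + vsc[i, 2] ** 2)
    return 0.5 * ke / _ACC


@njit(cache=True)
def md_chunk(
    ca, sc, vca, vsc, mca, msc, args,
    n_steps, dt, thermo, tbath, tau, fric, seed,
    log_interval, epot_trace, ekin_trace,
):
    """Velocity-Verlet MD chunk, mutating coordinates/velocities in place.

    thermo: 0 none (NVE), 1 Berendsen, 2 Langevin (BAOAB splitting).
    Returns (status, n_trace): status 1 flags an energy explosion.
    Bitwise reproducible for a given seed.
    """
    np.random.seed(seed)
    n = ca.shape[0]
    V, gca, gsc, blocks = total_force(ca, sc, args)
    ndof = 6.0 * n
    ntr = 0
    c1 = np.exp(-fric * dt)
    for step in range(n_steps):
        if thermo == 2:
            # B: half kick
            for i in range(n):
                fa = 0.5 * dt * _ACC / mca[i]
                fs = 0.5 * dt * _ACC / msc[i]
                for a in range(3):
                    vca[i, a] -= fa * gca[i, a]
                    vsc[i, a] -= fs * gsc[i, a]
            # A: half drift
            for i in range(n):
                for a in range(3):
                    ca[i, a] += 0.5 * dt * vca[i, a]
                    sc[i, a] += 0.5 * dt * vsc[i, a]
            # O: Ornstein-Uhlenbeck
            for i in range(n):
                sca = np.sqrt((1.0 - c1 * c1) * _KB * tbath * _ACC / mca[i])
                ssc = np.sqrt((1.0 - c1 * c1) * _KB * tbath * _ACC / msc[i])
                for a in range(3):
                    vca[i, a] = c1 * vca[i, a] + sca * np.random.standard_normal()
                    vsc[i, a] = c1 * vsc[i, a] + ssc * np.random.standard_normal()
            # A: half drift
            for i in range(n):
                for a in range(3):
                    ca[i, a] += 0.5 * dt * vca[i, a]
                    sc[i, a] += 0.5 * dt * vsc[i, a]
            V, gca, gsc, blocks = total_force(ca, sc, args)
            # B: half kick
            for i in range(n):
                fa = 0.5 * dt * _ACC / mca[i]
                fs = 0.5 * dt * _ACC / msc[i]
                for a in range(3):
                    vca[i, a] -= fa * gca[i, a]
                    vsc[i, a] -= fs * gsc[i, a]
        else:
            for i in range(n):
                fa = 0.5 * dt * _ACC / mca[i]
                fs = 0.5 * dt * _ACC / msc[i]
                for a in range(3):
                    vca[i, a] -= fa * gca[i, a]
                    vsc[i, a] -= fs * gsc[i, a]
                    ca[i, a] += dt * vca[i, a]
                    sc[i, a] += dt * vsc[i, a]
            V, gca, gsc, blocks = total_force(ca, sc, args)
            for i in range(n):
                fa = 0.5 * dt * _ACC / mca[i]
                fs = 0.5 * dt * _ACC / msc[i]
                for a in range(3):
                    vca[i, a] -= fa * gca[i, a]
                    vsc[i, a] -= fs * gsc[i, a]
            if thermo == 1:
                ke = kinetic_energy(vca, vsc, mca, msc)
                tkin = 2.0 * ke / (_KB * ndof)
                if tkin > 1e-12:
                    arg = 1.0 + (dt / tau) * (tbath / tkin - 1.0)
                    if arg < 1e-4:
                        arg = 1e-4
                    lam = np.sqrt(arg)
                    for i in range(n):
                        for a in range(3):
                            vca[i, a] *= lam
                            vsc[i, a] *= lam
        if not np.isfinite(V) or abs(V) > 1e8:
            return 1, ntr
        if log_interval > 0 and (step + 1) % log_interval == 0:
            epot_trace[ntr] = V
            ekin_trace[ntr] = kinetic_energy(vca, vsc, mca, msc)
            ntr += 1
    return 0, ntr
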