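"""Numba kernels for Gaussian integrals (McMurchie-Davidson scheme).

All kernels operate on packed shell arrays (see `basis.BasisSet`) and produce
blocks over *raw Cartesian* components ordered lx-major descending; the
spherical transformation happens in `integrals`. Internal units are Bohr/Ha.

Angular momenta up to l=3 plus one raising unit for derivatives are supported
by the scratch-array sizing below.
"""

import numpy as np
from numba import njit

# max l supported including the +1 raise used by derivative integrals
_LMAX = 4
_EDIM = _LMAX + 3          # room for the kinetic +2 extension
_RDIM = 4 * _LMAX + 3


@njit(cache=True)
def _boys(mmax, x, out):
    """Boys function F_m(x) for m = 0..mmax (downward recursion, stable)."""
    if x < 1e-13:
        for m in range(mmax + 1):
            out[m] = 1.0 / (2 * m + 1)
        return
    if x > 40.0:
        # asymptotic regime: exp(-x) below double precision
        out[0] = 0.5 * np.sqrt(np.pi / x)
        for m in range(1, mmax + 1):
            out[m] = out[m - 1] * (2 * m - 1) / (2.0 * x)
        return
    # series for F_mmax, then downward recursion
    s = mmax + 0.5
    term = 1.0 / s
    acc = term
    k = 1
    while True:
        s += 1.0
        term *= x / s
        acc += term
        if term < 1e-17 * acc or k > 400:
            break
        k += 1
    ex = np.exp(-x)
    out[mmax] = 0.5 * ex * acc
    for m in range(mmax - 1, -1, -1):
        out[m] = (2.0 * x * out[m + 1] + ex) / (2 * m + 1)


@njit(cache=True)
def _fill_E(imax, jmax, a, b, AB, E):
    """Hermite expansion coefficients E[i, j, t] for one Cartesian direction.

    AB = A - B. E must have shape >= (imax+1, jmax+1, imax+jmax+2).
    """
    p = a + b
    for i in range(imax + 1):
        for j in range(jmax + 1):
            for t in range(imax + jmax + 2):
                E[i, j, t] = 0.0
    E[0, 0, 0] = np.exp(-a * b / p * AB * AB)
    xpa = -b / p * AB
    xpb = a / p * AB
    inv2p = 0.5 / p
    for i in range(imax):
        for t in range(i + 2):
            v = xpa * E[i, 0, t]
            if t > 0:
                v += inv2p * E[i, 0, t - 1]
            v += (t + 1) * E[i, 0, t + 1]
            E[i + 1, 0, t] = v
    for i in range(imax + 1):
        for j in range(jmax):
            for t in range(i + j + 2):
                v = xpb * E[i, j, t]
                if t > 0:
                    v += inv2p * E[i, j, t - 1]
                v += (t + 1) * E[i, j, t + 1]
                E[i, j + 1, t] = v


@njit(cache=True)
def _fill_R(L, p, X, Y, Z, Rn, F):
    """Hermite Coulomb integrals R^0_{tuv} for t+u+v <= L into Rn[0].

    Rn has shape (L+2, L+2, L+2, L+2) indexed [n, t, u, v]; F is scratch.
    """
    T = p * (X * X + Y * Y + Z * Z)
    _boys(L, T, F)
    for n in range(L + 1):
        for t in range(L + 1):
            for u in range(L + 1):
                for v in range(L + 1):
                    Rn[n, t, u, v] = 0.0
    m2p = -2.0 * p
    fac = 1.0
    for n in range(L + 1):
        Rn[n, 0, 0, 0] = fac * F[n]
        fac *= m2p
    for total in range(1, L + 1):
        for t in range(total + 1):
            for u in range(total - t + 1):
                v = total - t - u
                for n in range(L - total + 1):
                    if t > 0:
                        val = X * Rn[n + 1, t - 1, u, v]
                        if t > 1:
                            val += (t - 1) * Rn[n + 1, t - 2, u, v]
                    elif u > 0:
                        val = Y * Rn[n + 1, t, u - 1, v]
                        if u > 1:
                            val += (u - 1) * Rn[n + 1, t, u - 2, v]
                    else:
                        val = Z * Rn[n + 1, t, u, v - 1]
                        if v > 1:
                            val += (v - 1) * Rn[n + 1, t, u, v - 2]
                    Rn[n, t, u, v] = val


@njit(cache=True)
def _ncart(l):
    return (l + 1) * (l + 2) // 2


@njit(cache=True)
def _comp_of(l, idx):
    """idx-th Cartesian component (lx, ly, lz) of shell l, lx-major order."""
    k = 0
    for lx in range(l, -1, -1):
        for ly in range(l - lx, -1, -1):
            if k == idx:
                return lx, ly, l - lx - ly
            k += 1
    return 0, 0, 0


# ---------------------------------------------------------------- one-electron


@njit(cache=True)
def build_one_electron(nsh, shell_l, shell_atom, shell_pstart, shell_nprim,
                       shell_cstart, prim_exp, prim_coef, coords, charges,
                       S, T, V, DX, DY, DZ):
    """Fill Cartesian S, T, V(nuclear attraction) and dipole matrices."""
    natm = coords.shape[0]
    Ex = np.zeros((_EDIM, _EDIM, 2 * _EDIM))
    Ey = np.zeros((_EDIM, _EDIM, 2 * _EDIM))
    Ez = np.zeros((_EDIM, _EDIM, 2 * _EDIM))
    Rn = np.zeros((_RDIM, _RDIM, _RDIM, _RDIM))
    F = np.zeros(_RDIM)
    for ish in range(nsh):
        la = shell_l[ish]
        A = coords[shell_atom[ish]]
        nca = _ncart(la)
        for jsh in range(ish + 1):
            lb = shell_l[jsh]
            B = coords[shell_atom[jsh]]
            ncb = _ncart(lb)
            i0 = shell_cstart[ish]
            j0 = shell_cstart[jsh]
            for ip in range(shell_nprim[ish]):
                a = prim_exp[shell_pstart[ish] + ip]
                ca = prim_coef[shell_pstart[ish] + ip]
                for jp in range(shell_nprim[jsh]):
                    b = prim_exp[shell_pstart[jsh] + jp]
                    cb = prim_coef[shell_pstart[jsh] + jp]
                    p = a + b
                    cc = ca * cb
                    mu = a * b / p
                    rab2 = ((A[0] - B[0]) ** 2 + (A[1] - B[1]) ** 2
                            + (A[2] - B[2]) ** 2)
                    if abs(cc) * np.exp(-mu * rab2) < 1e-16:
                        continue
                    _fill_E(la, lb + 2, a, b, A[0] - B[0], Ex)
                    _fill_E(la, lb + 2, a, b, A[1] - B[1], Ey)
                    _fill_E(la, lb + 2, a, b, A[2] - B[2], Ez)
                    Px = (a * A[0] + b * B[0]) / p
                    Py = (a * A[1] + b * B[1]) / p
                    Pz = (a * A[2] + b * B[2]) / p
                    pref = cc * (np.pi / p) ** 1.5
                    L = la + lb
                    for ia in range(nca):
                        ix, iy, iz = _comp_of(la, ia)
                        for jb in range(ncb):
                            jx, jy, jz = _comp_of(lb, jb)
                            sx = Ex[ix, jx, 0]
                            sy = Ey[iy, jy, 0]
                            sz = Ez[iz, jz, 0]
                            s00 = sx * sy * sz
                            S[i0 + ia, j0 + jb] += pref * s00
                            # dipole (about the origin)
                            DX[i0 + ia, j0 + jb] += pref * (Ex[ix, jx, 1] + Px * sx) * sy * sz
                            DY[i0 + ia, j0 + jb] += pref * sx * (Ey[iy, jy, 1] + Py * sy) * sz
                            DZ[i0 + ia, j0 + jb] += pref * sx * sy * (Ez[iz, jz, 1] + Pz * sz)
                            # kinetic
                            t_val = b * (2 * (jx + jy + jz) + 3) * s00
                            t_val -= 2.0 * b * b * (Ex[ix, jx + 2, 0] * sy * sz
                                                    + sx * Ey[iy, jy + 2, 0] * sz
                                                    + sx * sy * Ez[iz, jz + 2, 0])
                            if jx > 1:
                                t_val -= 0.5 * jx * (jx - 1) * Ex[ix, jx - 2, 0] * sy * sz
                            if jy > 1:
                                t_val -= 0.5 * jy * (jy - 1) * sx * Ey[iy, jy - 2, 0] * sz
                            if jz > 1:
                                t_val -= 0.5 * jz * (jz - 1) * sx * sy * Ez[iz, jz - 2, 0]
                            T[i0 + ia, j0 + jb] += pref * t_val
                    # nuclear attraction
                    vfac = cc * 2.0 * np.pi / p
                    for iat in range(natm):
                        C = coords[iat]
                        _fill_R(L, p, Px - C[0], Py - C[1], Pz - C[2], Rn, F)
                        Z = charges[iat]
                        for ia in range(nca):
                            ix, iy, iz = _comp_of(la, ia)
                            for jb in range(ncb):
                                jx, jy, jz = _comp_of(lb, jb)
                                acc = 0.0
                                for t in range(ix + jx + 1):
                                    for u in range(iy + jy + 1):
                                        for v in range(iz + jz + 1):
                                            acc += (Ex[ix, jx, t] * Ey[iy, jy, u]
                                                    * Ez[iz, jz, v] * Rn[0, t, u, v])
                                V[i0 + ia, j0 + jb] -= Z * vfac * acc
    # symmetrize
    n = S.shape[0]
    for i in range(n):
        for j in range(i):
            S[j, i] = S[i, j]
            T[j, i] = T[i, j]
            V[j, i] = V[i, j]
            DX[j, i] = DX[i, j]
            DY[j, i] = DY[i, j]
            DZ[j, i] = DZ[i, j]


@njit(cache=True)
def build_vnuc_single(nsh, shell_l, shell_atom, shell_pstart, shell_nprim,
                      shell_cstart, prim_exp, prim_coef, coords,
                      center, charge, V):
    """Nuclear-attraction matrix for a single point charge at `center`."""
    Ex = np.zeros((_EDIM, _EDIM, 2 * _EDIM))
    Ey = np.zeros((_EDIM, _EDIM, 2 * _EDIM))
    Ez = np.zeros((_EDIM, _EDIM, 2 * _EDIM))
    Rn = np.zeros((_RDIM, _RDIM, _RDIM, _RDIM))
    F = np.zeros(_RDIM)
    for ish in range(nsh):
        la = shell_l[ish]
        A = coords[shell_atom[ish]]
        nca = _ncart(la)
        for jsh in range(ish + 1):
            lb = shell_l[jsh]
            B = coords[shell_atom[jsh]]
            ncb = _ncart(lb)
            i0 = shell_cstart[ish]
            j0 = shell_cstart[jsh]
            for ip in range(shell_nprim[ish]):
                a = prim_exp[shell_pstart[ish] + ip]
                ca = prim_coef[shell_pstart[ish] + ip]
                for jp in range(shell_nprim[jsh]):
                    b = prim_exp[shell_pstart[jsh] + jp]
                    cb = prim_coef[shell_pstart[jsh] + jp]
                    p = a + b
                    _fill_E(la, lb, a, b, A[0] - B[0], Ex)
                    _fill_E(la, lb, a, b, A[1] - B[1], Ey)
                    _fill_E(la, lb, a, b, A[2] - B[2], Ez)
                    Px = (a * A[0] + b * B[0]) / p
                    Py = (a * A[1] + b * B[1]) / p
                    Pz = (a * A[2] + b * B[2]) / p
                    _fill_R(la + lb, p, Px - center[0], Py - center[1],
                            Pz - center[2], Rn, F)
                    vfac = ca * cb * 2.0 * np.pi / p
                    for ia in range(nca):
                        ix, iy, iz = _comp_of(la, ia)
                        for jb in range(ncb):
                            jx, jy, jz = _comp_of(lb, jb)
                            acc = 0.0
                            for t in range(ix + jx + 1):
                                for u in range(iy + jy + 1):
                                    for v in range(iz + jz + 1):
                                        acc += (Ex[ix, jx, t] * Ey[iy, jy, u]
                                                * Ez[iz, jz, v] * Rn[0, t, u, v])
                            V[i0 + ia, j0 + jb] -= charge * vfac * acc
    n = V.shape[0]
    for i in range(n):
        for j in range(i):
            V[j, i] = V[i, j]


# -------------------------------------------------------------------- ERIs


@njit(cache=True)
def schwarz_bounds(nsh, shell_l, shell_atom, shell_pstart, shell_nprim,
                   shell_cstart, prim_exp, prim_coef, coords, Q):
    """Q[i, j] = sqrt(max_component (ij|ij)) for shell-pair screening."""
    E1x = np.zeros((_EDIM, _EDIM, 2 * _EDIM))
    E1y = np.zeros((_EDIM, _EDIM, 2 * _EDIM))
    E1z = np.zeros((_EDIM, _EDIM, 2 * _EDIM))
    Rn = np.zeros((_RDIM, _RDIM, _RDIM, _RDIM))
    F = np.zeros(_RDIM)
    for ish in range(nsh):
        la = shell_l[ish]
        A = coords[shell_atom[ish]]
        nca = _ncart(la)
        for jsh in range(ish + 1):
            lb = shell_l[jsh]
            B = coords[shell_atom[jsh]]
            ncb = _ncart(lb)
            rab2 = ((A[0] - B[0]) ** 2 + (A[1] - B[1]) ** 2
                    + (A[2] - B[2]) ** 2)
            block = np.zeros((nca, ncb))
            E2x = np.zeros((_EDIM, _EDIM, 2 * _EDIM))
            E2y = np.zeros((_EDIM, _EDIM, 2 * _EDIM))
            E2z = np.zeros((_EDIM, _EDIM, 2 * _EDIM))
            for ip in range(shell_nprim[ish]):
                a = prim_exp[shell_pstart[ish] + ip]
                ca = prim_coef[shell_pstart[ish] + ip]
                for jp in range(shell_nprim[jsh]):
                    b = prim_exp[shell_pstart[jsh] + jp]
                    cb = prim_coef[shell_pstart[jsh] + jp]
                    p = a + b
                    kab = np.exp(-a * b / p * rab2)
                    if abs(ca * cb) * kab < 1e-16:
                        continue
                    _fill_E(la, lb, a, b, A[0] - B[0], E1x)
                    _fill_E(la, lb, a, b, A[1] - B[1], E1y)
                    _fill_E(la, lb, a, b, A[2] - B[2], E1z)
                    Px = (a * A[0] + b * B[0]) / p
                    Py = (a * A[1] + b * B[1]) / p
                    Pz = (a * A[2] + b * B[2]) / p
                    for kp in range(shell_nprim[ish]):
                        c = prim_exp[shell_pstart[ish] + kp]
                        cc = prim_coef[shell_pstart[ish] + kp]
                        for lp in range(shell_nprim[jsh]):
                            dd = prim_exp[shell_pstart[jsh] + lp]
                            cd = prim_coef[shell_pstart[jsh] + lp]
                            q = c + dd
                            kcd = np.exp(-c * dd / q * rab2)
                            if abs(cc * cd) * kcd < 1e-16:
                                continue
                            _fill_E(la, lb, c, dd, A[0] - B[0], E2x)
                            _fill_E(la, lb, c, dd, A[1] - B[1], E2y)
                            _fill_E(la, lb, c, dd, A[2] - B[2], E2z)
                            Qx = (c * A[0] + dd * B[0]) / q
                            Qy = (c * A[1] + dd * B[1]) / q
                            Qz = (c * A[2] + dd * B[2]) / q
                            alpha = p * q / (p + q)
                            L = 2 * (la + lb)
                            _fill_R(L, alpha, Px - Qx, Py - Qy, Pz - Qz,
                                    Rn, F)
                            pref = (ca * cb * cc * cd * 2.0 * np.pi ** 2.5
                                    / (p * q * np.sqrt(p + q)))
                            for bi in range(nca):
                                ix, iy, iz = _comp_of(la, bi)
                                for bj in range(ncb):
                                    jx, jy, jz = _comp_of(lb, bj)
                                    block[bi, bj] += pref * _md_eri_component(
                                        ix, iy, iz, jx, jy, jz,
                                        ix, iy, iz, jx, jy, jz,
                                        E1x, E1y, E1z, E2x, E2y, E2z, Rn)
            best = 0.0
            for bi in range(nca):
                for bj in range(ncb):
                    if abs(block[bi, bj]) > best:
                        best = abs(block[bi, bj])
            Q[ish, jsh] = np.sqrt(best)
            Q[jsh, ish] = Q[ish, jsh]


@njit(cache=True)
def _md_eri_component(ix, iy, iz, jx, jy, jz, kx, ky, kz, lx, ly, lz,
                      E1x, E1y, E1z, E2x, E2y, E2z, Rn):
    """MD contraction for one Cartesian component tuple of a prim quartet."""
    acc = 0.0
    for t in range(ix + jx + 1):
        for u in range(iy + jy + 1):
            for v in range(iz + jz + 1):
                e1 = E1x[ix, jx, t] * E1y[iy, jy, u] * E1z[iz, jz, v]
                if e1 == 0.0:
                    continue
                acc2 = 0.0
                for tau in range(kx + lx + 1):
                    for nu in range(ky + ly + 1):
                        for phi in range(kz + lz + 1):
                            sg = 1.0 if (tau + nu + phi) % 2 == 0 else -1.0
                            acc2 += (sg * E2x[kx, lx, tau] * E2y[ky, ly, nu]
                                     * E2z[kz, lz, phi]
                                     * Rn[0, t + tau, u + nu, v + phi])
                acc += e1 * acc2
    return acc


@njit(cache=True)
def build_eri(nsh, shell_l, shell_atom, shell_pstart, shell_nprim,
              shell_cstart, prim_exp, prim_coef, coords, eri):
    """Dense Cartesian ERI tensor (chemists' notation (ij|kl))."""
    E1x = np.zeros((_EDIM, _EDIM, 2 * _EDIM))
    E1y = np.zeros((_EDIM, _EDIM, 2 * _EDIM))
    E1z = np.zeros((_EDIM, _EDIM, 2 * _EDIM))
    E2x = np.zeros((_EDIM, _EDIM, 2 * _EDIM))
    E2y = np.zeros((_EDIM, _EDIM, 2 * _EDIM))
    E2z = np.zeros((_EDIM, _EDIM, 2 * _EDIM))
    Rn = np.zeros((_RDIM, _RDIM, _RDIM, _RDIM))
    F = np.zeros(_RDIM)
    block = np.zeros((15, 15, 15, 15))
    Q = np.zeros((nsh, nsh))
    schwarz_bounds(nsh, shell_l, shell_atom, shell_pstart, shell_nprim,
                   shell_cstart, prim_exp, prim_coef, coords, Q)
    for ish in range(nsh):
        la = shell_l[ish]
        A = coords[shell_atom[ish]]
        nca = _ncart(la)
        for jsh in range(ish + 1):
            lb = shell_l[jsh]
            B = coords[shell_atom[jsh]]
            ncb = _ncart(lb)
            for ksh in range(ish + 1):
                lc = shell_l[ksh]
                C = coords[shell_atom[ksh]]
                ncc = _ncart(lc)
                lmax = jsh if ksh == ish else ksh
                for lsh in range(lmax + 1):
                    if Q[ish, jsh] * Q[ksh, lsh] < 1e-14:
                        continue
                    ld = shell_l[lsh]
                    D = coords[shell_atom[lsh]]
                    ncd = _ncart(ld)
                    for bi in range(nca):
                        for bj in range(ncb):
                            for bk in range(ncc):
                                for bl in range(ncd):
                                    block[bi, bj, bk, bl] = 0.0
                    for ip in range(shell_nprim[ish]):
                        a = prim_exp[shell_pstart[ish] + ip]
                        ca = prim_coef[shell_pstart[ish] + ip]
                        for jp in range(shell_nprim[jsh]):
                            b = prim_exp[shell_pstart[jsh] + jp]
                            cb = prim_coef[shell_pstart[jsh] + jp]
                            p = a + b
                            rab2 = ((A[0] - B[0]) ** 2 + (A[1] - B[1]) ** 2
                                    + (A[2] - B[2]) ** 2)
                            kab = np.exp(-a * b / p * rab2)
                            if abs(ca * cb) * kab < 1e-15:
                                continue
                            _fill_E(la, lb, a, b, A[0] - B[0], E1x)
                            _fill_E(la, lb, a, b, A[1] - B[1], E1y)
                            _fill_E(la, lb, a, b, A[2] - B[2], E1z)
                            Px = (a * A[0] + b * B[0]) / p
                            Py = (a * A[1] + b * B[1]) / p
                            Pz = (a * A[2] + b * B[2]) / p
                            for kp in range(shell_nprim[ksh]):
                                c = prim_exp[shell_pstart[ksh] + kp]
                                cgk = prim_coef[shell_pstart[ksh] + kp]
                                for lp in range(shell_nprim[lsh]):
                                    d = prim_exp[shell_pstart[lsh] + lp]
                                    cgl = prim_coef[shell_pstart[lsh] + lp]
                                    q = c + d
                                    rcd2 = ((C[0] - D[0]) ** 2
                                            + (C[1] - D[1]) ** 2
                                            + (C[2] - D[2]) ** 2)
                                    kcd = np.exp(-c * d / q * rcd2)
                                    cfac = ca * cb * cgk * cgl
                                    if abs(cfac) * kab * kcd < 1e-15:
                                        continue
                                    _fill_E(lc, ld, c, d, C[0] - D[0], E2x)
                                    _fill_E(lc, ld, c, d, C[1] - D[1], E2y)
                                    _fill_E(lc, ld, c, d, C[2] - D[2], E2z)
                                    Qx = (c * C[0] + d * D[0]) / q
                                    Qy = (c * C[1] + d * D[1]) / q
                                    Qz = (c * C[2] + d * D[2]) / q
                                    alpha = p * q / (p + q)
                                    L = la + lb + lc + ld
                                    _fill_R(L, alpha, Px - Qx, Py - Qy,
                                            Pz - Qz, Rn, F)
                                    pref = (cfac * 2.0 * np.pi ** 2.5
                                            / (p * q * np.sqrt(p + q)))
                                    for bi in range(nca):
                                        ix, iy, iz = _comp_of(la, bi)
                                        for bj in range(ncb):
                                            jx, jy, jz = _comp_of(lb, bj)
                                            for bk in range(ncc):
                                                kx, ky, kz = _comp_of(lc, bk)
                                                for bl in range(ncd):
                                                    lx, ly, lz = _comp_of(ld, bl)
                                                    val = _md_eri_component(
                                                        ix, iy, iz, jx, jy, jz,
                                                        kx, ky, kz, lx, ly, lz,
                                                        E1x, E1y, E1z,
                                                        E2x, E2y, E2z, Rn)
                                                    block[bi, bj, bk, bl] += pref * val
                    i0 = shell_cstart[ish]
                    j0 = shell_cstart[jsh]
                    k0 = shell_cstart[ksh]
                    l0 = shell_cstart[lsh]
                    for bi in range(nca):
                        for bj in range(ncb):
                            for bk in range(ncc):
                                for bl in range(ncd):
                                    v = block[bi, bj, bk, bl]
                                    ii = i0 + bi
                                    jj = j0 + bj
                                    kk = k0 + bk
                                    ll = l0 + bl
                                    eri[ii, jj, kk, ll] = v
                                    eri[jj, ii, kk, ll] = v
                                    eri[ii, jj, ll, kk] = v
                                    eri[jj, ii, ll, kk] = v
                                    eri[kk, ll, ii, jj] = v
                                    eri[ll, kk, ii, jj] = v
                                    eri[kk, ll, jj, ii] = v
                                    eri[ll, kk, jj, ii] = v
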