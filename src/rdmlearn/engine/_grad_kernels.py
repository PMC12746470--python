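"""Numba kernels for derivative integrals and gradient contractions.

Derivatives are assembled by the angular-momentum raise/lower identity
d/dAx G(a, lx) = 2a G(lx+1) - lx G(lx-1); translational invariance supplies
the remaining center. All blocks are raw Cartesian (see `_kernels`).
"""

import numpy as np
from numba import njit

from ._kernels import (_EDIM, _RDIM, _comp_of, _fill_E, _fill_R,
                       _md_eri_component, _ncart, schwarz_bounds)


@njit(cache=True)
def _ov(ix, iy, iz, jx, jy, jz, Ex, Ey, Ez):
    if ix < 0 or iy < 0 or iz < 0 or jx < 0 or jy < 0 or jz < 0:
        return 0.0
    return Ex[ix, jx, 0] * Ey[iy, jy, 0] * Ez[iz, jz, 0]


@njit(cache=True)
def _kin(ix, iy, iz, jx, jy, jz, b, Ex, Ey, Ez):
    """Kinetic primitive integral over E tables (without (pi/p)^1.5)."""
    if ix < 0 or iy < 0 or iz < 0:
        return 0.0
    s00 = _ov(ix, iy, iz, jx, jy, jz, Ex, Ey, Ez)
    t = b * (2 * (jx + jy + jz) + 3) * s00
    t -= 2.0 * b * b * (_ov(ix, iy, iz, jx + 2, jy, jz, Ex, Ey, Ez)
                        + _ov(ix, iy, iz, jx, jy + 2, jz, Ex, Ey, Ez)
                        + _ov(ix, iy, iz, jx, jy, jz + 2, Ex, Ey, Ez))
    if jx > 1:
        t -= 0.5 * jx * (jx - 1) * _ov(ix, iy, iz, jx - 2, jy, jz, Ex, Ey, Ez)
    if jy > 1:
        t -= 0.5 * jy * (jy - 1) * _ov(ix, iy, iz, jx, jy - 2, jz, Ex, Ey, Ez)
    if jz > 1:
        t -= 0.5 * jz * (jz - 1) * _ov(ix, iy, iz, jx, jy, jz - 2, Ex, Ey, Ez)
    return t


@njit(cache=True)
def _vattr(ix, iy, iz, jx, jy, jz, Ex, Ey, Ez, Rn, dt, du, dv):
    """Hermite-Coulomb contraction with optional R-index shift (dt,du,dv)."""
    if ix < 0 or iy < 0 or iz < 0:
        return 0.0
    acc = 0.0
    for t in range(ix + jx + 1):
        for u in range(iy + jy + 1):
            for v in range(iz + jz + 1):
                acc += (Ex[ix, jx, t] * Ey[iy, jy, u] * Ez[iz, jz, v]
                        * Rn[0, t + dt, u + du, v + dv])
    return acc


@njit(cache=True)
def grad_one_electron(nsh, shell_l, shell_atom, shell_pstart, shell_nprim,
                      shell_cstart, prim_exp, prim_coef, coords, charges,
                      D, W, grad):
    """Accumulate Tr[D d(T+V)] - Tr[W dS] into grad (natm, 3)."""
    natm = coords.shape[0]
    Ex = np.zeros((_EDIM, _EDIM, 2 * _EDIM))
    Ey = np.zeros((_EDIM, _EDIM, 2 * _EDIM))
    Ez = np.zeros((_EDIM, _EDIM, 2 * _EDIM))
    Rn = np.zeros((_RDIM, _RDIM, _RDIM, _RDIM))
    F = np.zeros(_RDIM)
    dvc = np.zeros((natm, 3))
    for ish in range(nsh):
        la = shell_l[ish]
        ata = shell_atom[ish]
        A = coords[ata]
        nca = _ncart(la)
        for jsh in range(nsh):
            lb = shell_l[jsh]
            atb = shell_atom[jsh]
            B = coords[atb]
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
                    _fill_E(la + 1, lb + 2, a, b, A[0] - B[0], Ex)
                    _fill_E(la + 1, lb + 2, a, b, A[1] - B[1], Ey)
                    _fill_E(la + 1, lb + 2, a, b, A[2] - B[2], Ez)
                    Px = (a * A[0] + b * B[0]) / p
                    Py = (a * A[1] + b * B[1]) / p
                    Pz = (a * A[2] + b * B[2]) / p
                    pref = cc * (np.pi / p) ** 1.5
                    vfac = cc * 2.0 * np.pi / p
                    L = la + 1 + lb
                    for ia in range(nca):
                        ix, iy, iz = _comp_of(la, ia)
                        for jb in range(ncb):
                            jx, jy, jz = _comp_of(lb, jb)
                            dmat = D[i0 + ia, j0 + jb]
                            wmat = W[i0 + ia, j0 + jb]
                            # overlap + kinetic A-derivatives per component
                            for d in range(3):
                                if d == 0:
                                    sp1 = _ov(ix + 1, iy, iz, jx, jy, jz, Ex, Ey, Ez)
                                    sm1 = _ov(ix - 1, iy, iz, jx, jy, jz, Ex, Ey, Ez)
                                    tp1 = _kin(ix + 1, iy, iz, jx, jy, jz, b, Ex, Ey, Ez)
                                    tm1 = _kin(ix - 1, iy, iz, jx, jy, jz, b, Ex, Ey, Ez)
                                    li = ix
                                elif d == 1:
                                    sp1 = _ov(ix, iy + 1, iz, jx, jy, jz, Ex, Ey, Ez)
                                    sm1 = _ov(ix, iy - 1, iz, jx, jy, jz, Ex, Ey, Ez)
                                    tp1 = _kin(ix, iy + 1, iz, jx, jy, jz, b, Ex, Ey, Ez)
                                    tm1 = _kin(ix, iy - 1, iz, jx, jy, jz, b, Ex, Ey, Ez)
                                    li = iy
                                else:
                                    sp1 = _ov(ix, iy, iz + 1, jx, jy, jz, Ex, Ey, Ez)
                                    sm1 = _ov(ix, iy, iz - 1, jx, jy, jz, Ex, Ey, Ez)
                                    tp1 = _kin(ix, iy, iz + 1, jx, jy, jz, b, Ex, Ey, Ez)
                                    tm1 = _kin(ix, iy, iz - 1, jx, jy, jz, b, Ex, Ey, Ez)
                                    li = iz
                                dS = pref * (2.0 * a * sp1 - li * sm1)
                                dT = pref * (2.0 * a * tp1 - li * tm1)
                                grad[ata, d] += dmat * dT - wmat * dS
                                grad[atb, d] += -dmat * dT + wmat * dS
                            # nuclear attraction: A-derivative and operator terms
                            for iat in range(natm):
                                C = coords[iat]
                                _fill_R(L + 1, p, Px - C[0], Py - C[1],
                                        Pz - C[2], Rn, F)
                                Z = charges[iat]
                                for d in range(3):
                                    if d == 0:
                                        vp1 = _vattr(ix + 1, iy, iz, jx, jy, jz, Ex, Ey, Ez, Rn, 0, 0, 0)
                                        vm1 = _vattr(ix - 1, iy, iz, jx, jy, jz, Ex, Ey, Ez, Rn, 0, 0, 0)
                                        vop = _vattr(ix, iy, iz, jx, jy, jz, Ex, Ey, Ez, Rn, 1, 0, 0)
                                        li = ix
                                    elif d == 1:
                                        vp1 = _vattr(ix, iy + 1, iz, jx, jy, jz, Ex, Ey, Ez, Rn, 0, 0, 0)
                                        vm1 = _vattr(ix, iy - 1, iz, jx, jy, jz, Ex, Ey, Ez, Rn, 0, 0, 0)
                                        vop = _vattr(ix, iy, iz, jx, jy, jz, Ex, Ey, Ez, Rn, 0, 1, 0)
                                        li = iy
                                    else:
                                        vp1 = _vattr(ix, iy, iz + 1, jx, jy, jz, Ex, Ey, Ez, Rn, 0, 0, 0)
                                        vm1 = _vattr(ix, iy, iz - 1, jx, jy, jz, Ex, Ey, Ez, Rn, 0, 0, 0)
                                        vop = _vattr(ix, iy, iz, jx, jy, jz, Ex, Ey, Ez, Rn, 0, 0, 1)
                                        li = iz
                                    dVA = -Z * vfac * (2.0 * a * vp1 - li * vm1)
                                    dVC = Z * vfac * vop
                                    dvc[iat, d] = dVC
                                    grad[ata, d] += dmat * dVA
                                    grad[atb, d] += -dmat * dVA
                                    grad[iat, d] += dmat * dVC
                                    grad[atb, d] += -dmat * dVC


@njit(cache=True)
def dvnuc_per_atom(nsh, shell_l, shell_atom, shell_pstart, shell_nprim,
                   shell_cstart, prim_exp, prim_coef, coords, charges, out):
    """Full derivative matrices d v_nuc / dR_I into out (natm, 3, nc, nc)."""
    natm = coords.shape[0]
    Ex = np.zeros((_EDIM, _EDIM, 2 * _EDIM))
    Ey = np.zeros((_EDIM, _EDIM, 2 * _EDIM))
    Ez = np.zeros((_EDIM, _EDIM, 2 * _EDIM))
    Rn = np.zeros((_RDIM, _RDIM, _RDIM, _RDIM))
    F = np.zeros(_RDIM)
    for ish in range(nsh):
        la = shell_l[ish]
        ata = shell_atom[ish]
        A = coords[ata]
        nca = _ncart(la)
        for jsh in range(nsh):
            lb = shell_l[jsh]
            atb = shell_atom[jsh]
            B = coords[atb]
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
                    _fill_E(la + 1, lb, a, b, A[0] - B[0], Ex)
                    _fill_E(la + 1, lb, a, b, A[1] - B[1], Ey)
                    _fill_E(la + 1, lb, a, b, A[2] - B[2], Ez)
                    Px = (a * A[0] + b * B[0]) / p
                    Py = (a * A[1] + b * B[1]) / p
                    Pz = (a * A[2] + b * B[2]) / p
                    vfac = cc * 2.0 * np.pi / p
                    L = la + 1 + lb
                    for iat in range(natm):
                        C = coords[iat]
                        _fill_R(L + 1, p, Px - C[0], Py - C[1], Pz - C[2],
                                Rn, F)
                        Z = charges[iat]
                        for ia in range(nca):
                            ix, iy, iz = _comp_of(la, ia)
                            for jb in range(ncb):
                                jx, jy, jz = _comp_of(lb, jb)
                                ii = i0 + ia
                                jj = j0 + jb
                                for d in range(3):
                                    if d == 0:
                                        vp1 = _vattr(ix + 1, iy, iz, jx, jy, jz, Ex, Ey, Ez, Rn, 0, 0, 0)
                                        vm1 = _vattr(ix - 1, iy, iz, jx, jy, jz, Ex, Ey, Ez, Rn, 0, 0, 0)
                                        vop = _vattr(ix, iy, iz, jx, jy, jz, Ex, Ey, Ez, Rn, 1, 0, 0)
                                        li = ix
                                    elif d == 1:
                                        vp1 = _vattr(ix, iy + 1, iz, jx, jy, jz, Ex, Ey, Ez, Rn, 0, 0, 0)
                                        vm1 = _vattr(ix, iy - 1, iz, jx, jy, jz, Ex, Ey, Ez, Rn, 0, 0, 0)
                                        vop = _vattr(ix, iy, iz, jx, jy, jz, Ex, Ey, Ez, Rn, 0, 1, 0)
                                        li = iy
                                    else:
                                        vp1 = _vattr(ix, iy, iz + 1, jx, jy, jz, Ex, Ey, Ez, Rn, 0, 0, 0)
                                        vm1 = _vattr(ix, iy, iz - 1, jx, jy, jz, Ex, Ey, Ez, Rn, 0, 0, 0)
                                        vop = _vattr(ix, iy, iz, jx, jy, jz, Ex, Ey, Ez, Rn, 0, 0, 1)
                                        li = iz
                                    dVA = -Z * vfac * (2.0 * a * vp1 - li * vm1)
                                    dVC = Z * vfac * vop
                                    out[ata, d, ii, jj] += dVA
                                    out[atb, d, ii, jj] += -dVA - dVC
                                    out[iat, d, ii, jj] += dVC


@njit(cache=True)
def _eri_deriv_slot(slot, d, ix, iy, iz, jx, jy, jz, kx, ky, kz, lx, ly, lz,
                    a, b, c, e2, E1x, E1y, E1z, E2x, E2y, E2z, Rn):
    """d(ab|cd)/d(center_slot)_d via raise/lower; slot in {0,1,2} = A,B,C.

    Branch-explicit (no scratch allocation): this sits in the innermost loop
    of the two-electron gradient.
    """
    pos = 3 * slot + d
    if pos == 0:
        up = _md_eri_component(ix + 1, iy, iz, jx, jy, jz, kx, ky, kz,
                               lx, ly, lz, E1x, E1y, E1z, E2x, E2y, E2z, Rn)
        val = 2.0 * a * up
        if ix > 0:
            val -= ix * _md_eri_component(ix - 1, iy, iz, jx, jy, jz,
                                          kx, ky, kz, lx, ly, lz,
                                          E1x, E1y, E1z, E2x, E2y, E2z, Rn)
    elif pos == 1:
        up = _md_eri_component(ix, iy + 1, iz, jx, jy, jz, kx, ky, kz,
                               lx, ly, lz, E1x, E1y, E1z, E2x, E2y, E2z, Rn)
        val = 2.0 * a * up
        if iy > 0:
            val -= iy * _md_eri_component(ix, iy - 1, iz, jx, jy, jz,
                                          kx, ky, kz, lx, ly, lz,
                                          E1x, E1y, E1z, E2x, E2y, E2z, Rn)
    elif pos == 2:
        up = _md_eri_component(ix, iy, iz + 1, jx, jy, jz, kx, ky, kz,
                               lx, ly, lz, E1x, E1y, E1z, E2x, E2y, E2z, Rn)
        val = 2.0 * a * up
        if iz > 0:
            val -= iz * _md_eri_component(ix, iy, iz - 1, jx, jy, jz,
                                          kx, ky, kz, lx, ly, lz,
                                          E1x, E1y, E1z, E2x, E2y, E2z, Rn)
    elif pos == 3:
        up = _md_eri_component(ix, iy, iz, jx + 1, jy, jz, kx, ky, kz,
                               lx, ly, lz, E1x, E1y, E1z, E2x, E2y, E2z, Rn)
        val = 2.0 * b * up
        if jx > 0:
            val -= jx * _md_eri_component(ix, iy, iz, jx - 1, jy, jz,
                                          kx, ky, kz, lx, ly, lz,
                                          E1x, E1y, E1z, E2x, E2y, E2z, Rn)
    elif pos == 4:
        up = _md_eri_component(ix, iy, iz, jx, jy + 1, jz, kx, ky, kz,
                               lx, ly, lz, E1x, E1y, E1z, E2x, E2y, E2z, Rn)
        val = 2.0 * b * up
        if jy > 0:
            val -= jy * _md_eri_component(ix, iy, iz, jx, jy - 1, jz,
                                          kx, ky, kz, lx, ly, lz,
                                          E1x, E1y, E1z, E2x, E2y, E2z, Rn)
    elif pos == 5:
        up = _md_eri_component(ix, iy, iz, jx, jy, jz + 1, kx, ky, kz,
                               lx, ly, lz, E1x, E1y, E1z, E2x, E2y, E2z, Rn)
        val = 2.0 * b * up
        if jz > 0:
            val -= jz * _md_eri_component(ix, iy, iz, jx, jy, jz - 1,
                                          kx, ky, kz, lx, ly, lz,
                                          E1x, E1y, E1z, E2x, E2y, E2z, Rn)
    elif pos == 6:
        up = _md_eri_component(ix, iy, iz, jx, jy, jz, kx + 1, ky, kz,
                               lx, ly, lz, E1x, E1y, E1z, E2x, E2y, E2z, Rn)
        val = 2.0 * c * up
        if kx > 0:
            val -= kx * _md_eri_component(ix, iy, iz, jx, jy, jz,
                                          kx - 1, ky, kz, lx, ly, lz,
                                          E1x, E1y, E1z, E2x, E2y, E2z, Rn)
    elif pos == 7:
        up = _md_eri_component(ix, iy, iz, jx, jy, jz, kx, ky + 1, kz,
                               lx, ly, lz, E1x, E1y, E1z, E2x, E2y, E2z, Rn)
        val = 2.0 * c * up
        if ky > 0:
            val -= ky * _md_eri_component(ix, iy, iz, jx, jy, jz,
                                          kx, ky - 1, kz, lx, ly, lz,
                                          E1x, E1y, E1z, E2x, E2y, E2z, Rn)
    else:
        up = _md_eri_component(ix, iy, iz, jx, jy, jz, kx, ky, kz + 1,
                               lx, ly, lz, E1x, E1y, E1z, E2x, E2y, E2z, Rn)
        val = 2.0 * c * up
        if kz > 0:
            val -= kz * _md_eri_component(ix, iy, iz, jx, jy, jz,
                                          kx, ky, kz - 1, lx, ly, lz,
                                          E1x, E1y, E1z, E2x, E2y, E2z, Rn)
    return val


@njit(cache=True)
def grad_two_electron(nsh, shell_l, shell_atom, shell_pstart, shell_nprim,
                      shell_cstart, prim_exp, prim_coef, coords, G, grad):
    """Accumulate sum_{abcd} G_abcd d(ab|cd)/dR into grad (natm, 3).

    G must carry the full 8-fold permutational symmetry of the integrals
    (pass the symmetrized two-particle density contraction).
    """
    E1x = np.zeros((_EDIM, _EDIM, 2 * _EDIM))
    E1y = np.zeros((_EDIM, _EDIM, 2 * _EDIM))
    E1z = np.zeros((_EDIM, _EDIM, 2 * _EDIM))
    E2x = np.zeros((_EDIM, _EDIM, 2 * _EDIM))
    E2y = np.zeros((_EDIM, _EDIM, 2 * _EDIM))
    E2z = np.zeros((_EDIM, _EDIM, 2 * _EDIM))
    Rn = np.zeros((_RDIM, _RDIM, _RDIM, _RDIM))
    F = np.zeros(_RDIM)
    dblk = np.zeros((4, 3))
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
                lmax_sh = jsh if ksh == ish else ksh
                for lsh in range(lmax_sh + 1):
                    ld = shell_l[lsh]
                    D = coords[shell_atom[lsh]]
                    ncd = _ncart(ld)
                    mult = 1.0
                    if ish != jsh:
                        mult *= 2.0
                    if ksh != lsh:
                        mult *= 2.0
                    ij = ish * (ish + 1) // 2 + jsh
                    kl = ksh * (ksh + 1) // 2 + lsh
                    if ij != kl:
                        mult *= 2.0
                    i0 = shell_cstart[ish]
                    j0 = shell_cstart[jsh]
                    k0 = shell_cstart[ksh]
                    l0 = shell_cstart[lsh]
                    # Schwarz x density screening of the whole quartet block
                    gmax = 0.0
                    for bi in range(nca):
                        for bj in range(ncb):
                            for bk in range(ncc):
                                for bl in range(ncd):
                                    gv = abs(G[i0 + bi, j0 + bj,
                                              k0 + bk, l0 + bl])
                                    if gv > gmax:
                                        gmax = gv
                    if mult * gmax * Q[ish, jsh] * Q[ksh, lsh] < 1e-13:
                        continue
                    for s in range(4):
                        for d in range(3):
                            dblk[s, d] = 0.0
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
                            _fill_E(la + 1, lb + 1, a, b, A[0] - B[0], E1x)
                            _fill_E(la + 1, lb + 1, a, b, A[1] - B[1], E1y)
                            _fill_E(la + 1, lb + 1, a, b, A[2] - B[2], E1z)
                            Px = (a * A[0] + b * B[0]) / p
                            Py = (a * A[1] + b * B[1]) / p
                            Pz = (a * A[2] + b * B[2]) / p
                            for kp in range(shell_nprim[ksh]):
                                c = prim_exp[shell_pstart[ksh] + kp]
                                cgk = prim_coef[shell_pstart[ksh] + kp]
                                for lp in range(shell_nprim[lsh]):
                                    dd = prim_exp[shell_pstart[lsh] + lp]
                                    cgl = prim_coef[shell_pstart[lsh] + lp]
                                    q = c + dd
                                    rcd2 = ((C[0] - D[0]) ** 2
                                            + (C[1] - D[1]) ** 2
                                            + (C[2] - D[2]) ** 2)
                                    kcd = np.exp(-c * dd / q * rcd2)
                                    cfac = ca * cb * cgk * cgl
                                    if abs(cfac) * kab * kcd < 1e-15:
                                        continue
                                    _fill_E(lc + 1, ld + 1, c, dd, C[0] - D[0], E2x)
                                    _fill_E(lc + 1, ld + 1, c, dd, C[1] - D[1], E2y)
                                    _fill_E(lc + 1, ld + 1, c, dd, C[2] - D[2], E2z)
                                    Qx = (c * C[0] + dd * D[0]) / q
                                    Qy = (c * C[1] + dd * D[1]) / q
                                    Qz = (c * C[2] + dd * D[2]) / q
                                    alpha = p * q / (p + q)
                                    L = la + lb + lc + ld + 1
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
                                                    g = G[i0 + bi, j0 + bj,
                                                          k0 + bk, l0 + bl]
                                                    if abs(g) < 1e-14:
                                                        continue
                                                    w = pref * g
                                                    for d in range(3):
                                                        da = _eri_deriv_slot(
                                                            0, d, ix, iy, iz, jx, jy, jz,
                                                            kx, ky, kz, lx, ly, lz,
                                                            a, b, c, dd,
                                                            E1x, E1y, E1z, E2x, E2y, E2z, Rn)
                                                        db = _eri_deriv_slot(
                                                            1, d, ix, iy, iz, jx, jy, jz,
                                                            kx, ky, kz, lx, ly, lz,
                                                            a, b, c, dd,
                                                            E1x, E1y, E1z, E2x, E2y, E2z, Rn)
                                                        dc = _eri_deriv_slot(
                                                            2, d, ix, iy, iz, jx, jy, jz,
                                                            kx, ky, kz, lx, ly, lz,
                                                            a, b, c, dd,
                                                            E1x, E1y, E1z, E2x, E2y, E2z, Rn)
                                                        dblk[0, d] += w * da
                                                        dblk[1, d] += w * db
                                                        dblk[2, d] += w * dc
                                                        dblk[3, d] -= w * (da + db + dc)
                    for d in range(3):
                        grad[shell_atom[ish], d] += mult * dblk[0, d]
                        grad[shell_atom[jsh], d] += mult * dblk[1, d]
                        grad[shell_atom[ksh], d] += mult * dblk[2, d]
                        grad[shell_atom[lsh], d] += mult * dblk[3, d]
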