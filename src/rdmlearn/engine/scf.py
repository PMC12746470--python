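"""Restricted closed-shell self-consistent field solver (DIIS accelerated)."""

from __future__ import annotations

import numpy as np
from scipy.linalg import eigh


def fock_matrix(h, eri, gamma):
    """f = dE/dgamma = h + J[gamma] - K[gamma]/2 (closed-shell convention)."""
    J = np.einsum("ijkl,lk->ij", eri, gamma, optimize=True)
    K = np.einsum("ikjl,lk->ij", eri, gamma, optimize=True)
    return h + J - 0.5 * K


def electronic_energy(h, eri, gamma):
    """E_el[gamma] = Tr[gamma h] + (1/2)Tr[gamma J] - (1/4)Tr[gamma K]."""
    J = np.einsum("ijkl,lk->ij", eri, gamma, optimize=True)
    K = np.einsum("ikjl,lk->ij", eri, gamma, optimize=True)
    return float(np.sum(gamma * (h + 0.5 * J - 0.25 * K)))


def run_rhf(S, h, eri, n_electrons, conv_tol=1e-9, max_cycles=128,
            diis_size=8, level_shift=0.0):
    """Solve RHF equations; returns dict with gamma, mo energies/coeffs, flag.

    gamma is the spin-summed density with Tr[gamma S] = N. The convergence
    test combines the energy change with the DIIS error (orbital gradient).
    """
    nocc = n_electrons // 2
    gamma = np.zeros_like(h)
    e_old = 0.0
    fock_list: list[np.ndarray] = []
    err_list: list[np.ndarray] = []
    converged = False
    mo_e = None
    mo_c = None
    e_el = 0.0
    for cycle in range(max_cycles):
        F = fock_matrix(h, eri, gamma)
        err = F @ gamma @ S - S @ gamma @ F
        fock_list.append(F)
        err_list.append(err)
        if len(fock_list) > diis_size:
            fock_list.pop(0)
            err_list.pop(0)
        F_eff = F
        if len(fock_list) > 1:
            n = len(fock_list)
            B = -np.ones((n + 1, n + 1))
            B[-1, -1] = 0.0
            for i in range(n):
                for j in range(n):
                    B[i, j] = float(np.sum(err_list[i] * err_list[j]))
            rhs = np.zeros(n + 1)
            rhs[-1] = -1.0
            try:
                c = np.linalg.solve(B, rhs)[:n]
                F_eff = sum(ci * Fi for ci, Fi in zip(c, fock_list))
            except np.linalg.LinAlgError:
                pass
        if level_shift > 0.0 and cycle > 0:
            F_eff = F_eff + level_shift * (S - S @ (0.5 * gamma) @ S)
        mo_e, mo_c = eigh(F_eff, S)
        occ = mo_c[:, :nocc]
        gamma = 2.0 * occ @ occ.T
        e_el = electronic_energy(h, eri, gamma)
        de = abs(e_el - e_old)
        if cycle > 0 and de < conv_tol and np.abs(err).max() < 1e-7:
            converged = True
            break
        e_old = e_el
    # canonical orbital energies from the unshifted converged Fock
    F = fock_matrix(h, eri, gamma)
    mo_e, mo_c = eigh(F, S)
    return {
        "gamma": gamma,
        "energy_electronic": e_el,
        "mo_energies": mo_e,
        "mo_coeff": mo_c,
        "converged": converged,
        "n_cycles": cycle + 1,
    }


def energy_weighted_density(mo_e, mo_c, nocc):
    """rho_eps = sum_i eps_i n_i c_i c_i^T with aufbau n_i = 2."""
    occ = mo_c[:, :nocc]
    return 2.0 * occ @ np.diag(mo_e[:nocc]) @ occ.T
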