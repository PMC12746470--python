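"""Molecular integrals over spherical AOs (thin wrappers around the kernels)."""

from __future__ import annotations

import numpy as np

from . import _grad_kernels, _kernels
from .basis import BasisSet


class IntegralFactory:
    """Computes and caches AO integrals for one (geometry, basis) pair."""

    def __init__(self, basis: BasisSet):
        self.basis = basis
        self._C = basis.c2s_matrix()
        self._one = None
        self._eri = None

    def _to_sph(self, m_cart: np.ndarray) -> np.ndarray:
        return self._C @ m_cart @ self._C.T

    def _build_one(self):
        b = self.basis
        nc = b.ncart
        S = np.zeros((nc, nc))
        T = np.zeros((nc, nc))
        V = np.zeros((nc, nc))
        DX = np.zeros((nc, nc))
        DY = np.zeros((nc, nc))
        DZ = np.zeros((nc, nc))
        _kernels.build_one_electron(*b.kernel_args(),
                                    b.atomic_numbers.astype(np.float64),
                                    S, T, V, DX, DY, DZ)
        self._one = tuple(self._to_sph(m) for m in (S, T, V, DX, DY, DZ))

    def overlap(self) -> np.ndarray:
        if self._one is None:
            self._build_one()
        return self._one[0]

    def kinetic(self) -> np.ndarray:
        if self._one is None:
            self._build_one()
        return self._one[1]

    def nuclear_attraction(self) -> np.ndarray:
        if self._one is None:
            self._build_one()
        return self._one[2]

    def dipole(self) -> np.ndarray:
        """Electronic dipole integrals <mu|r|nu> about the origin, (3, n, n)."""
        if self._one is None:
            self._build_one()
        return np.stack(self._one[3:6])

    def core_hamiltonian(self) -> np.ndarray:
        return self.kinetic() + self.nuclear_attraction()

    def eri(self) -> np.ndarray:
        """Dense (ij|kl) tensor in the spherical AO basis."""
        if self._eri is None:
            b = self.basis
            nc = b.ncart
            eri_c = np.zeros((nc, nc, nc, nc))
            _kernels.build_eri(*b.kernel_args(), eri_c)
            C = self._C
            tmp = np.einsum("pi,ijkl->pjkl", C, eri_c, optimize=True)
            tmp = np.einsum("qj,pjkl->pqkl", C, tmp, optimize=True)
            tmp = np.einsum("rk,pqkl->pqrl", C, tmp, optimize=True)
            self._eri = np.einsum("sl,pqrl->pqrs", C, tmp, optimize=True)
        return self._eri

    def nuclear_repulsion(self) -> float:
        b = self.basis
        e = 0.0
        for i in range(len(b.atomic_numbers)):
            for j in range(i):
                r = np.linalg.norm(b.coords[i] - b.coords[j])
                e += b.atomic_numbers[i] * b.atomic_numbers[j] / r
        return e

    def nuclear_repulsion_grad(self) -> np.ndarray:
        b = self.basis
        natm = len(b.atomic_numbers)
        g = np.zeros((natm, 3))
        for i in range(natm):
            for j in range(natm):
                if i == j:
                    continue
                d = b.coords[i] - b.coords[j]
                r = np.linalg.norm(d)
                g[i] -= b.atomic_numbers[i] * b.atomic_numbers[j] * d / r ** 3
        return g

    def point_charge_potential(self, center_bohr, charge) -> np.ndarray:
        """Attraction matrix <mu| -q/|r-c| |nu> for one point charge."""
        b = self.basis
        V = np.zeros((b.ncart, b.ncart))
        _kernels.build_vnuc_single(*b.kernel_args(),
                                   np.asarray(center_bohr, float),
                                   float(charge), V)
        return self._to_sph(V)

    def dvnuc(self) -> np.ndarray:
        """Full d v_nuc / dR_I, shape (natm, 3, nao, nao), Ha/Bohr."""
        b = self.basis
        natm = len(b.atomic_numbers)
        out = np.zeros((natm, 3, b.ncart, b.ncart))
        _grad_kernels.dvnuc_per_atom(*b.kernel_args(),
                                     b.atomic_numbers.astype(np.float64), out)
        C = self._C
        res = np.einsum("pi,adij,qj->adpq", C, out, C, optimize=True)
        # enforce exact symmetry (kernel fills elementwise)
        return 0.5 * (res + res.transpose(0, 1, 3, 2))

    def gradient_contraction(self, D_sph: np.ndarray, W_sph: np.ndarray) -> np.ndarray:
        """Gradient of Tr[D(T+V)] - Tr[W S] + E2[D] + E_nn, (natm, 3), Ha/Bohr.

        E2[D] = 1/2 sum D D (ij|kl) - 1/4 sum D D (ik|jl) (closed-shell
        exchange weight), matching the RHF energy expression with D = gamma.
        """
        b = self.basis
        C = self._C
        Dc = C.T @ D_sph @ C
        Wc = C.T @ W_sph @ C
        natm = len(b.atomic_numbers)
        grad = np.zeros((natm, 3))
        zf = b.atomic_numbers.astype(np.float64)
        _grad_kernels.grad_one_electron(*b.kernel_args(), zf, Dc, Wc, grad)
        # symmetrized two-particle contraction
        G = (0.5 * np.einsum("ab,cd->abcd", Dc, Dc)
             - 0.125 * np.einsum("ac,bd->abcd", Dc, Dc)
             - 0.125 * np.einsum("ad,bc->abcd", Dc, Dc))
        _grad_kernels.grad_two_electron(*b.kernel_args(), G, grad)
        grad += self.nuclear_repulsion_grad()
        return grad
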