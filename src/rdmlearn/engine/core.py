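"""The ab initio engine adapter: every reference quantity the workflow needs.

The adapter exposes a narrow contract (external potential, SCF, Fock builds,
energies, analytic forces, Hessians, derivative integrals) so the learning
stack never touches integral code directly. The backing implementation is a
self-contained restricted Hartree-Fock engine; all quantities are exchanged
in Hartree atomic units internally, with geometry I/O in Angstrom and forces
in Ha/Angstrom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from ..exceptions import ConfigurationError, ConvergenceError, InputError
from ..representation import AOMatrix, Geometry
from . import scf
from .basis import ANGSTROM_PER_BOHR, BasisSet
from .integrals import IntegralFactory

AMU_TO_ME = 1822.888486209
HARTREE_TO_CM1 = 219474.6313632
SUPPORTED_FUNCTIONALS = ("HF", "RHF")


@dataclass(frozen=True)
class MethodSpec:
    """Electronic-structure method specification.

    ``functional`` names the self-consistent mean-field flavor; this engine
    implements restricted Hartree-Fock ("HF"). ``scf_convergence`` is the
    energy threshold in Ha and must be at least as tight as 1e-6.
    """

    functional: str = "HF"
    basis: str = "sto-3g"
    scf_convergence: float = 1e-9
    max_cycles: int = 128
    options: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.functional.upper() not in SUPPORTED_FUNCTIONALS:
            raise ConfigurationError(
                f"functional {self.functional!r} not available; this engine "
                f"supports {SUPPORTED_FUNCTIONALS}")
        if self.scf_convergence > 1e-6:
            raise ConfigurationError(
                "scf_convergence must be <= 1e-6 Ha (tighter than the "
                "surrogate's target accuracy)")

    def label(self) -> str:
        return f"{self.functional.upper()}/{self.basis}"


@dataclass
class SCFResult:
    gamma: AOMatrix
    energy: float
    overlap: AOMatrix
    orbital_energies: np.ndarray
    dipole: np.ndarray
    converged: bool
    forces: np.ndarray | None = None
    mo_coeff: np.ndarray | None = None
    n_cycles: int = 0


@dataclass
class NormalModes:
    """Vibrational normal modes from a mass-weighted Hessian.

    ``frequencies`` are angular frequencies in atomic units; ``modes`` holds
    orthonormal mass-weighted mode vectors as columns (3N x n_vib); masses
    are in electron-mass units.
    """

    frequencies: np.ndarray
    modes: np.ndarray
    masses: np.ndarray
    n_vib: int

    @property
    def frequencies_cm1(self) -> np.ndarray:
        return self.frequencies * HARTREE_TO_CM1

    def cartesian_displacements(self) -> np.ndarray:
        """Mass-unweighted Cartesian displacement vectors (3N x n_vib), Bohr."""
        m3 = np.repeat(self.masses, 3)
        return self.modes / np.sqrt(m3)[:, None]


class SCFEngine:
    """Self-consistent field engine bound to one MethodSpec."""

    def __init__(self, method: MethodSpec):
        self.method = method
        self._cache: dict[str, IntegralFactory] = {}
        self.scf_call_count = 0
        self.fock_call_count = 0

    # -------------------------------------------------------------- plumbing

    def factory(self, g: Geometry) -> IntegralFactory:
        key = g.fingerprint()
        if key not in self._cache:
            if len(self._cache) > 8:
                self._cache.clear()
            basis = BasisSet(g.atomic_numbers,
                             g.positions / ANGSTROM_PER_BOHR,
                             self.method.basis)
            self._cache[key] = IntegralFactory(basis)
        return self._cache[key]

    def n_basis(self, g: Geometry) -> int:
        return self.factory(g).basis.nao

    def _ao_matrix(self, values, role, g: Geometry) -> AOMatrix:
        return AOMatrix(values=0.5 * (values + values.T), role=role,
                        basis_label=self.method.basis,
                        geometry_fingerprint=g.fingerprint())

    def _check_trace(self, gamma: np.ndarray, g: Geometry, tol=0.1):
        S = self.factory(g).overlap()
        tr = float(np.sum(gamma * S))
        if abs(tr - g.n_electrons) > tol:
            raise InputError(
                f"Tr[gamma S] = {tr:.4f} violates electron count "
                f"{g.n_electrons} beyond {tol}")

    # ------------------------------------------------------------ operations

    def external_potential_matrix(self, g: Geometry) -> AOMatrix:
        """Full-Coulomb electron-nuclear potential matrix (all electrons)."""
        return self._ao_matrix(self.factory(g).nuclear_attraction(),
                               "potential", g)

    def overlap_matrix(self, g: Geometry) -> AOMatrix:
        return self._ao_matrix(self.factory(g).overlap(), "overlap", g)

    def run_scf(self, g: Geometry, with_forces: bool = True) -> SCFResult:
        self.scf_call_count += 1
        f = self.factory(g)
        res = scf.run_rhf(f.overlap(), f.core_hamiltonian(), f.eri(),
                          g.n_electrons,
                          conv_tol=self.method.scf_convergence,
                          max_cycles=self.method.max_cycles)
        if not res["converged"]:
            # one retry with a level shift, per homogeneous-label policy the
            # caller decides whether to keep it
            res = scf.run_rhf(f.overlap(), f.core_hamiltonian(), f.eri(),
                              g.n_electrons,
                              conv_tol=self.method.scf_convergence,
                              max_cycles=self.method.max_cycles,
                              level_shift=0.3)
        gamma = res["gamma"]
        energy = res["energy_electronic"] + f.nuclear_repulsion()
        forces = None
        if with_forces and res["converged"]:
            W = scf.energy_weighted_density(res["mo_energies"],
                                            res["mo_coeff"],
                                            g.n_electrons // 2)
            forces = -f.gradient_contraction(gamma, W) / ANGSTROM_PER_BOHR
        dip = self._dipole(gamma, g)
        return SCFResult(gamma=self._ao_matrix(gamma, "density", g),
                         energy=float(energy),
                         overlap=self._ao_matrix(f.overlap(), "overlap", g),
                         orbital_energies=res["mo_energies"],
                         dipole=dip,
                         converged=bool(res["converged"]),
                         forces=forces,
                         mo_coeff=res["mo_coeff"],
                         n_cycles=res["n_cycles"])

    def fock_build(self, gamma: AOMatrix | np.ndarray, g: Geometry) -> AOMatrix:
        """f[gamma] = dE/dgamma at the given (trace-consistent) density."""
        self.fock_call_count += 1
        gv = gamma.values if isinstance(gamma, AOMatrix) else np.asarray(gamma)
        self._check_trace(gv, g)
        f = self.factory(g)
        F = scf.fock_matrix(f.core_hamiltonian(), f.eri(), gv)
        return self._ao_matrix(F, "fock", g)

    def energy_from_dm(self, gamma: AOMatrix | np.ndarray, g: Geometry) -> float:
        """Total energy functional E[gamma] including nuclear repulsion."""
        gv = gamma.values if isinstance(gamma, AOMatrix) else np.asarray(gamma)
        self._check_trace(gv, g)
        f = self.factory(g)
        return float(scf.electronic_energy(f.core_hamiltonian(), f.eri(), gv)
                     + f.nuclear_repulsion())

    def analytic_forces_from_dm(self, gamma, weighted_density,
                                g: Geometry) -> np.ndarray:
        """Hellmann-Feynman + Pulay forces for given (gamma, rho_eps), Ha/A."""
        gv = gamma.values if isinstance(gamma, AOMatrix) else np.asarray(gamma)
        wv = (weighted_density.values if isinstance(weighted_density, AOMatrix)
              else np.asarray(weighted_density))
        if gv.shape != wv.shape:
            raise InputError("gamma and weighted density dimension mismatch")
        f = self.factory(g)
        if gv.shape[0] != f.basis.nao:
            raise InputError("density dimension does not match basis")
        return -f.gradient_contraction(gv, wv) / ANGSTROM_PER_BOHR

    def nuclear_attraction_derivatives(self, g: Geometry) -> np.ndarray:
        """Full d v / dR_I matrices, shape (natm, 3, M, M), Ha/Angstrom."""
        return self.factory(g).dvnuc() / ANGSTROM_PER_BOHR

    def one_electron_property(self, gamma, which: str, g: Geometry):
        gv = gamma.values if isinstance(gamma, AOMatrix) else np.asarray(gamma)
        self._check_trace(gv, g)
        if which == "dipole":
            return self._dipole(gv, g)
        if which == "kinetic":
            return float(np.sum(gv * self.factory(g).kinetic()))
        raise ConfigurationError(f"unknown one-electron property {which!r}")

    def _dipole(self, gamma: np.ndarray, g: Geometry) -> np.ndarray:
        f = self.factory(g)
        el = -np.einsum("dij,ji->d", f.dipole(), gamma)
        nuc = (g.atomic_numbers[:, None]
               * g.positions / ANGSTROM_PER_BOHR).sum(axis=0)
        return el + nuc

    # --------------------------------------------------- geometry machinery

    def potential_energy_and_forces(self, g: Geometry):
        res = self.run_scf(g, with_forces=True)
        if not res.converged:
            raise ConvergenceError("SCF did not converge")
        return res.energy, res.forces

    def relax_geometry(self, g: Geometry, fmax: float = 5e-5,
                       maxiter: int = 200) -> Geometry:
        """Minimize the energy; fmax is the max force component (Ha/A)."""
        shape = g.positions.shape

        def fun(x):
            gg = g.with_positions(x.reshape(shape))
            e, frc = self.potential_energy_and_forces(gg)
            return e, -frc.ravel()

        res = minimize(fun, g.positions.ravel(), jac=True, method="BFGS",
                       options={"gtol": fmax * 0.5, "maxiter": maxiter})
        out = g.with_positions(res.x.reshape(shape))
        _, frc = self.potential_energy_and_forces(out)
        if np.abs(frc).max() > fmax:
            raise ConvergenceError(
                f"relaxation stalled at max|F| = {np.abs(frc).max():.2e} Ha/A")
        return out

    def hessian_normal_modes(self, g: Geometry, step: float = 5e-3,
                             freq_tol_cm1: float = 30.0) -> NormalModes:
        """Normal modes by central finite differences of analytic forces.

        ``g`` must be a relaxed minimum (max|F| <= 1e-4 Ha/A); translations
        and rotations are projected out before diagonalization.
        """
        _, f0 = self.potential_energy_and_forces(g)
        if np.abs(f0).max() > 1e-4:
            raise InputError(
                f"geometry is not relaxed (max|F| = {np.abs(f0).max():.2e})")
        n = g.n_atoms
        hess = np.zeros((3 * n, 3 * n))
        step_ang = step * ANGSTROM_PER_BOHR
        for i in range(3 * n):
            pos_p = g.positions.copy().ravel()
            pos_p[i] += step_ang
            pos_m = g.positions.copy().ravel()
            pos_m[i] -= step_ang
            _, fp = self.potential_energy_and_forces(g.with_positions(pos_p.reshape(-1, 3)))
            _, fm = self.potential_energy_and_forces(g.with_positions(pos_m.reshape(-1, 3)))
            # dE/dx in Ha/Bohr per unit Bohr displacement
            hess[i] = (-(fp - fm).ravel() * ANGSTROM_PER_BOHR) / (2 * step)
        hess = 0.5 * (hess + hess.T)
        masses_me = g.masses * AMU_TO_ME
        m3 = np.repeat(masses_me, 3)
        mw = hess / np.sqrt(np.outer(m3, m3))
        # project out rigid translations and rotations
        proj = _rigid_space(g.positions / ANGSTROM_PER_BOHR, masses_me)
        n_rigid = proj.shape[1]
        P = np.eye(3 * n) - proj @ proj.T
        mw = P @ mw @ P
        w, vec = np.linalg.eigh(mw)
        order = np.argsort(w)
        w = w[order]
        vec = vec[:, order]
        n_vib = 3 * n - n_rigid
        w_vib = w[n_rigid:] if n_vib > 0 else w[:0]
        v_vib = vec[:, n_rigid:]
        neg_tol = (freq_tol_cm1 / HARTREE_TO_CM1) ** 2
        if np.any(w_vib < -neg_tol):
            bad = np.sqrt(-w_vib[w_vib < -neg_tol]) * HARTREE_TO_CM1
            raise InputError(
                f"imaginary frequencies {bad} cm^-1: not a minimum")
        w_vib = np.clip(w_vib, 0.0, None)
        return NormalModes(frequencies=np.sqrt(w_vib), modes=v_vib,
                           masses=masses_me, n_vib=n_vib)


def _rigid_space(coords_bohr: np.ndarray, masses_me: np.ndarray) -> np.ndarray:
    """Orthonormal basis of mass-weighted rigid translations + rotations."""
    n = len(coords_bohr)
    com = (masses_me[:, None] * coords_bohr).sum(axis=0) / masses_me.sum()
    x = coords_bohr - com
    sq = np.sqrt(masses_me)
    vecs = []
    for d in range(3):
        v = np.zeros((n, 3))
        v[:, d] = 1.0
        vecs.append((v * sq[:, None]).ravel())
    for d in range(3):
        axis = np.zeros(3)
        axis[d] = 1.0
        v = np.cross(np.broadcast_to(axis, (n, 3)), x)
        vecs.append((v * sq[:, None]).ravel())
    V = np.stack(vecs, axis=1)
    q, r = np.linalg.qr(V)
    keep = np.abs(np.diag(r)) > 1e-8 * max(1.0, np.abs(np.diag(r)).max())
    return q[:, keep]
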