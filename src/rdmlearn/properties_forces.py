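"""Energies, properties, gaps, and forces from predicted density matrices.

Forces for a machine-learned, non-variational density need a correction on
top of the Hellmann-Feynman + Pulay expression: with f the Fock operator at
the predicted density and f' its projection onto the density's natural
orbitals (f with off-diagonal natural-orbital couplings removed), the
residual coupling df = f - f' contracts with the density derivative,

    F_I = F_I[HF+Pulay](gamma, rho_eps) - Tr[(f - f') d gamma / dR_I],

with rho_eps = f gamma built from the density's canonicalized natural
orbitals. df vanishes when gamma and f commute, i.e. at a converged SCF
density, so the correction disappears in the variational limit. The
orientation of the correction term was fixed against finite-difference
energy derivatives of the full surrogate pipeline (consistency ~1e-6 Ha/A).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh

from .engine import SCFEngine
from .exceptions import ConfigurationError, InputError
from .learning import (ModelStack, natural_occupations, predict_gamma_features,
                       purify, unpack_symmetric)
from .representation import (AOMatrix, FrameTransform, Geometry,
                             align_to_reference, ao_rotation_matrix,
                             pack_symmetric)

HARTREE_TO_EV = 27.211386245988

FORCE_MODES = ("hellmann_feynman", "corrected", "delta_learned")


@dataclass
class ForceContext:
    """Everything the corrected-force expression consumes (one geometry)."""

    gamma: AOMatrix
    fock: AOMatrix
    fock_prime: AOMatrix
    natural_orbitals: np.ndarray
    occupations: np.ndarray
    orbital_energies: np.ndarray
    weighted_density: np.ndarray
    grad_gamma: np.ndarray | None = None   # (natm, 3, M, M), per Angstrom
    grad_v: np.ndarray | None = None       # (natm, 3, M, M), per Angstrom


def homo_lumo_gap(gamma, g: Geometry, engine: SCFEngine,
                  return_ev: bool = True) -> float:
    """Gap from diagonalizing the Fock matrix built at the given density.

    Building f[gamma] and diagonalizing recovers canonical orbitals whose
    eigenvalue spectrum is much better than the input density's accuracy
    (the Harris-functional effect).
    """
    F = engine.fock_build(gamma, g).values
    S = engine.overlap_matrix(g).values
    eps = eigh(F, S, eigvals_only=True)
    nocc = g.n_electrons // 2
    gap = float(eps[nocc] - eps[nocc - 1])
    if gap <= 0:
        import logging

        logging.getLogger(__name__).warning(
            "non-positive HOMO-LUMO gap %.3e Ha (near-degeneracy)", gap)
    return gap * HARTREE_TO_EV if return_ev else gap


def fock_prime(fock, gamma, S) -> AOMatrix:
    """f' = f made co-diagonal with the natural orbitals of gamma.

    The natural orbitals of an aufbau density are degenerate within the
    occupation-2 and occupation-0 blocks, so "diagonal in the natural-orbital
    basis" is read with block-canonicalized orbitals (the unique choice that
    also diagonalizes f inside each block). The removed part, df = f - f',
    is then exactly the occupied-virtual coupling of f, which vanishes when
    [f, gamma] = 0 (converged density).

    Computed in the Loewdin-orthogonal frame: with P the occupied projector
    S^1/2 (gamma/2) S^1/2 and Q = 1 - P,
    df_orth = P f_orth Q + Q f_orth P, back-transformed to the AO metric.
    """
    fv = fock.values if isinstance(fock, AOMatrix) else np.asarray(fock, float)
    gv = gamma.values if isinstance(gamma, AOMatrix) else np.asarray(gamma, float)
    Sv = S.values if isinstance(S, AOMatrix) else np.asarray(S, float)
    if fv.shape != gv.shape or fv.shape != Sv.shape:
        raise InputError("fock/gamma/overlap dimension mismatch")
    s_val, s_vec = eigh(Sv)
    Y = s_vec @ np.diag(np.sqrt(s_val)) @ s_vec.T       # S^1/2
    X = s_vec @ np.diag(1.0 / np.sqrt(s_val)) @ s_vec.T  # S^-1/2
    P = Y @ (0.5 * gv) @ Y
    P = 0.5 * (P + P.T)
    f_orth = X @ fv @ X
    Q = np.eye(len(P)) - P
    df_orth = P @ f_orth @ Q + Q @ f_orth @ P
    df = Y @ df_orth @ Y
    out = fv - df
    return AOMatrix(values=0.5 * (out + out.T), role="fock",
                    basis_label=getattr(fock, "basis_label", ""),
                    geometry_fingerprint=getattr(fock, "geometry_fingerprint", ""))


def canonicalized_natural_orbitals(gamma, S, fock):
    """Natural orbitals of an aufbau density, canonicalized within each
    occupation block so they also diagonalize the Fock operator there.

    Returns (occupations, orbitals C with C^T S C = 1, orbital energies
    eps_i = <phi_i|f|phi_i>); these are exactly the eigenpairs of f' and the
    ingredients of the energy-weighted density rho_eps = f gamma.
    """
    occ, C = natural_occupations(gamma, S)
    nocc = int(round(occ.sum() / 2.0))
    eps = np.empty(len(occ))
    Cout = C.copy()
    for block in (slice(0, nocc), slice(nocc, len(occ))):
        Cb = C[:, block]
        if Cb.shape[1] == 0:
            continue
        fb = Cb.T @ fock @ Cb
        e_b, U = eigh(0.5 * (fb + fb.T))
        Cout[:, block] = Cb @ U
        eps[block] = e_b
    return occ, Cout, eps


def _alignment_jacobian(g: Geometry, ref: Geometry, step: float = 1e-5):
    """d(aligned positions)/d(lab positions), (3N, 3N), by cheap geometric FD."""
    n = g.n_atoms
    J = np.zeros((3 * n, 3 * n))
    for i in range(3 * n):
        for sgn in (1.0, -1.0):
            pos = g.positions.copy().ravel()
            pos[i] += sgn * step
            al, _ = align_to_reference(g.with_positions(pos.reshape(-1, 3)), ref)
            J[:, i] += sgn * al.positions.ravel() / (2 * step)
    return J


def _rotation_derivative(g: Geometry, ref: Geometry, step: float = 1e-5):
    """d(rotation matrix)/d(lab positions), (3N, 3, 3), by geometric FD."""
    n = g.n_atoms
    out = np.zeros((3 * n, 3, 3))
    for i in range(3 * n):
        for sgn in (1.0, -1.0):
            pos = g.positions.copy().ravel()
            pos[i] += sgn * step
            _, t = align_to_reference(g.with_positions(pos.reshape(-1, 3)), ref)
            out[i] += sgn * t.rotation / (2 * step)
    return out


class SurrogatePredictor:
    """End-to-end predictor: lab geometry -> aligned features -> density ->
    energies / properties / forces, with frame transport handled internally."""

    def __init__(self, stack: ModelStack, engine: SCFEngine,
                 force_mode: str = "corrected",
                 grad_mode: str = "fd", fd_step: float = 1e-3):
        if force_mode not in FORCE_MODES:
            raise ConfigurationError(f"unknown force mode {force_mode!r}")
        stack.require()
        if force_mode == "delta_learned" and stack.delta_forces is None:
            raise ConfigurationError("delta_learned forces need a force model")
        self.stack = stack
        self.engine = engine
        self.force_mode = force_mode
        self.grad_mode = grad_mode
        self.fd_step = fd_step
        self.reference = stack.gamma_model.reference

    # ------------------------------------------------------------- plumbing

    def _align(self, g: Geometry):
        return align_to_reference(g, self.reference)

    def _frame(self, g: Geometry, t: FrameTransform) -> FrameTransform:
        f = self.engine.factory(g)
        G = ao_rotation_matrix(f.basis.ao_shell_slices(), t.rotation,
                               f.basis.nao)
        return FrameTransform(rotation=t.rotation, translation=t.translation,
                              ao_rotation=G)

    # ----------------------------------------------------------- prediction

    def predict_aligned(self, aligned: Geometry) -> dict:
        """Predict at an already-aligned geometry; density in aligned frame."""
        v = self.engine.external_potential_matrix(aligned)
        S = self.engine.overlap_matrix(aligned)
        out = {"aligned": aligned, "v": v, "S": S}
        feats = pack_symmetric(v).values
        raw = unpack_symmetric(
            predict_gamma_features(self.stack.gamma_model, feats))
        gamma_p = purify(raw, S.values, aligned.n_electrons)
        out["gamma_raw"] = raw
        if self.stack.flavor == "gamma+delta":
            refined = self.stack.delta_refine.predict(
                pack_symmetric(gamma_p.values).values)
            gamma_p = purify(unpack_symmetric(refined), S.values,
                             aligned.n_electrons)
        out["gamma"] = gamma_p
        return out

    def predict(self, g: Geometry) -> dict:
        """Predict for a lab-frame geometry; adds the lab-frame density."""
        aligned, t = self._align(g)
        out = self.predict_aligned(aligned)
        tf = self._frame(g, t)
        G = tf.ao_rotation
        gl = G @ out["gamma"].values @ G.T
        out["transform"] = tf
        out["gamma_lab"] = AOMatrix(values=0.5 * (gl + gl.T), role="density",
                                    basis_label=self.engine.method.basis,
                                    geometry_fingerprint=g.fingerprint())
        return out

    def gamma_lab(self, g: Geometry) -> AOMatrix:
        return self.predict(g)["gamma_lab"]

    def energy(self, g: Geometry) -> float:
        if self.stack.flavor == "delta_learned":
            aligned, _ = self._align(g)
            out = self.predict_aligned(aligned)
            feats = pack_symmetric(out["gamma"].values).values
            return float(self.stack.delta_energy.predict(feats)[0])
        aligned, _ = self._align(g)
        out = self.predict_aligned(aligned)
        return self.engine.energy_from_dm(out["gamma"], aligned)

    def homo_lumo_gap(self, g: Geometry, return_ev: bool = True) -> float:
        aligned, _ = self._align(g)
        out = self.predict_aligned(aligned)
        return homo_lumo_gap(out["gamma"], aligned, self.engine, return_ev)

    # ------------------------------------------------------- force machinery

    def force_context(self, g: Geometry, with_grad_gamma: bool = False) -> ForceContext:
        """Assemble the corrected-force ingredients in the lab frame."""
        pred = self.predict(g)
        gamma = pred["gamma_lab"]
        S = self.engine.overlap_matrix(g)
        F = self.engine.fock_build(gamma, g)
        occ, C, eps = canonicalized_natural_orbitals(gamma.values, S.values,
                                                     F.values)
        Fp = fock_prime(F, gamma, S)
        # energy-weighted density rho_eps = f gamma: natural orbitals with
        # their f expectations and aufbau occupations
        W = C @ np.diag(eps * occ) @ C.T
        grad_gamma = None
        if with_grad_gamma:
            grad_gamma = self.grad_gamma(g, mode=self.grad_mode)
        return ForceContext(gamma=gamma, fock=F, fock_prime=Fp,
                            natural_orbitals=C, occupations=occ,
                            orbital_energies=eps, weighted_density=W,
                            grad_gamma=grad_gamma,
                            grad_v=None)

    def grad_gamma(self, g: Geometry, mode: str = "fd") -> np.ndarray:
        """d(gamma_lab)/dR_I, shape (natm, 3, M, M), per Angstrom.

        mode "fd": central differences of the complete
        predict-align-purify-transport pipeline (robust default).
        mode "analytic": kernel-gradient chain rule with derivative
        nuclear-attraction integrals, analytic purification perturbation
        theory, and geometric finite differences only for the frame
        transport terms.
        """
        if mode == "fd":
            return self._grad_gamma_fd(g)
        if mode == "analytic":
            return self._grad_gamma_analytic(g)
        raise ConfigurationError(f"unknown grad mode {mode!r}")

    def _grad_gamma_fd(self, g: Geometry) -> np.ndarray:
        n = g.n_atoms
        M = self.engine.n_basis(g)
        out = np.zeros((n, 3, M, M))
        h = self.fd_step
        for i in range(3 * n):
            acc = np.zeros((M, M))
            for sgn in (1.0, -1.0):
                pos = g.positions.copy().ravel()
                pos[i] += sgn * h
                gp = g.with_positions(pos.reshape(-1, 3))
                acc += sgn * self.predict(gp)["gamma_lab"].values
            out[i // 3, i % 3] = acc / (2 * h)
        return out

    def _grad_gamma_analytic(self, g: Geometry) -> np.ndarray:
        model = self.stack.gamma_model
        if model.kernel.kind not in ("RBF", "LIN", "POL"):
            raise ConfigurationError("non-differentiable kernel")
        aligned, t = self._align(g)
        tf = self._frame(g, t)
        G = tf.ao_rotation
        n = g.n_atoms
        M = self.engine.n_basis(g)
        pred = self.predict_aligned(aligned)
        S = pred["S"].values
        x = pack_symmetric(pred["v"]).values

        # kernel gradient: d gamma_raw / d x, assembled lazily per direction
        k = model.kernel
        diffs = x[None, :] - model.X                      # (ntrain, nf)
        if k.kind == "RBF":
            Kq = np.exp(-k.gamma_scale * np.sum(diffs ** 2, axis=1))
        elif k.kind == "LIN":
            Kq = model.X @ x
        else:
            Kq = (k.gamma_scale * (model.X @ x) + k.offset) ** k.degree

        dv_al = self.engine.nuclear_attraction_derivatives(aligned)  # per Ang
        J = _alignment_jacobian(g, self.reference)                   # (3N,3N)
        dR = _rotation_derivative(g, self.reference)                 # (3N,3,3)

        # overlap derivative in the aligned frame by cheap rebuilds
        hS = 1e-4
        dS_al = np.zeros((3 * n, M, M))
        for i in range(3 * n):
            for sgn in (1.0, -1.0):
                pos = aligned.positions.copy().ravel()
                pos[i] += sgn * hS
                f = self.engine.factory(aligned.with_positions(pos.reshape(-1, 3)))
                dS_al[i] += sgn * f.overlap() / (2 * hS)

        # purification linearization pieces at the aligned geometry
        s_val, s_vec = eigh(S)
        sq = np.sqrt(s_val)
        Y = s_vec @ np.diag(sq) @ s_vec.T          # S^1/2
        X_ = s_vec @ np.diag(1.0 / sq) @ s_vec.T   # S^-1/2
        raw = pred["gamma_raw"]
        Mmat = Y @ raw @ Y
        nvals, U = eigh(0.5 * (Mmat + Mmat.T))
        order = np.argsort(nvals)[::-1]
        nvals = nvals[order]
        U = U[:, order]
        nocc = g.n_electrons // 2
        P = U[:, :nocc] @ U[:, :nocc].T
        gamma_al = 2.0 * X_ @ P @ X_

        out = np.zeros((n, 3, M, M))
        iu = np.triu_indices(M)
        diag_mask = iu[0] == iu[1]
        for I in range(n):
            for d in range(3):
                col = 3 * I + d
                # d v_aligned / d x_lab through the alignment map
                dv = np.zeros((M, M))
                dS = np.zeros((M, M))
                for j in range(3 * n):
                    w = J[j, col]
                    if abs(w) > 1e-14:
                        dv += w * dv_al[j // 3, j % 3]
                        dS += w * dS_al[j]
                dx = dv[iu].copy()
                # packed distance uses each off-diagonal once; chain rule of
                # the packing is just the packed derivative
                if k.kind == "RBF":
                    dK = -2.0 * k.gamma_scale * (diffs @ dx) * Kq
                elif k.kind == "LIN":
                    dK = model.X @ dx
                else:
                    base = k.gamma_scale * (model.X @ x) + k.offset
                    dK = (k.degree * base ** (k.degree - 1)
                          * k.gamma_scale * (model.X @ dx))
                draw = unpack_symmetric(dK @ model.B)
                # S^1/2 derivative via Sylvester in the S eigenbasis
                dS_e = s_vec.T @ dS @ s_vec
                dY_e = dS_e / (sq[:, None] + sq[None, :])
                dY = s_vec @ dY_e @ s_vec.T
                dX = -X_ @ dY @ X_
                dM = dY @ raw @ Y + Y @ draw @ Y + Y @ raw @ dY
                # projector perturbation theory (occ-virt coupling only)
                Ut_dM_U = U.T @ dM @ U
                dP_nat = np.zeros_like(P)
                for i_o in range(nocc):
                    for a_v in range(nocc, M):
                        denom = nvals[i_o] - nvals[a_v]
                        if abs(denom) < 1e-12:
                            denom = np.sign(denom) * 1e-12 if denom else 1e-12
                        c = Ut_dM_U[a_v, i_o] / denom
                        dP_nat[a_v, i_o] += c
                        dP_nat[i_o, a_v] += c
                dP = U @ dP_nat @ U.T
                dgamma_al = 2.0 * (dX @ P @ X_ + X_ @ dP @ X_ + X_ @ P @ dX)
                # transport to the lab frame: gamma_lab = G gamma_al G^T
                dG = self._ao_rotation_derivative(g, dR[col])
                term = (dG @ gamma_al @ G.T + G @ dgamma_al @ G.T
                        + G @ gamma_al @ dG.T)
                out[I, d] = 0.5 * (term + term.T)
        return out

    def _ao_rotation_derivative(self, g: Geometry, dRot: np.ndarray,
                                step: float = 1e-6) -> np.ndarray:
        """d(ao_rotation)/d(rotation entries) contracted with dRot, by FD
        along the geodesic direction."""
        aligned, t = self._align(g)
        f = self.engine.factory(g)
        slices = f.basis.ao_shell_slices()
        nao = f.basis.nao
        R = t.rotation
        # project dRot onto the tangent space of SO(3) at R and step along it
        A = dRot @ R.T
        A = 0.5 * (A - A.T)
        from scipy.linalg import expm

        Rp = expm(step * A) @ R
        Rm = expm(-step * A) @ R
        Gp = ao_rotation_matrix(slices, Rp, nao)
        Gm = ao_rotation_matrix(slices, Rm, nao)
        return (Gp - Gm) / (2 * step)

    def compute_forces(self, g: Geometry, mode: str | None = None) -> np.ndarray:
        """Forces (natm, 3) in Ha/Angstrom for the requested mode."""
        mode = mode or self.force_mode
        if mode not in FORCE_MODES:
            raise ConfigurationError(f"unknown force mode {mode!r}")
        if mode == "delta_learned":
            if self.stack.delta_forces is None:
                raise ConfigurationError("no delta force model fitted")
            aligned, t = self._align(g)
            out = self.predict_aligned(aligned)
            feats = pack_symmetric(out["gamma"].values).values
            F_al = self.stack.delta_forces.predict(feats)
            return F_al @ t.rotation            # rows: F_lab = R^T F_aligned
        ctx = self.force_context(g, with_grad_gamma=(mode == "corrected"))
        forces = self.engine.analytic_forces_from_dm(
            ctx.gamma, ctx.weighted_density, g)
        if mode == "corrected":
            forces = forces - correction_term(ctx)
        return forces

    def forces(self, g: Geometry) -> np.ndarray:
        return self.compute_forces(g, self.force_mode)


def correction_term(ctx: ForceContext) -> np.ndarray:
    """Tr[(f - f') d gamma/dR_I] per atom/component (Ha/Angstrom).

    Enters the corrected force with a minus sign (see module docstring).
    """
    if ctx.grad_gamma is None:
        raise InputError("ForceContext lacks grad_gamma")
    df = ctx.fock.values - ctx.fock_prime.values
    return np.einsum("mn,adnm->ad", df, ctx.grad_gamma)
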