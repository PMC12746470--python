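"""Matrix-target kernel ridge regression, aufbau purification, delta models.

The map learned here sends the packed external-potential matrix to the
packed one-particle density matrix,

    gamma[v] = sum_i beta_i K(v_i, v),

with matrix-shaped weights beta_i obtained by solving the regularized
kernel system (K + alpha I) B = Y for all feature columns at once. The
prediction is made N-representable by a single diagonalization with aufbau
occupations (spin-compensated: occupations in {0, 2}, Tr[gamma S] = N).
Delta models are plain affine least-squares maps used for gamma refinement
and for direct energy/force prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve, eigh

from .engine import MethodSpec
from .exceptions import ConfigurationError, InputError
from .representation import (AOMatrix, FeatureVector, Geometry,
                             pack_symmetric, unpack_symmetric)

logger = logging.getLogger(__name__)

KERNEL_KINDS = ("LIN", "RBF", "POL")

MODEL_FLAVORS = ("gamma", "gamma+delta", "delta_learned")


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family and hyperparameters.

    ``gamma_scale`` is the kernel width/scale parameter; ``None`` means the
    default 1/N_features, resolved against the data set at fit time.
    """

    kind: str = "RBF"
    alpha: float = 0.0
    gamma_scale: float | None = None
    degree: int = 3
    offset: float = 0.0

    def __post_init__(self):
        if self.kind not in KERNEL_KINDS:
            raise ConfigurationError(f"unknown kernel kind {self.kind!r}")
        if self.alpha < 0:
            raise ConfigurationError("alpha must be >= 0")
        if self.gamma_scale is not None and self.gamma_scale <= 0:
            raise ConfigurationError("gamma_scale must be > 0")

    def resolve(self, n_features: int) -> "KernelSpec":
        if self.gamma_scale is not None:
            return self
        return replace(self, gamma_scale=1.0 / n_features)


def kernel_eval(x, y, k: KernelSpec) -> float:
    """Scalar kernel K(x, y)."""
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.shape != y.shape:
        raise InputError("feature length mismatch")
    k = k.resolve(len(x))
    if k.kind == "LIN":
        return float(x @ y)
    if k.kind == "RBF":
        d = x - y
        return float(np.exp(-k.gamma_scale * (d @ d)))
    return float((k.gamma_scale * (x @ y) + k.offset) ** k.degree)


def kernel_matrix(X, Y, k: KernelSpec) -> np.ndarray:
    """Entrywise kernel matrix K[i, j] = K(X[i], Y[j])."""
    X = np.atleast_2d(np.asarray(X, float))
    Y = np.atleast_2d(np.asarray(Y, float))
    if X.shape[1] != Y.shape[1]:
        raise InputError("feature length mismatch")
    k = k.resolve(X.shape[1])
    if k.kind == "LIN":
        return X @ Y.T
    if k.kind == "RBF":
        d2 = (np.sum(X ** 2, axis=1)[:, None] + np.sum(Y ** 2, axis=1)[None, :]
              - 2.0 * X @ Y.T)
        return np.exp(-k.gamma_scale * np.clip(d2, 0.0, None))
    return (k.gamma_scale * (X @ Y.T) + k.offset) ** k.degree


@dataclass
class GammaModel:
    """Fitted KRR state for the potential -> density map."""

    kernel: KernelSpec
    X: np.ndarray                 # (n, N_features) training potentials
    B: np.ndarray                 # (n, N_features) matrix-shaped weights, packed
    reference: Geometry
    method: MethodSpec
    jitter_used: float = 0.0

    @property
    def n_train(self) -> int:
        return self.X.shape[0]

    @property
    def basis_dim(self) -> int:
        nf = self.X.shape[1]
        return int(round((np.sqrt(8 * nf + 1) - 1) / 2))


def _solve_regularized(K: np.ndarray, Y: np.ndarray, alpha: float):
    """Solve (K + alpha I) B = Y by symmetric factorization with escalating
    diagonal jitter; indefinite kernels (odd-degree POL) fall back to a
    minimum-norm least-squares solve."""
    n = K.shape[0]
    # jitter scales with the kernel magnitude, which varies over ~15 orders
    # between RBF (unit diagonal) and POL on raw matrix elements
    scale = max(1.0, float(np.mean(np.abs(np.diag(K)))))
    jitters = ((0.0, 1e-12 * scale, 1e-10 * scale, 1e-8 * scale)
               if alpha == 0.0 else (0.0,))
    last_err = None
    for jit in jitters:
        try:
            A = K + (alpha + jit) * np.eye(n)
            c, low = cho_factor(A, lower=True)
            if jit > 0:
                logger.warning("kernel system needed diagonal jitter %g", jit)
            B = cho_solve((c, low), Y)
            # iterative refinement: the alpha = 0 systems favored here are
            # severely ill-conditioned, and a couple of corrections buys
            # several digits of interpolation accuracy
            for _ in range(3):
                resid = Y - A @ B
                if np.abs(resid).max() < 1e-14 * max(np.abs(Y).max(), 1.0):
                    break
                B = B + cho_solve((c, low), resid)
            return B, jit
        except np.linalg.LinAlgError as err:
            last_err = err
    # indefinite kernel matrix (odd-degree POL can be non-PSD): minimum-norm
    # least squares; exact-duplicate inputs were already rejected upstream
    logger.warning("kernel matrix not positive definite; minimum-norm "
                   "least-squares fallback used (%s)", last_err)
    B, *_ = np.linalg.lstsq(K + alpha * np.eye(n), Y, rcond=None)
    return B, float("nan")


def fit_gamma(ts, k: KernelSpec) -> GammaModel:
    """Fit the KRR gamma model on a TrainingSet."""
    X = ts.features_v
    Y = ts.features_gamma
    if X.shape[0] < 1:
        raise InputError("need at least one training sample")
    k = k.resolve(X.shape[1])
    if k.alpha == 0.0 and X.shape[0] > 1:
        order = np.lexsort(X.T)
        if np.any(np.all(X[order][1:] == X[order][:-1], axis=1)):
            raise ConfigurationError(
                "duplicate feature rows with alpha=0; deduplicate or use "
                "alpha > 0 / jitter")
    K = kernel_matrix(X, X, k)
    B, jit = _solve_regularized(K, Y, k.alpha)
    return GammaModel(kernel=k, X=np.ascontiguousarray(X),
                      B=np.ascontiguousarray(B), reference=ts.reference,
                      method=ts.method, jitter_used=jit)


def predict_gamma_features(model: GammaModel, v_features: np.ndarray) -> np.ndarray:
    """Packed raw prediction(s); accepts a single vector or a batch."""
    v = np.atleast_2d(np.asarray(v_features, float))
    if v.shape[1] != model.X.shape[1]:
        raise InputError(
            f"feature length {v.shape[1]} != model {model.X.shape[1]}")
    Kq = kernel_matrix(v, model.X, model.kernel)
    out = Kq @ model.B
    return out[0] if np.asarray(v_features).ndim == 1 else out


def predict_gamma(model: GammaModel, v: FeatureVector | np.ndarray) -> AOMatrix:
    """Raw (un-purified) density prediction as a symmetric AO matrix."""
    feats = v.values if isinstance(v, FeatureVector) else np.asarray(v, float)
    packed = predict_gamma_features(model, feats)
    return AOMatrix(values=unpack_symmetric(packed), role="density",
                    basis_label=model.method.basis)


# --------------------------------------------------------------- purification


def _fix_eigenvector_signs(U: np.ndarray) -> np.ndarray:
    """First significant component of each eigenvector made positive."""
    V = U.copy()
    for j in range(V.shape[1]):
        col = V[:, j]
        nz = np.nonzero(np.abs(col) > 1e-10)[0]
        if len(nz) and col[nz[0]] < 0:
            V[:, j] = -col
    return V


def natural_occupations(raw: np.ndarray, S: np.ndarray):
    """Occupations and orbitals of gamma in the Loewdin-orthogonal basis.

    Returns (occupations descending, orbitals as AO-basis columns C with
    C^T S C = 1 and gamma = C diag(n) C^T).
    """
    s_val, s_vec = eigh(S)
    if s_val.min() <= 1e-10:
        raise InputError("overlap matrix is numerically singular")
    S_half = s_vec @ np.diag(np.sqrt(s_val)) @ s_vec.T
    S_mhalf = s_vec @ np.diag(1.0 / np.sqrt(s_val)) @ s_vec.T
    M = S_half @ raw @ S_half
    n, U = eigh(0.5 * (M + M.T))
    order = np.argsort(n)[::-1]
    n = n[order]
    U = _fix_eigenvector_signs(U[:, order])
    C = S_mhalf @ U
    return n, C


def purify(raw: AOMatrix | np.ndarray, S: AOMatrix | np.ndarray,
           n_electrons: int) -> AOMatrix:
    """Impose aufbau occupations by a single diagonalization.

    The N/2 natural orbitals of largest occupation get occupation 2, all
    others 0; the result satisfies Tr[gamma S] = N and gamma S gamma = 2 gamma
    exactly (up to roundoff).
    """
    rv = raw.values if isinstance(raw, AOMatrix) else np.asarray(raw, float)
    Sv = S.values if isinstance(S, AOMatrix) else np.asarray(S, float)
    if n_electrons % 2 != 0:
        raise InputError("closed-shell purification needs even N")
    nocc = n_electrons // 2
    occ, C = natural_occupations(rv, Sv)
    if nocc < len(occ) and abs(occ[nocc - 1] - occ[nocc]) < 1e-10:
        logger.warning("degenerate occupations at the aufbau boundary; "
                       "deterministic ordering tie-break applied")
    Cocc = C[:, :nocc]
    out = 2.0 * Cocc @ Cocc.T
    label = raw.basis_label if isinstance(raw, AOMatrix) else ""
    fp = raw.geometry_fingerprint if isinstance(raw, AOMatrix) else ""
    return AOMatrix(values=0.5 * (out + out.T), role="density",
                    basis_label=label, geometry_fingerprint=fp)


# --------------------------------------------------------------- delta models


@dataclass
class DeltaModel:
    """Affine least-squares map of packed-gamma features to targets."""

    W: np.ndarray                  # (n_features_in, n_targets)
    b: np.ndarray                  # (n_targets,)
    target_kind: str               # gamma_refine | energy | forces
    target_shape: tuple = ()

    def predict(self, feats: np.ndarray) -> np.ndarray:
        f = np.atleast_2d(np.asarray(feats, float))
        out = f @ self.W + self.b
        if np.asarray(feats).ndim == 1:
            out = out[0]
            if self.target_shape:
                out = out.reshape(self.target_shape)
        return out


def _fit_affine(X: np.ndarray, Y: np.ndarray):
    """Minimum-norm affine least squares; returns (W, b)."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    A = np.hstack([X, np.ones((X.shape[0], 1))])
    sol, res, rank, _ = np.linalg.lstsq(A, Y, rcond=None)
    if rank < min(A.shape):
        logger.info("rank-deficient delta fit (rank %d < %d); minimum-norm "
                    "solution used", rank, min(A.shape))
    return sol[:-1], sol[-1]


def fit_delta_refine(pred_feats: np.ndarray, target_feats: np.ndarray) -> DeltaModel:
    """Affine refinement of predicted gamma features toward the SCF targets."""
    if pred_feats.shape[0] != target_feats.shape[0]:
        raise InputError("row count mismatch")
    W, b = _fit_affine(pred_feats, target_feats)
    return DeltaModel(W=W, b=b, target_kind="gamma_refine")


def fit_delta_properties(gamma_feats: np.ndarray,
                         energies: np.ndarray | None = None,
                         forces: np.ndarray | None = None):
    """One affine model per property block; returns dict of DeltaModels."""
    out = {}
    if energies is not None:
        W, b = _fit_affine(gamma_feats, np.asarray(energies, float)[:, None])
        out["energy"] = DeltaModel(W=W, b=b, target_kind="energy")
    if forces is not None:
        F = np.asarray(forces, float)
        shape = F.shape[1:]
        W, b = _fit_affine(gamma_feats, F.reshape(F.shape[0], -1))
        out["forces"] = DeltaModel(W=W, b=b, target_kind="forces",
                                   target_shape=shape)
    return out


# ----------------------------------------------------------------- the stack


@dataclass
class ModelStack:
    """A gamma model plus optional delta models, tagged with a flavor.

    Flavors: "gamma" (purified KRR density only), "gamma+delta" (adds the
    affine gamma refinement), "delta_learned" (energies/forces from affine
    maps on the purified predicted density).
    """

    gamma_model: GammaModel
    flavor: str = "gamma"
    delta_refine: DeltaModel | None = None
    delta_energy: DeltaModel | None = None
    delta_forces: DeltaModel | None = None

    def __post_init__(self):
        if self.flavor not in MODEL_FLAVORS:
            raise ConfigurationError(f"unknown flavor {self.flavor!r}; "
                                     f"choose from {MODEL_FLAVORS}")

    def require(self):
        if self.flavor == "gamma+delta" and self.delta_refine is None:
            raise ConfigurationError("flavor gamma+delta needs delta_refine")
        if self.flavor == "delta_learned" and self.delta_energy is None:
            raise ConfigurationError("flavor delta_learned needs delta_energy")


def predict_full(stack: ModelStack, v_features, S, n_electrons: int,
                 energy_evaluator=None, force_evaluator=None) -> dict:
    """Run the configured model flavor on one packed potential.

    Always returns the purified density (refined when the flavor says so);
    energies/forces come from the delta models for "delta_learned", else from
    the supplied evaluator callables acting on the purified density.
    """
    stack.require()
    Sv = S.values if isinstance(S, AOMatrix) else np.asarray(S, float)
    feats = (v_features.values if isinstance(v_features, FeatureVector)
             else np.asarray(v_features, float))
    raw_packed = predict_gamma_features(stack.gamma_model, feats)
    raw = unpack_symmetric(raw_packed)
    gamma_p = purify(raw, Sv, n_electrons)
    out = {"gamma_raw": raw, "gamma": gamma_p}
    gamma_for_props = gamma_p
    if stack.flavor == "gamma+delta":
        refined_packed = stack.delta_refine.predict(pack_symmetric(gamma_p.values).values)
        refined = purify(unpack_symmetric(refined_packed), Sv, n_electrons)
        out["gamma_refined"] = refined
        gamma_for_props = refined
    out["gamma_final"] = gamma_for_props
    if stack.flavor == "delta_learned":
        gfeats = pack_symmetric(gamma_p.values).values
        out["energy"] = float(stack.delta_energy.predict(gfeats)[0])
        if stack.delta_forces is not None:
            out["forces"] = stack.delta_forces.predict(gfeats)
    else:
        if energy_evaluator is not None:
            out["energy"] = float(energy_evaluator(gamma_for_props))
        if force_evaluator is not None:
            out["forces"] = force_evaluator(gamma_for_props)
    return out
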