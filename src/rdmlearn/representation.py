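"""Geometries, basis-tagged AO matrices, feature packing, and frame alignment.

The learnable map acts on symmetric matrices expressed in one common
molecular frame; this module supplies the frame machinery (mass-weighted
Kabsch superposition plus the matching block-orthogonal rotation of
solid-harmonic AO shells) and the bijective packing of symmetric matrices
into feature vectors.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace

import numpy as np

from .engine._solid_harmonics import C2S
from .engine.basis import MASSES, SYMBOLS, Z_OF
from .exceptions import AlignmentError, RepresentationError

PACKING_ID = "upper-triangle-row-major"

AOMATRIX_ROLES = frozenset(
    {"potential", "density", "fock", "overlap", "dipole_component", "kinetic"})


@dataclass(frozen=True)
class Geometry:
    """A molecular geometry (positions in Angstrom)."""

    atomic_numbers: np.ndarray
    positions: np.ndarray
    total_charge: int = 0
    multiplicity: int = 1

    def __post_init__(self):
        object.__setattr__(self, "atomic_numbers",
                           np.asarray(self.atomic_numbers, dtype=np.int64))
        object.__setattr__(self, "positions",
                           np.asarray(self.positions, dtype=np.float64).reshape(-1, 3))
        if len(self.atomic_numbers) < 1:
            raise RepresentationError("geometry needs at least one atom")
        if len(self.atomic_numbers) != len(self.positions):
            raise RepresentationError("atomic_numbers/positions length mismatch")
        if self.multiplicity != 1:
            raise RepresentationError("only closed-shell (multiplicity 1) supported")
        if self.n_electrons % 2 != 0:
            raise RepresentationError(
                f"odd electron count {self.n_electrons} is not closed-shell")

    @property
    def n_atoms(self) -> int:
        return len(self.atomic_numbers)

    @property
    def n_electrons(self) -> int:
        return int(self.atomic_numbers.sum()) - self.total_charge

    @property
    def masses(self) -> np.ndarray:
        """Atomic masses in amu."""
        return np.array([MASSES[int(z)] for z in self.atomic_numbers])

    @property
    def symbols(self) -> list[str]:
        return [SYMBOLS[int(z)] for z in self.atomic_numbers]

    def with_positions(self, positions) -> "Geometry":
        return replace(self, positions=np.asarray(positions, float))

    def center_of_mass(self) -> np.ndarray:
        m = self.masses
        return (m[:, None] * self.positions).sum(axis=0) / m.sum()

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(self.atomic_numbers.tobytes())
        h.update(np.round(self.positions, 10).tobytes())
        h.update(f"{self.total_charge}:{self.multiplicity}".encode())
        return h.hexdigest()[:16]


@dataclass(frozen=True)
class AOMatrix:
    """A symmetric matrix over the atomic-orbital basis, tagged by role."""

    values: np.ndarray
    role: str
    basis_label: str = ""
    geometry_fingerprint: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise RepresentationError(f"AOMatrix must be square, got {v.shape}")
        scale = max(np.abs(v).max(), 1.0)
        if np.abs(v - v.T).max() > 1e-10 * scale:
            raise RepresentationError("AOMatrix must be symmetric (rtol 1e-10)")
        if self.role not in AOMATRIX_ROLES:
            raise RepresentationError(f"unknown AOMatrix role {self.role!r}")

    @property
    def dim(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class FeatureVector:
    """Flattened upper triangle of a symmetric AO matrix."""

    values: np.ndarray
    packing: str = PACKING_ID

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, np.float64).ravel())
        n = len(self.values)
        m = (np.sqrt(8 * n + 1) - 1) / 2
        if abs(m - round(m)) > 1e-9:
            raise RepresentationError(
                f"feature length {n} is not M(M+1)/2 for integer M")

    @property
    def matrix_dim(self) -> int:
        return int(round((np.sqrt(8 * len(self.values) + 1) - 1) / 2))


def pack_symmetric(m: AOMatrix | np.ndarray) -> FeatureVector:
    """Pack a symmetric matrix into its upper triangle (row-major)."""
    v = m.values if isinstance(m, AOMatrix) else np.asarray(m, float)
    if v.ndim != 2 or v.shape[0] != v.shape[1]:
        raise RepresentationError(f"expected square matrix, got {v.shape}")
    scale = max(np.abs(v).max(), 1.0)
    if np.abs(v - v.T).max() > 1e-10 * scale:
        raise RepresentationError("matrix is not symmetric")
    iu = np.triu_indices(v.shape[0])
    return FeatureVector(values=v[iu])


def unpack_symmetric(vec: FeatureVector | np.ndarray, dim: int | None = None) -> np.ndarray:
    """Inverse of :func:`pack_symmetric`; returns the symmetric matrix."""
    v = vec.values if isinstance(vec, FeatureVector) else np.asarray(vec, float).ravel()
    n = len(v)
    m = int(round((np.sqrt(8 * n + 1) - 1) / 2))
    if m * (m + 1) // 2 != n:
        raise RepresentationError(f"length {n} is not triangular")
    if dim is not None and dim != m:
        raise RepresentationError(f"length {n} inconsistent with dim {dim}")
    out = np.zeros((m, m))
    out[np.triu_indices(m)] = v
    out = out + out.T - np.diag(np.diag(out))
    return out


# ------------------------------------------------------------------- frames


@dataclass(frozen=True)
class FrameTransform:
    """Rigid motion g -> R (g - t_pre) ... applied as (g + translation) @ rotation.T.

    ``apply`` maps source positions onto the reference frame:
    x_aligned = rotation @ (x + translation). ``ao_rotation`` is the matching
    block-orthogonal matrix over solid-harmonic AO shells (built lazily by
    the callers that know the basis).
    """

    rotation: np.ndarray
    translation: np.ndarray
    ao_rotation: np.ndarray | None = None

    def __post_init__(self):
        R = np.asarray(self.rotation, float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", np.asarray(self.translation, float))
        if np.abs(R @ R.T - np.eye(3)).max() > 1e-10:
            raise RepresentationError("rotation is not orthogonal")
        if abs(np.linalg.det(R) - 1.0) > 1e-10:
            raise RepresentationError("rotation must be proper (det +1)")

    def apply(self, positions: np.ndarray) -> np.ndarray:
        return (np.asarray(positions, float) + self.translation) @ self.rotation.T

    def inverse_apply(self, positions: np.ndarray) -> np.ndarray:
        return np.asarray(positions, float) @ self.rotation - self.translation

    def inverse(self) -> "FrameTransform":
        Rinv = self.rotation.T
        aor = None if self.ao_rotation is None else self.ao_rotation.T
        return FrameTransform(rotation=Rinv,
                              translation=-self.rotation @ self.translation,
                              ao_rotation=aor)

    @staticmethod
    def identity(n_ao: int | None = None) -> "FrameTransform":
        aor = None if n_ao is None else np.eye(n_ao)
        return FrameTransform(np.eye(3), np.zeros(3), aor)


def kabsch_rotation(P: np.ndarray, Q: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Proper rotation R minimizing sum_i w_i |R p_i - q_i|^2 (centered input)."""
    H = (weights[:, None] * P).T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def mass_weighted_rmsd(a: Geometry, b: Geometry) -> float:
    w = a.masses / a.masses.sum()
    d = a.positions - b.positions
    return float(np.sqrt((w[:, None] * d ** 2).sum()))


def align_to_reference(g: Geometry, ref: Geometry) -> tuple[Geometry, FrameTransform]:
    """Mass-weighted Kabsch superposition of ``g`` onto ``ref``.

    Returns the aligned geometry and the FrameTransform that maps lab-frame
    positions to the aligned frame (``ao_rotation`` left unset; use
    :func:`ao_rotation_matrix` with the basis at hand).
    """
    if g.n_atoms != ref.n_atoms or np.any(g.atomic_numbers != ref.atomic_numbers):
        raise AlignmentError("atom count/element ordering mismatch")
    w = g.masses / g.masses.sum()
    gc = (w[:, None] * g.positions).sum(axis=0)
    rc = (w[:, None] * ref.positions).sum(axis=0)
    P = g.positions - gc
    Q = ref.positions - rc
    R = kabsch_rotation(P, Q, w)
    t = FrameTransform(rotation=R, translation=-gc)
    aligned = g.with_positions(t.apply(g.positions) + rc)
    # fold the ref-center shift into the translation so apply() is exact
    t = FrameTransform(rotation=R, translation=R.T @ rc - gc)
    return aligned, t


# ------------------------------------------------- AO rotations (per shell)


def _solid_harmonic_values(l: int, pts: np.ndarray) -> np.ndarray:
    """Evaluate S_lm at points, (npts, 2l+1)."""
    comps = [(lx, ly, l - lx - ly)
             for lx in range(l, -1, -1) for ly in range(l - lx, -1, -1)]
    mono = np.stack([pts[:, 0] ** lx * pts[:, 1] ** ly * pts[:, 2] ** lz
                     for lx, ly, lz in comps], axis=1)
    return mono @ np.asarray(C2S[l]).T


def wigner_real_block(l: int, R: np.ndarray) -> np.ndarray:
    """(2l+1) x (2l+1) matrix D with S_lm(R y) = sum_m' D[m', m] S_lm'(y)."""
    if l == 0:
        return np.ones((1, 1))
    rng = np.random.default_rng(12345 + l)
    pts = rng.normal(size=(8 * (2 * l + 1), 3))
    B = _solid_harmonic_values(l, pts)
    T = _solid_harmonic_values(l, pts @ np.asarray(R, float).T)
    D, *_ = np.linalg.lstsq(B, T, rcond=None)
    resid = np.abs(B @ D - T).max()
    if resid > 1e-9:
        raise RepresentationError(f"AO rotation block l={l} ill-conditioned")
    return D


def ao_rotation_matrix(shell_slices, R: np.ndarray, n_ao: int) -> np.ndarray:
    """Block-orthogonal AO rotation for per-shell (l, start, stop) slices."""
    G = np.zeros((n_ao, n_ao))
    blocks: dict[int, np.ndarray] = {}
    for l, s0, s1 in shell_slices:
        if l not in blocks:
            blocks[l] = wigner_real_block(l, R)
        G[s0:s1, s0:s1] = blocks[l]
    return G


def rotate_ao_matrix(m: AOMatrix, t: FrameTransform) -> AOMatrix:
    """Transform an AO matrix into the rotated frame: ao_rot^T  m  ao_rot."""
    if t.ao_rotation is None:
        raise RepresentationError("FrameTransform lacks an ao_rotation")
    G = t.ao_rotation
    if G.shape[0] != m.dim:
        raise RepresentationError(
            f"ao_rotation dim {G.shape[0]} != matrix dim {m.dim}")
    vals = G.T @ m.values @ G
    return AOMatrix(values=0.5 * (vals + vals.T), role=m.role,
                    basis_label=m.basis_label,
                    geometry_fingerprint=m.geometry_fingerprint)


# ------------------------------------------------------------------ XYZ I/O


def read_xyz(path) -> list[Geometry]:
    """Read (possibly multi-frame) XYZ / extended-XYZ; returns geometries."""
    geoms = []
    with open(path) as f:
        lines = f.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        zs, pos = [], []
        for j in range(n):
            parts = lines[i + 2 + j].split()
            zs.append(Z_OF[parts[0]])
            pos.append([float(x) for x in parts[1:4]])
        geoms.append(Geometry(atomic_numbers=zs, positions=pos))
        i += 2 + n
    return geoms


def _fmt_extxyz_comment(metadata: dict | None, has_forces: bool) -> str:
    props = "species:S:1:pos:R:3" + (":forces:R:3" if has_forces else "")
    fields = [f"Properties={props}"]
    for k, v in (metadata or {}).items():
        fields.append(f"{k}={v}")
    return " ".join(fields)


def write_xyz(path, geometries, metadata=None, forces=None, mode="w"):
    """Write geometries as extended-XYZ; optional per-frame metadata/forces.

    ``metadata`` is a dict or a list of dicts (one per frame); ``forces`` a
    list of (n_atoms, 3) arrays in Ha/Angstrom.
    """
    if isinstance(geometries, Geometry):
        geometries = [geometries]
    if isinstance(metadata, dict) or metadata is None:
        metadata = [metadata] * len(geometries)
    if forces is None:
        forces = [None] * len(geometries)
    with open(path, mode) as f:
        for g, md, frc in zip(geometries, metadata, forces):
            f.write(f"{g.n_atoms}\n")
            f.write(_fmt_extxyz_comment(md, frc is not None) + "\n")
            for k, (sym, p) in enumerate(zip(g.symbols, g.positions)):
                row = f"{sym} {p[0]:.10f} {p[1]:.10f} {p[2]:.10f}"
                if frc is not None:
                    row += f" {frc[k][0]:.10f} {frc[k][1]:.10f} {frc[k][2]:.10f}"
                f.write(row + "\n")
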