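"""Training-set generation by thermal normal-mode sampling, and AIMD test sets.

Each sampled geometry displaces the relaxed structure along its vibrational
modes with independent Gaussian mode coordinates of classical-harmonic
variance k_B T / omega_i^2 (mass-weighted convention, proportionality
constant 1). Modes below a configurable frequency floor are swept uniformly
instead, and an optional explicit torsion rotation covers conformational
minima that harmonic displacements cannot reach.

Record i of a sampled set is drawn from an rng seeded by (seed, i), so
growing a set is bit-identical to having requested the larger size upfront.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.constants import k as _kB_J
from scipy.constants import physical_constants

from .engine import ANGSTROM_PER_BOHR, HARTREE_TO_CM1, MethodSpec, NormalModes, SCFEngine
from .exceptions import ConvergenceError, InputError
from .representation import Geometry, align_to_reference, pack_symmetric

logger = logging.getLogger(__name__)

KB_HARTREE = _kB_J / physical_constants["Hartree energy"][0]  # Ha / K

SAMPLER_VERSION = "1"


@dataclass(frozen=True)
class TorsionSpec:
    """Rigid rotation of ``rotating_atoms`` about the ``axis_atoms`` bond.

    The rotation angle is drawn uniformly from [0, 2 pi); this is how
    conformational minima separated by low barriers enter a training set.
    """

    axis_atoms: tuple[int, int]
    rotating_atoms: tuple[int, ...]


@dataclass(frozen=True)
class SamplerConfig:
    temperature: float = 300.0
    n_samples: int = 1
    seed: int = 0
    mode_frequency_floor_cm1: float = 50.0
    displacement_cap_sigma: float | None = None
    torsion: TorsionSpec | None = None

    def __post_init__(self):
        if self.temperature < 0:
            raise InputError("temperature must be >= 0")
        if self.n_samples < 1:
            raise InputError("n_samples must be >= 1")


def _rotate_about_axis(positions, i, j, rotating, angle):
    p = positions.copy()
    origin = p[i]
    axis = p[j] - p[i]
    axis = axis / np.linalg.norm(axis)
    c, s = np.cos(angle), np.sin(angle)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + s * K + (1 - c) * (K @ K)
    for a in rotating:
        p[a] = origin + R @ (p[a] - origin)
    return p


def _draw_mode_coordinates(rng, modes: NormalModes, cfg: SamplerConfig):
    kT = KB_HARTREE * cfg.temperature
    floor = cfg.mode_frequency_floor_cm1 / HARTREE_TO_CM1
    omega = modes.frequencies
    sigma = np.zeros_like(omega)
    ok = omega >= max(floor, 1e-12)
    sigma[ok] = np.sqrt(kT) / omega[ok]
    q = rng.standard_normal(modes.n_vib) * sigma
    if cfg.displacement_cap_sigma is not None:
        cap = cfg.displacement_cap_sigma * sigma
        q = np.clip(q, -cap, cap)
    # soft/torsional modes: uniform sweep with the variance a floor-frequency
    # mode would have, instead of the diverging 1/omega^2 normal width
    if floor > 0 and np.any(~ok):
        A = np.sqrt(3.0 * kT) / floor
        q[~ok] = rng.uniform(-A, A, size=int((~ok).sum()))
    return q


def sample_normal_mode_geometries(eq: Geometry, modes: NormalModes,
                                  cfg: SamplerConfig,
                                  start_index: int = 0) -> list[Geometry]:
    """Draw ``cfg.n_samples`` thermally displaced geometries around ``eq``.

    ``start_index`` offsets the per-record seed stream (used by growth).
    """
    disp_cart = modes.cartesian_displacements()  # (3N, nvib), Bohr
    out = []
    for i in range(start_index, start_index + cfg.n_samples):
        rng = np.random.default_rng((cfg.seed, i))
        q = _draw_mode_coordinates(rng, modes, cfg)
        d = (disp_cart @ q).reshape(-1, 3) * ANGSTROM_PER_BOHR
        pos = eq.positions + d
        if cfg.torsion is not None:
            angle = rng.uniform(0.0, 2.0 * np.pi)
            pos = _rotate_about_axis(pos, cfg.torsion.axis_atoms[0],
                                     cfg.torsion.axis_atoms[1],
                                     cfg.torsion.rotating_atoms, angle)
        out.append(eq.with_positions(pos))
    return out


# ---------------------------------------------------------------- containers


@dataclass
class TrainingSet:
    """Paired (v, gamma, E, F) records in a common aligned frame."""

    features_v: np.ndarray          # (n, M(M+1)/2)
    features_gamma: np.ndarray      # (n, M(M+1)/2)
    energies: np.ndarray            # (n,), Ha
    positions_lab: np.ndarray       # (n, natm, 3), Angstrom
    positions_aligned: np.ndarray   # (n, natm, 3), Angstrom
    rotations: np.ndarray           # (n, 3, 3) lab -> aligned
    reference: Geometry
    method: MethodSpec
    forces: np.ndarray | None = None  # (n, natm, 3), Ha/A, aligned frame
    provenance: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.features_v.shape[0]

    @property
    def n_features(self) -> int:
        return self.features_v.shape[1]

    @property
    def basis_dim(self) -> int:
        nf = self.n_features
        return int(round((np.sqrt(8 * nf + 1) - 1) / 2))

    def subset(self, indices) -> "TrainingSet":
        idx = np.asarray(indices)
        return TrainingSet(
            features_v=self.features_v[idx],
            features_gamma=self.features_gamma[idx],
            energies=self.energies[idx],
            positions_lab=self.positions_lab[idx],
            positions_aligned=self.positions_aligned[idx],
            rotations=self.rotations[idx],
            reference=self.reference,
            method=self.method,
            forces=None if self.forces is None else self.forces[idx],
            provenance=dict(self.provenance, subset=len(idx)),
        )

    def extend(self, other: "TrainingSet") -> "TrainingSet":
        if other.n_features != self.n_features:
            raise InputError("feature dimension mismatch between sets")
        forces = None
        if self.forces is not None and other.forces is not None:
            forces = np.concatenate([self.forces, other.forces])
        prov = dict(self.provenance)
        prov["n_requested"] = (self.provenance.get("n_requested", self.n_samples)
                               + other.provenance.get("n_requested", other.n_samples))
        return TrainingSet(
            features_v=np.concatenate([self.features_v, other.features_v]),
            features_gamma=np.concatenate([self.features_gamma, other.features_gamma]),
            energies=np.concatenate([self.energies, other.energies]),
            positions_lab=np.concatenate([self.positions_lab, other.positions_lab]),
            positions_aligned=np.concatenate([self.positions_aligned, other.positions_aligned]),
            rotations=np.concatenate([self.rotations, other.rotations]),
            reference=self.reference,
            method=self.method,
            forces=forces,
            provenance=prov,
        )

    # ------------------------------------------------------------------ I/O

    def save(self, path):
        import h5py

        with h5py.File(path, "w") as f:
            for name in ("features_v", "features_gamma", "energies",
                         "positions_lab", "positions_aligned", "rotations"):
                f.create_dataset(name, data=getattr(self, name))
            if self.forces is not None:
                f.create_dataset("forces", data=self.forces)
            f.create_dataset("ref_atomic_numbers", data=self.reference.atomic_numbers)
            f.create_dataset("ref_positions", data=self.reference.positions)
            f.attrs["ref_total_charge"] = self.reference.total_charge
            f.attrs["functional"] = self.method.functional
            f.attrs["basis"] = self.method.basis
            f.attrs["scf_convergence"] = self.method.scf_convergence
            for k, v in self.provenance.items():
                f.attrs[f"prov_{k}"] = v

    @classmethod
    def load(cls, path) -> "TrainingSet":
        import h5py

        with h5py.File(path, "r") as f:
            ref = Geometry(atomic_numbers=f["ref_atomic_numbers"][...],
                           positions=f["ref_positions"][...],
                           total_charge=int(f.attrs["ref_total_charge"]))
            method = MethodSpec(functional=str(f.attrs["functional"]),
                                basis=str(f.attrs["basis"]),
                                scf_convergence=float(f.attrs["scf_convergence"]))
            prov = {k[5:]: (v.item() if hasattr(v, "item") else v)
                    for k, v in f.attrs.items() if k.startswith("prov_")}
            return cls(
                features_v=f["features_v"][...],
                features_gamma=f["features_gamma"][...],
                energies=f["energies"][...],
                positions_lab=f["positions_lab"][...],
                positions_aligned=f["positions_aligned"][...],
                rotations=f["rotations"][...],
                reference=ref,
                method=method,
                forces=f["forces"][...] if "forces" in f else None,
                provenance=prov,
            )


def build_training_set(geometries, ref: Geometry, method: MethodSpec,
                       engine: SCFEngine | None = None,
                       with_forces: bool = False,
                       max_failure_frac: float = 0.05,
                       provenance: dict | None = None) -> TrainingSet:
    """Align, label with SCF, and pack each geometry into a TrainingSet.

    Non-converged SCFs are dropped with a warning; more than
    ``max_failure_frac`` failures aborts with a diagnostic.
    """
    engine = engine or SCFEngine(method)
    Xv, Xg, Es, Fs = [], [], [], []
    plab, palg, rots = [], [], []
    n_failed = 0
    for g in geometries:
        aligned, t = align_to_reference(g, ref)
        res = engine.run_scf(aligned, with_forces=with_forces)
        if not res.converged:
            n_failed += 1
            logger.warning("dropping non-converged SCF record (fp=%s)",
                           aligned.fingerprint())
            continue
        v = engine.external_potential_matrix(aligned)
        Xv.append(pack_symmetric(v).values)
        Xg.append(pack_symmetric(res.gamma).values)
        Es.append(res.energy)
        if with_forces:
            Fs.append(res.forces)
        plab.append(g.positions)
        palg.append(aligned.positions)
        rots.append(t.rotation)
    if n_failed > max_failure_frac * len(geometries):
        raise ConvergenceError(
            f"{n_failed}/{len(geometries)} SCF failures exceeds "
            f"{max_failure_frac:.0%} budget")
    prov = dict(provenance or {})
    prov.setdefault("sampler_version", SAMPLER_VERSION)
    prov.setdefault("n_requested", len(geometries))
    return TrainingSet(
        features_v=np.array(Xv),
        features_gamma=np.array(Xg),
        energies=np.array(Es),
        positions_lab=np.array(plab),
        positions_aligned=np.array(palg),
        rotations=np.array(rots),
        reference=ref,
        method=method,
        forces=np.array(Fs) if with_forces else None,
        provenance=prov,
    )


def sample_and_build(eq: Geometry, modes: NormalModes, cfg: SamplerConfig,
                     method: MethodSpec, engine: SCFEngine | None = None,
                     with_forces: bool = False,
                     reference: Geometry | None = None) -> TrainingSet:
    """Convenience: normal-mode sample around ``eq`` and SCF-label."""
    geoms = sample_normal_mode_geometries(eq, modes, cfg)
    prov = {"T": cfg.temperature, "seed": cfg.seed,
            "sampler_version": SAMPLER_VERSION, "n_requested": cfg.n_samples}
    return build_training_set(geoms, reference or eq, method, engine,
                              with_forces=with_forces, provenance=prov)


def grow_training_set(existing: TrainingSet, increment: int, eq: Geometry,
                      modes: NormalModes, cfg: SamplerConfig,
                      engine: SCFEngine | None = None,
                      with_forces: bool = False) -> TrainingSet:
    """Append freshly sampled records; deterministic under the seed schedule."""
    if increment == 0:
        return existing
    start = int(existing.provenance.get("n_requested", existing.n_samples))
    geoms = sample_normal_mode_geometries(
        eq, modes, replace(cfg, n_samples=increment), start_index=start)
    prov = {"T": cfg.temperature, "seed": cfg.seed,
            "sampler_version": SAMPLER_VERSION, "n_requested": increment}
    new = build_training_set(geoms, existing.reference, existing.method,
                             engine, with_forces=with_forces, provenance=prov)
    return existing.extend(new)


def generate_test_set_aimd(eq: Geometry, method: MethodSpec, temperature: float,
                           seed: int, engine: SCFEngine | None = None,
                           duration_fs: float = 2000.0,
                           sample_window_fs: float = 1000.0,
                           n_frames: int = 100,
                           dt_fs: float = 0.5) -> list[Geometry]:
    """Reference AIMD test-set protocol: NVE velocity Verlet, frames from the
    trailing window at equally spaced intervals. Defaults follow the standard
    protocol (2 ps at 0.5 fs, 100 frames from the last 1 ps); every knob is
    overridable for scaled-down runs."""
    from .dynamics import EngineForceProvider, maxwell_boltzmann_velocities, run_nve

    engine = engine or SCFEngine(method)
    vel = maxwell_boltzmann_velocities(eq, temperature, seed)
    n_steps = int(round(duration_fs / dt_fs))
    traj = run_nve(eq, vel, EngineForceProvider(engine), dt_fs, n_steps)
    times = np.array([s.time for s in traj.states])
    t0 = duration_fs - sample_window_fs
    pick = np.linspace(t0, duration_fs, n_frames, endpoint=False) + sample_window_fs / n_frames
    frames = []
    for t in pick:
        k = int(np.argmin(np.abs(times - t)))
        frames.append(eq.with_positions(traj.states[k].positions))
    return frames
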