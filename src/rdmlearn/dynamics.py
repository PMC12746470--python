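"""NVE velocity-Verlet dynamics with pluggable force providers, plus the
stability / trajectory-decoherence diagnostics used to compare surrogate and
reference dynamics launched from identical initial conditions.

Units at this layer: positions Angstrom, velocities Angstrom/fs, masses amu,
energies Ha, forces Ha/Angstrom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.constants import angstrom, atomic_mass, femto, k as _kB
from scipy.constants import physical_constants

from .exceptions import InputError
from .representation import Geometry, kabsch_rotation

_EH = physical_constants["Hartree energy"][0]

# acceleration: (Ha/Angstrom) / amu -> Angstrom/fs^2
ACC_CONV = _EH / (angstrom * atomic_mass) * femto ** 2 / angstrom
# kinetic energy: amu (Angstrom/fs)^2 -> Ha
KE_CONV = atomic_mass * (angstrom / femto) ** 2 / _EH
# Maxwell-Boltzmann sigma^2(v) = KB_VEL * T / m, in (Angstrom/fs)^2 per (K/amu)
KB_VEL = _kB / atomic_mass * (femto / angstrom) ** 2


@dataclass
class MDState:
    positions: np.ndarray      # (n, 3) Angstrom
    velocities: np.ndarray     # (n, 3) Angstrom/fs
    masses: np.ndarray         # (n,) amu
    time: float                # fs
    potential_energy: float    # Ha
    kinetic_energy: float      # Ha
    forces: np.ndarray | None = None  # (n, 3) Ha/Angstrom

    def __post_init__(self):
        for arr in (self.positions, self.velocities):
            if not np.all(np.isfinite(arr)):
                raise InputError("non-finite entries in MD state")

    @property
    def total_energy(self) -> float:
        return self.potential_energy + self.kinetic_energy


@dataclass
class Trajectory:
    states: list
    provider_tag: str = ""
    config: dict = field(default_factory=dict)
    diagnostic: str | None = None

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.states])

    @property
    def total_energies(self) -> np.ndarray:
        return np.array([s.total_energy for s in self.states])

    @property
    def n_frames(self) -> int:
        return len(self.states)


class EngineForceProvider:
    """Reference ab initio forces."""

    tag = "engine"

    def __init__(self, engine):
        self.engine = engine

    def __call__(self, g: Geometry):
        return self.engine.potential_energy_and_forces(g)


class MLForceProvider:
    """Surrogate forces from a SurrogatePredictor (any force mode)."""

    def __init__(self, predictor, mode: str | None = None):
        self.predictor = predictor
        self.mode = mode or predictor.force_mode
        self.tag = f"ml:{self.mode}"

    def __call__(self, g: Geometry):
        e = self.predictor.energy(g)
        f = self.predictor.compute_forces(g, self.mode)
        return e, f


def kinetic_energy(velocities, masses) -> float:
    return float(0.5 * KE_CONV * np.sum(masses[:, None] * velocities ** 2))


def maxwell_boltzmann_velocities(g: Geometry, temperature: float,
                                 seed: int) -> np.ndarray:
    """Per-component normal draws at variance k_B T/m, net momentum removed."""
    if temperature < 0:
        raise InputError("temperature must be >= 0")
    m = g.masses
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(KB_VEL * temperature / m)
    v = rng.standard_normal((g.n_atoms, 3)) * sigma[:, None]
    p = (m[:, None] * v).sum(axis=0)
    v -= p / m.sum()
    return v


def velocity_verlet_step(state: MDState, force_provider, dt: float,
                         geometry_template: Geometry) -> MDState:
    """One standard two-half-kick velocity-Verlet update (dt in fs)."""
    if dt <= 0:
        raise InputError("dt must be positive")
    m = state.masses
    if state.forces is None:
        _, f0 = force_provider(geometry_template.with_positions(state.positions))
    else:
        f0 = state.forces
    a0 = ACC_CONV * f0 / m[:, None]
    v_half = state.velocities + 0.5 * dt * a0
    x_new = state.positions + dt * v_half
    g_new = geometry_template.with_positions(x_new)
    e_pot, f1 = force_provider(g_new)
    a1 = ACC_CONV * f1 / m[:, None]
    v_new = v_half + 0.5 * dt * a1
    return MDState(positions=x_new, velocities=v_new, masses=m,
                   time=state.time + dt, potential_energy=e_pot,
                   kinetic_energy=kinetic_energy(v_new, m), forces=f1)


def run_nve(g: Geometry, velocities: np.ndarray, provider, dt: float,
            n_steps: int) -> Trajectory:
    """Propagate NVE dynamics; returns the full time-ordered trajectory.

    Provider failures truncate the trajectory and record a diagnostic
    instead of raising, so partial runs remain inspectable.
    """
    masses = g.masses
    e0, f0 = provider(g)
    state = MDState(positions=g.positions.copy(),
                    velocities=np.asarray(velocities, float).copy(),
                    masses=masses, time=0.0, potential_energy=e0,
                    kinetic_energy=kinetic_energy(velocities, masses),
                    forces=f0)
    states = [state]
    diagnostic = None
    for step in range(n_steps):
        try:
            state = velocity_verlet_step(state, provider, dt, g)
        except Exception as err:  # noqa: BLE001 - deliberate containment
            diagnostic = f"provider failed at frame {step + 1}: {err}"
            break
        states.append(state)
    tag = getattr(provider, "tag", provider.__class__.__name__)
    return Trajectory(states=states, provider_tag=tag,
                      config={"dt": dt, "n_steps": n_steps},
                      diagnostic=diagnostic)


def decoherence_rmsd(a: Trajectory, b: Trajectory) -> np.ndarray:
    """Per-frame RMSD (Angstrom) after optimal rigid superposition."""
    if a.n_frames != b.n_frames:
        raise InputError("trajectory length mismatch")
    if not np.allclose(a.times, b.times):
        raise InputError("trajectory time grids differ")
    out = np.zeros(a.n_frames)
    for k, (sa, sb) in enumerate(zip(a.states, b.states)):
        P = sa.positions - sa.positions.mean(axis=0)
        Q = sb.positions - sb.positions.mean(axis=0)
        w = np.ones(len(P))
        R = kabsch_rotation(P, Q, w)
        out[k] = np.sqrt(np.mean(np.sum((P @ R.T - Q) ** 2, axis=1)))
    return out


def energy_drift(t: Trajectory) -> dict:
    """Least-squares slope of E_tot vs time (Ha/ps) and max |deviation| (Ha)."""
    if t.n_frames < 2:
        raise InputError("need at least two frames")
    times_ps = t.times / 1000.0
    e = t.total_energies
    A = np.stack([times_ps, np.ones_like(times_ps)], axis=1)
    (slope, _), *_ = np.linalg.lstsq(A, e, rcond=None)
    return {"slope": float(slope), "max_deviation": float(np.abs(e - e[0]).max())}


def first_passage_time(rmsd: np.ndarray, times: np.ndarray,
                       threshold: float) -> float:
    """First time the RMSD series exceeds threshold; inf if never."""
    above = np.nonzero(rmsd > threshold)[0]
    return float(times[above[0]]) if len(above) else float("inf")
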