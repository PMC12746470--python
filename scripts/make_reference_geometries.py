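"""Regenerate the shipped relaxed equilibrium geometries.

Relaxes standard starting structures with the package's own engine and
writes them to src/rdmlearn/data/geometries/. Run from the repository root:

    python scripts/make_reference_geometries.py [molecule ...]
"""

import sys
import time
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from rdmlearn.engine import MethodSpec, SCFEngine  # noqa: E402
from rdmlearn.representation import Geometry, write_xyz  # noqa: E402

OUT = Path(__file__).resolve().parents[1] / "src/rdmlearn/data/geometries"


def starting_structures() -> dict:
    rcc, rch = 1.394, 1.087
    ring, zs = [], []
    for i in range(6):
        a = np.pi / 3 * i
        ring.append([rcc * np.cos(a), rcc * np.sin(a), 0.0])
        zs.append(6)
    for i in range(6):
        a = np.pi / 3 * i
        ring.append([(rcc + rch) * np.cos(a), (rcc + rch) * np.sin(a), 0.0])
        zs.append(1)
    return {
        "h2o": ([8, 1, 1],
                [[0.0, 0.0, 0.1173], [0.0, 0.7572, -0.4692],
                 [0.0, -0.7572, -0.4692]]),
        "nh3": ([7, 1, 1, 1],
                [[0.0, 0.0, 0.112], [0.0, 0.938, -0.262],
                 [0.813, -0.469, -0.262], [-0.813, -0.469, -0.262]]),
        "co2": ([6, 8, 8],
                [[0.0, 0.0, 0.0], [0.0, 0.0, 1.162], [0.0, 0.0, -1.162]]),
        "ch3oh": ([6, 8, 1, 1, 1, 1],
                  [[-0.0503, 0.6685, 0.0], [-0.0503, -0.7585, 0.0],
                   [-1.0807, 1.0417, 0.0], [0.4650, 1.0417, 0.8924],
                   [0.4650, 1.0417, -0.8924], [0.8544, -1.0677, 0.0]]),
        "c6h6": (zs, ring),
    }


def main(selected=None, bases=("sto-3g",)):
    structures = starting_structures()
    names = selected or list(structures)
    for name in names:
        z, pos = structures[name]
        for basis in bases:
            t0 = time.time()
            engine = SCFEngine(MethodSpec(functional="HF", basis=basis))
            eq = engine.relax_geometry(Geometry(z, pos), fmax=5e-5)
            e, f = engine.potential_energy_and_forces(eq)
            out = OUT / f"{name}_hf_{basis}.xyz"
            write_xyz(out, eq, metadata={
                "energy": f"{e:.10f}",
                "method": f"HF/{basis}",
                "max_force_Ha_per_A": f"{np.abs(f).max():.2e}"})
            print(f"{name} HF/{basis}: E={e:.8f} max|F|={np.abs(f).max():.2e} "
                  f"({time.time() - t0:.0f}s) -> {out.name}")


if __name__ == "__main__":
    args = sys.argv[1:]
    main(args or None)
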