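"""Regenerate the shipped normal-mode data.

Computes harmonic normal modes at the shipped relaxed geometries with the
package engine (finite differences of analytic gradients) and stores them as
JSON under src/rdmlearn/data/modes/. Run from the repository root:

    python scripts/make_reference_modes.py [molecule ...]

The benzene Hessian takes ~25 minutes on one CPU; consumers that prefer a
fresh computation can always call SCFEngine.hessian_normal_modes directly.
"""

import json
import sys
import time
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from rdmlearn.data import reference_geometry  # noqa: E402
from rdmlearn.engine import MethodSpec, SCFEngine  # noqa: E402

OUT = Path(__file__).resolve().parents[1] / "src/rdmlearn/data/modes"

DEFAULT = ["h2o", "ch3oh", "c6h6"]


def main(names, basis="sto-3g"):
    OUT.mkdir(parents=True, exist_ok=True)
    for name in names:
        t0 = time.time()
        engine = SCFEngine(MethodSpec(functional="HF", basis=basis))
        eq = reference_geometry(name, "hf", basis)
        modes = engine.hessian_normal_modes(eq)
        payload = {
            "molecule": name,
            "method": f"HF/{basis}",
            "n_vib": int(modes.n_vib),
            "frequencies_au": modes.frequencies.tolist(),
            "modes": modes.modes.tolist(),
            "masses_me": modes.masses.tolist(),
            "geometry_fingerprint": eq.fingerprint(),
        }
        out = OUT / f"{name}_hf_{basis}.json"
        with open(out, "w") as f:
            json.dump(payload, f)
        print(f"{name}: n_vib={modes.n_vib} "
              f"({time.time() - t0:.0f}s) -> {out.name}", flush=True)


if __name__ == "__main__":
    main(sys.argv[1:] or DEFAULT)
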