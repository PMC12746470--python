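"""Shipped reference data: relaxed equilibrium geometries.

The XYZ files under ``geometries/`` are equilibrium structures relaxed with
this package's own engine (see ``scripts/make_reference_geometries.py`` for
regeneration); file names encode molecule, functional and basis. They are
convenience inputs — consumers that need a strict minimum should still
verify forces (``hessian_normal_modes`` does so automatically).
"""

from importlib import resources

from ..representation import Geometry, read_xyz


def reference_geometry(molecule: str, functional: str = "hf",
                       basis: str = "sto-3g") -> Geometry:
    """Load a shipped relaxed geometry, e.g. ('c6h6', 'hf', 'sto-3g')."""
    name = f"{molecule.lower()}_{functional.lower()}_{basis.lower()}.xyz"
    path = resources.files("rdmlearn.data").joinpath(f"geometries/{name}")
    with resources.as_file(path) as p:
        return read_xyz(p)[0]


def reference_modes(molecule: str, functional: str = "hf",
                    basis: str = "sto-3g"):
    """Load shipped normal-mode data (see scripts/make_reference_modes.py).

    The stored fingerprint ties the modes to the shipped relaxed geometry;
    loading fails loudly if the two fall out of sync.
    """
    import json

    import numpy as np

    from ..engine import NormalModes

    name = f"{molecule.lower()}_{functional.lower()}_{basis.lower()}.json"
    path = resources.files("rdmlearn.data").joinpath(f"modes/{name}")
    with resources.as_file(path) as p:
        with open(p) as f:
            payload = json.load(f)
    eq = reference_geometry(molecule, functional, basis)
    if payload["geometry_fingerprint"] != eq.fingerprint():
        raise RuntimeError(
            f"stored modes for {molecule} do not match the shipped geometry; "
            "regenerate with scripts/make_reference_modes.py")
    return NormalModes(frequencies=np.array(payload["frequencies_au"]),
                       modes=np.array(payload["modes"]),
                       masses=np.array(payload["masses_me"]),
                       n_vib=int(payload["n_vib"]))


def available_geometries() -> list[str]:
    root = resources.files("rdmlearn.data").joinpath("geometries")
    return sorted(p.name for p in root.iterdir() if p.name.endswith(".xyz"))
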