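"""Model archives and run configuration.

Archives are single HDF5 containers holding every array of a fitted model
stack plus kernel/method/reference metadata and a format version; loading
reconstructs the stack bit-exactly. Nothing here ships with the repo —
archives are runtime artifacts.
"""

from __future__ import annotations

import hashlib
import json

import numpy as np

from .engine import MethodSpec
from .exceptions import ConfigurationError, InputError
from .learning import DeltaModel, GammaModel, KernelSpec, ModelStack
from .representation import Geometry

FORMAT_VERSION = 1


def _write_geometry(grp, g: Geometry):
    grp.create_dataset("atomic_numbers", data=g.atomic_numbers)
    grp.create_dataset("positions", data=g.positions)
    grp.attrs["total_charge"] = g.total_charge
    grp.attrs["multiplicity"] = g.multiplicity


def _read_geometry(grp) -> Geometry:
    return Geometry(atomic_numbers=grp["atomic_numbers"][...],
                    positions=grp["positions"][...],
                    total_charge=int(grp.attrs["total_charge"]),
                    multiplicity=int(grp.attrs["multiplicity"]))


def _write_delta(f, name: str, dm: DeltaModel | None):
    if dm is None:
        return
    grp = f.create_group(name)
    grp.create_dataset("W", data=dm.W)
    grp.create_dataset("b", data=dm.b)
    grp.attrs["target_kind"] = dm.target_kind
    grp.attrs["target_shape"] = json.dumps(list(dm.target_shape))


def _read_delta(f, name: str) -> DeltaModel | None:
    if name not in f:
        return None
    grp = f[name]
    return DeltaModel(W=grp["W"][...], b=grp["b"][...],
                      target_kind=str(grp.attrs["target_kind"]),
                      target_shape=tuple(json.loads(grp.attrs["target_shape"])))


def save_model(stack: ModelStack, path):
    import h5py

    gm = stack.gamma_model
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["flavor"] = stack.flavor
        f.create_dataset("X", data=gm.X)
        f.create_dataset("B", data=gm.B)
        k = gm.kernel
        f.attrs["kernel_kind"] = k.kind
        f.attrs["kernel_alpha"] = k.alpha
        f.attrs["kernel_gamma_scale"] = (np.nan if k.gamma_scale is None
                                         else k.gamma_scale)
        f.attrs["kernel_degree"] = k.degree
        f.attrs["kernel_offset"] = k.offset
        f.attrs["jitter_used"] = gm.jitter_used
        f.attrs["functional"] = gm.method.functional
        f.attrs["basis"] = gm.method.basis
        f.attrs["scf_convergence"] = gm.method.scf_convergence
        _write_geometry(f.create_group("reference"), gm.reference)
        _write_delta(f, "delta_refine", stack.delta_refine)
        _write_delta(f, "delta_energy", stack.delta_energy)
        _write_delta(f, "delta_forces", stack.delta_forces)


def load_model(path) -> ModelStack:
    import h5py

    with h5py.File(path, "r") as f:
        version = int(f.attrs["format_version"])
        if version != FORMAT_VERSION:
            raise ConfigurationError(
                f"model archive format {version} != supported {FORMAT_VERSION}")
        gs = float(f.attrs["kernel_gamma_scale"])
        kernel = KernelSpec(kind=str(f.attrs["kernel_kind"]),
                            alpha=float(f.attrs["kernel_alpha"]),
                            gamma_scale=None if np.isnan(gs) else gs,
                            degree=int(f.attrs["kernel_degree"]),
                            offset=float(f.attrs["kernel_offset"]))
        method = MethodSpec(functional=str(f.attrs["functional"]),
                            basis=str(f.attrs["basis"]),
                            scf_convergence=float(f.attrs["scf_convergence"]))
        gm = GammaModel(kernel=kernel, X=f["X"][...], B=f["B"][...],
                        reference=_read_geometry(f["reference"]),
                        method=method,
                        jitter_used=float(f.attrs["jitter_used"]))
        stack = ModelStack(gamma_model=gm, flavor=str(f.attrs["flavor"]),
                           delta_refine=_read_delta(f, "delta_refine"),
                           delta_energy=_read_delta(f, "delta_energy"),
                           delta_forces=_read_delta(f, "delta_forces"))
    return stack


def check_model_compatibility(stack: ModelStack, method: MethodSpec,
                              geometry: Geometry):
    """Refuse predictions with mismatched basis/geometry metadata."""
    gm = stack.gamma_model
    if gm.method.basis.lower() != method.basis.lower():
        raise InputError(
            f"model was fitted in basis {gm.method.basis!r}, requested "
            f"{method.basis!r}")
    ref = gm.reference
    if (geometry.n_atoms != ref.n_atoms
            or np.any(geometry.atomic_numbers != ref.atomic_numbers)):
        raise InputError("geometry atoms do not match the model's reference")


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]
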