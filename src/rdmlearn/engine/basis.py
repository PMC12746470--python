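"""Gaussian basis sets over real solid-harmonic shells.

Basis parameters ship as JSON (`data/basis_sets.json`). Shells are packed
into flat arrays consumed by the numba integral kernels; matrices are built
in raw Cartesian components and transformed to normalized real
solid harmonics by the block matrix returned from :meth:`BasisSet.c2s_matrix`.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

import numpy as np

from ._solid_harmonics import C2S

ANGSTROM_PER_BOHR = 0.529177210903

SYMBOLS = ["X", "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne"]
Z_OF = {s: z for z, s in enumerate(SYMBOLS)}

# standard atomic weights (amu)
MASSES = {1: 1.008, 2: 4.002602, 6: 12.011, 7: 14.007, 8: 15.999}


@lru_cache(maxsize=1)
def _basis_library() -> dict:
    with resources.files("rdmlearn.engine").joinpath("data/basis_sets.json").open() as f:
        return json.load(f)


def available_basis_sets() -> list[str]:
    return sorted(_basis_library().keys())


def _prim_norm(a: float, l: int) -> float:
    """Normalization of a solid-harmonic Gaussian primitive."""
    # self-overlap of S_lm * exp(-a r^2): (4 pi/(2l+1)) * J_l(2a)
    dfact = 1.0
    for k in range(2 * l + 1, 0, -2):
        dfact *= k
    p = 2.0 * a
    J = dfact * np.sqrt(np.pi / p) / (2.0 * (2.0 * p) ** (l + 1))
    self_ov = 4.0 * np.pi / (2 * l + 1) * J
    return 1.0 / np.sqrt(self_ov)


class BasisSet:
    """Packed shell representation of a molecular basis.

    Parameters
    ----------
    atomic_numbers : sequence of int
    positions_bohr : (natm, 3) array, Bohr
    name : basis-set label resolvable in the shipped library
    table : optional explicit basis table {element: [[l, [[exp, coef], ...]]]}
        overriding the library lookup (used for custom/toy bases)
    """

    def __init__(self, atomic_numbers, positions_bohr, name: str,
                 table: dict | None = None):
        if table is None:
            lib = _basis_library()
            key = name.lower()
            if key not in lib:
                raise KeyError(
                    f"basis {name!r} not available; choose from {available_basis_sets()}")
            table = lib[key]
        else:
            key = name.lower()
        self.name = key
        self.atomic_numbers = np.asarray(atomic_numbers, dtype=np.int64)
        self.coords = np.ascontiguousarray(positions_bohr, dtype=np.float64)

        shell_l, shell_atom, pstart, nprim = [], [], [], []
        exps, coefs = [], []
        for iat, z in enumerate(self.atomic_numbers):
            sym = SYMBOLS[z]
            if sym not in table:
                raise KeyError(f"element {sym} missing from basis {name!r}")
            for l, prims in table[sym]:
                shell_l.append(l)
                shell_atom.append(iat)
                pstart.append(len(exps))
                nprim.append(len(prims))
                for e, c in prims:
                    exps.append(e)
                    coefs.append(c * _prim_norm(e, l))
        self.shell_l = np.array(shell_l, dtype=np.int64)
        self.shell_atom = np.array(shell_atom, dtype=np.int64)
        self.shell_pstart = np.array(pstart, dtype=np.int64)
        self.shell_nprim = np.array(nprim, dtype=np.int64)
        self.prim_exp = np.array(exps, dtype=np.float64)
        self.prim_coef = np.array(coefs, dtype=np.float64)
        self.nshell = len(shell_l)

        # normalize contracted shells (all m-components share one norm)
        for ish in range(self.nshell):
            l = self.shell_l[ish]
            s0 = self.shell_pstart[ish]
            n = self.shell_nprim[ish]
            c = self.prim_coef[s0:s0 + n]
            e = self.prim_exp[s0:s0 + n]
            dfact = 1.0
            for k in range(2 * l + 1, 0, -2):
                dfact *= k
            P = e[:, None] + e[None, :]
            J = dfact * np.sqrt(np.pi / P) / (2.0 * (2.0 * P) ** (l + 1))
            self_ov = 4.0 * np.pi / (2 * l + 1) * (c[:, None] * c[None, :] * J).sum()
            self.prim_coef[s0:s0 + n] = c / np.sqrt(self_ov)

        ncart = (self.shell_l + 1) * (self.shell_l + 2) // 2
        nsph = 2 * self.shell_l + 1
        self.shell_cstart = np.concatenate([[0], np.cumsum(ncart)])[:-1].astype(np.int64)
        self.shell_sstart = np.concatenate([[0], np.cumsum(nsph)])[:-1].astype(np.int64)
        self.ncart = int(ncart.sum())
        self.nsph = int(nsph.sum())

    @property
    def nao(self) -> int:
        return self.nsph

    def c2s_matrix(self) -> np.ndarray:
        """Block matrix C (nsph x ncart): M_sph = C @ M_cart @ C.T."""
        C = np.zeros((self.nsph, self.ncart))
        for ish in range(self.nshell):
            l = int(self.shell_l[ish])
            blk = np.asarray(C2S[l])
            s0 = self.shell_sstart[ish]
            c0 = self.shell_cstart[ish]
            C[s0:s0 + blk.shape[0], c0:c0 + blk.shape[1]] = blk
        return C

    def ao_shell_slices(self):
        """Per-shell (l, start, stop) over the spherical AO dimension."""
        out = []
        for ish in range(self.nshell):
            l = int(self.shell_l[ish])
            s0 = int(self.shell_sstart[ish])
            out.append((l, s0, s0 + 2 * l + 1))
        return out

    def kernel_args(self):
        return (self.nshell, self.shell_l, self.shell_atom, self.shell_pstart,
                self.shell_nprim, self.shell_cstart, self.prim_exp,
                self.prim_coef, self.coords)
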