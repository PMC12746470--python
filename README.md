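# rdmlearn

Surrogate electronic structure from machine-learned one-electron reduced
density matrices (1-RDMs).

`rdmlearn` learns the map from the electron–nuclear (external) potential
matrix v̂ to the converged one-electron density matrix γ̂ with matrix-target
kernel ridge regression. Predicted densities are made N-representable by a
single-diagonalization aufbau purification (occupations in {0, 2}, exact
electron count), and every downstream quantity — total energies, dipoles,
kinetic energies, HOMO–LUMO gaps, and atomic forces — is evaluated from the
predicted density. Because a predicted density is not variational, plain
Hellmann–Feynman + Pulay forces are inconsistent with the energy surface;
the package implements the correction built from the residual
occupied–virtual Fock coupling, `F = F_HF+Pulay − Tr[(f − f′) ∂γ/∂R]`,
which restores energy–force consistency to ~1e-6 Ha/Å and makes NVE
molecular dynamics on the surrogate surface stable.

The reference data come from a self-contained restricted Hartree–Fock
engine (McMurchie–Davidson Gaussian integrals JIT-compiled with numba:
overlap/kinetic/nuclear-attraction/dipole/ERI plus the analytic derivative
integrals needed for forces and Hessians). Shipped basis sets: STO-3G,
6-31G, 6-31G*, cc-pVDZ, cc-pVTZ for H, C, N, O.

## Layout

| module | what it does |
| --- | --- |
| `rdmlearn.representation` | geometries, symmetric AO matrices, feature packing, Kabsch frame alignment + solid-harmonic AO rotations, XYZ I/O |
| `rdmlearn.engine` | the SCF engine adapter: v̂, S, SCF, Fock builds, E[γ], analytic forces, normal modes, ∂v̂/∂R |
| `rdmlearn.sampling` | thermal normal-mode training-set generation (variance k_BT/ω² per mode), torsion sweeps, AIMD test sets |
| `rdmlearn.learning` | kernels (LIN/RBF/POL), matrix-target KRR fit/predict, aufbau purification, affine δ-models, model flavors |
| `rdmlearn.tuning` | k-fold cross-validated grid/randomized kernel search |
| `rdmlearn.properties_forces` | energies/gaps/properties from predicted densities; f′, ∂γ/∂R (analytic + finite-difference routes), corrected forces |
| `rdmlearn.dynamics` | NVE velocity Verlet, Maxwell–Boltzmann initialization, energy-drift and trajectory-decoherence diagnostics |
| `rdmlearn.cli` / `rdmlearn.io` | command-line workflow, YAML config, HDF5 model/training-set archives |

Model flavors: `gamma` (purified KRR density; E/F evaluated from it),
`gamma+delta` (adds an affine refinement of the predicted density), and
`delta_learned` (affine maps from the purified density straight to E and F —
no Fock build at prediction time).

## CLI

```bash
rdmlearn gen-train --config config.yaml --out run/train --with-forces
rdmlearn tune      --trainset run/train/trainset.h5 --out run/tune
rdmlearn fit       --trainset run/train/trainset.h5 --config config.yaml \
                   --out run/model.h5 [--flavor gamma|gamma+delta|delta_learned]
rdmlearn predict   --model run/model.h5 --geoms geoms.xyz --out run/pred --forces
rdmlearn eval      --model run/model.h5 --geoms geoms.xyz --out run/eval --with-forces
rdmlearn scan      --config config.yaml --sizes 10,20,40 --out run/scan
rdmlearn md        --model run/model.h5 --geom h2o.xyz --out run/md \
                   --temperature 300 --dt 0.5 --n-steps 2000
```

A minimal `config.yaml`:

```yaml
molecule: h2o.xyz
method: {functional: HF, basis: sto-3g}
sampler: {temperature: 300.0, n_samples: 27, seed: 0}
kernel: {kind: RBF, alpha: 0.0}        # width defaults to 1/N_features
```

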