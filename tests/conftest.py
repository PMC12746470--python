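"""Shared fixtures. Heavy objects (SCF engines, fitted models) are
session-scoped so the suite stays inside its time budget."""

import os

import numpy as np
import pytest

from rdmlearn.data import reference_geometry
from rdmlearn.engine import MethodSpec, SCFEngine
from rdmlearn.learning import KernelSpec, ModelStack, fit_gamma
from rdmlearn.representation import Geometry
from rdmlearn.sampling import (SamplerConfig, build_training_set,
                               sample_normal_mode_geometries)

RUN_SLOW = bool(os.environ.get("RDMLEARN_RUN_SLOW"))

slow = pytest.mark.skipif(
    not RUN_SLOW, reason="extended test; set RDMLEARN_RUN_SLOW=1 to run")


@pytest.fixture(scope="session")
def sto3g():
    return MethodSpec(functional="HF", basis="sto-3g")


@pytest.fixture(scope="session")
def engine(sto3g):
    return SCFEngine(sto3g)


@pytest.fixture(scope="session")
def water_eq():
    return reference_geometry("h2o")


@pytest.fixture(scope="session")
def water_bent():
    """A displaced, asymmetric water geometry (not a stationary point)."""
    return Geometry([8, 1, 1], [[0.0, 0.0, 0.1173],
                                [0.0, 0.7572, -0.4692],
                                [0.05, -0.70, -0.52]])


@pytest.fixture(scope="session")
def water_modes(engine, water_eq):
    return engine.hessian_normal_modes(water_eq)


@pytest.fixture(scope="session")
def water_train(engine, water_eq, water_modes, sto3g):
    geoms = sample_normal_mode_geometries(
        water_eq, water_modes, SamplerConfig(temperature=300.0, n_samples=27,
                                             seed=11))
    return build_training_set(geoms, water_eq, sto3g, engine,
                              with_forces=True,
                              provenance={"T": 300.0, "seed": 11})


@pytest.fixture(scope="session")
def water_test(engine, water_eq, water_modes, sto3g):
    geoms = sample_normal_mode_geometries(
        water_eq, water_modes, SamplerConfig(temperature=300.0, n_samples=10,
                                             seed=4242))
    return build_training_set(geoms, water_eq, sto3g, engine)


@pytest.fixture(scope="session")
def water_model(water_train):
    return fit_gamma(water_train, KernelSpec(kind="RBF", alpha=0.0))


@pytest.fixture(scope="session")
def water_stack(water_model):
    return ModelStack(gamma_model=water_model)


@pytest.fixture(scope="session")
def methanol_eq():
    return reference_geometry("ch3oh")


@pytest.fixture(scope="session")
def methanol_modes(engine, methanol_eq):
    return engine.hessian_normal_modes(methanol_eq)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
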