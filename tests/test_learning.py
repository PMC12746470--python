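import numpy as np
import pytest

from rdmlearn.engine import MethodSpec
from rdmlearn.exceptions import ConfigurationError, InputError
from rdmlearn.learning import (KernelSpec, ModelStack, fit_delta_properties,
                               fit_delta_refine, fit_gamma, kernel_eval,
                               kernel_matrix, natural_occupations,
                               predict_full, predict_gamma,
                               predict_gamma_features, purify)
from rdmlearn.representation import Geometry, pack_symmetric, unpack_symmetric
from rdmlearn.sampling import TrainingSet


def synthetic_trainset(n, dim, rng, fn, noise=0.0):
    """TrainingSet whose targets are a known matrix functional of v."""
    ref = Geometry([8, 1, 1], [[0, 0, 0.1], [0, 0.76, -0.47], [0, -0.76, -0.47]])
    Xv, Xg = [], []
    for _ in range(n):
        a = rng.standard_normal((dim, dim)) * 0.3
        v = 0.5 * (a + a.T)
        g = fn(v)
        if noise:
            e = rng.standard_normal((dim, dim)) * noise
            g = g + 0.5 * (e + e.T)
        Xv.append(pack_symmetric(v).values)
        Xg.append(pack_symmetric(g).values)
    z = np.zeros((n, 3, 3))
    return TrainingSet(features_v=np.array(Xv), features_gamma=np.array(Xg),
                       energies=np.zeros(n), positions_lab=z,
                       positions_aligned=z, rotations=np.tile(np.eye(3), (n, 1, 1)),
                       reference=ref, method=MethodSpec())


class TestKernels:
    def test_rbf_self_is_one(self, rng):
        x = rng.standard_normal(6)
        assert kernel_eval(x, x, KernelSpec(kind="RBF")) == 1.0

    def test_pol_unit_base(self):
        x = np.array([1.0, 0.0])
        y = np.array([2.0, 0.0])
        k = KernelSpec(kind="POL", gamma_scale=0.5, offset=0.0, degree=3)
        assert kernel_eval(x, y, k) == pytest.approx(1.0)

    def test_lin_hand_dot(self):
        assert kernel_eval([1.0, 2.0], [3.0, 4.0],
                           KernelSpec(kind="LIN")) == pytest.approx(11.0)

    def test_defaults(self):
        k = KernelSpec(kind="POL")
        assert k.degree == 3 and k.offset == 0.0
        assert k.resolve(20).gamma_scale == pytest.approx(1.0 / 20)

    def test_matrix_brute_force_oracle(self, rng):
        X = rng.standard_normal((5, 4))
        Y = rng.standard_normal((5, 4))
        for kind in ("LIN", "RBF", "POL"):
            k = KernelSpec(kind=kind)
            K = kernel_matrix(X, Y, k)
            for i in range(5):
                for j in range(5):
                    assert K[i, j] == pytest.approx(
                        kernel_eval(X[i], Y[j], k), abs=1e-12)

    def test_rbf_unit_diag_and_psd(self, rng):
        X = rng.standard_normal((20, 7))
        K = kernel_matrix(X, X, KernelSpec(kind="RBF"))
        np.testing.assert_allclose(np.diag(K), 1.0)
        assert np.linalg.eigvalsh(K).min() >= -1e-10

    def test_lin_psd(self, rng):
        X = rng.standard_normal((20, 7))
        K = kernel_matrix(X, X, KernelSpec(kind="LIN"))
        assert np.linalg.eigvalsh(K).min() >= -1e-10

    def test_shape_mismatch(self, rng):
        with pytest.raises(InputError):
            kernel_eval(np.ones(3), np.ones(4), KernelSpec())

    def test_unknown_kind(self):
        with pytest.raises(ConfigurationError):
            KernelSpec(kind="MATERN")


class TestFitGamma:
    def test_one_point_interpolation(self, rng):
        ts = synthetic_trainset(1, 3, rng, lambda v: v @ v + v)
        model = fit_gamma(ts, KernelSpec(kind="LIN", alpha=0.0))
        pred = predict_gamma_features(model, ts.features_v[0])
        np.testing.assert_allclose(pred, ts.features_gamma[0], atol=1e-8)

    def test_interpolation_synthetic_functional(self, rng):
        ts = synthetic_trainset(10, 4, rng, lambda v: v @ v + v)
        model = fit_gamma(ts, KernelSpec(kind="RBF", alpha=0.0))
        pred = predict_gamma_features(model, ts.features_v)
        assert np.abs(pred - ts.features_gamma).max() < 1e-8

    def test_duplicate_rows_alpha0_rejected(self, rng):
        ts = synthetic_trainset(4, 3, rng, lambda v: v)
        ts.features_v[1] = ts.features_v[0]
        with pytest.raises(ConfigurationError):
            fit_gamma(ts, KernelSpec(kind="RBF", alpha=0.0))

    def test_alpha0_beats_alpha01_on_water(self, water_train, water_test):
        rmses = {}
        for alpha in (0.0, 0.1):
            model = fit_gamma(water_train, KernelSpec(kind="RBF", alpha=alpha))
            pred = predict_gamma_features(model, water_test.features_v)
            rmses[alpha] = np.sqrt(np.mean((pred - water_test.features_gamma) ** 2))
        assert rmses[0.0] < rmses[0.1]

    def test_weights_unpack_symmetric(self, water_model):
        for row in water_model.B[:3]:
            m = unpack_symmetric(row)
            assert np.array_equal(m, m.T)

    def test_normal_equations_oracle(self, rng):
        # direct dense solve of (K + aI) B = Y must match
        ts = synthetic_trainset(15, 3, rng, lambda v: 2 * v)
        k = KernelSpec(kind="RBF", alpha=1e-3)
        model = fit_gamma(ts, k)
        K = kernel_matrix(ts.features_v, ts.features_v, k)
        B_ref = np.linalg.solve(K + 1e-3 * np.eye(15), ts.features_gamma)
        np.testing.assert_allclose(model.B, B_ref, atol=1e-8)

    def test_noise_floor_recovery(self, rng):
        # with additive noise sigma, test RMSE approaches sigma from above
        # and decreases with training size
        sigma = 1e-3
        fn = lambda v: v * 0.5  # noqa: E731 - exactly learnable
        test = synthetic_trainset(40, 3, np.random.default_rng(5), fn)
        rmses = []
        for n in (10, 40, 160):
            ts = synthetic_trainset(n, 3, np.random.default_rng(1), fn,
                                    noise=sigma)
            model = fit_gamma(ts, KernelSpec(kind="LIN", alpha=1e-8))
            pred = predict_gamma_features(model, test.features_v)
            rmses.append(np.sqrt(np.mean((pred - test.features_gamma) ** 2)))
        assert rmses[2] < rmses[0] * 2
        assert rmses[2] < 3 * sigma


class TestPredictGamma:
    def test_training_point_interpolation(self, water_model, water_train):
        # the thermal water kernel system has cond(K) ~ 1e14, which amplifies
        # kernel-evaluation roundoff; interpolation is solver-limited at
        # ~kappa * eps, not at the 1e-8 seen for well-conditioned inputs
        out = predict_gamma(water_model, water_train.features_v[0])
        target = unpack_symmetric(water_train.features_gamma[0])
        assert np.abs(out.values - target).max() < 5e-7

    def test_continuity_scan(self, water_model, water_train, rng):
        v0 = water_train.features_v[0]
        u = rng.standard_normal(len(v0))
        u /= np.linalg.norm(u)
        base = predict_gamma_features(water_model, v0)
        deltas = []
        for eps in (1e-1, 1e-2, 1e-3, 1e-4, 1e-5):
            d = predict_gamma_features(water_model, v0 + eps * u) - base
            deltas.append(np.linalg.norm(d))
        assert all(a > b for a, b in zip(deltas, deltas[1:]))
        assert deltas[-1] < 1e-5 * deltas[0] * 1e4  # -> 0 linearly

    def test_raw_trace_soft_check(self, water_model, water_test, engine,
                                  water_eq):
        for i in range(water_test.n_samples):
            raw = unpack_symmetric(
                predict_gamma_features(water_model, water_test.features_v[i]))
            aligned = water_eq.with_positions(water_test.positions_aligned[i])
            S = engine.overlap_matrix(aligned).values
            assert abs(np.sum(raw * S) - 10.0) < 1e-3

    def test_dimension_mismatch(self, water_model):
        with pytest.raises(InputError):
            predict_gamma_features(water_model, np.ones(5))


class TestPurify:
    def test_two_level_hand_computation(self):
        # orthonormal 2-level toy, occupations (1.9, 0.1) on fixed axes
        gamma = np.diag([1.9, 0.1])
        out = purify(gamma, np.eye(2), 2)
        np.testing.assert_allclose(out.values, np.diag([2.0, 0.0]), atol=1e-12)

    def test_fixed_point(self, engine, water_eq):
        res = engine.run_scf(water_eq, with_forces=False)
        out = purify(res.gamma, res.overlap, 10)
        assert np.abs(out.values - res.gamma.values).max() < 1e-7

    def test_idempotent_operation(self, water_model, water_test, engine,
                                  water_eq):
        i = 0
        raw = unpack_symmetric(
            predict_gamma_features(water_model, water_test.features_v[i]))
        aligned = water_eq.with_positions(water_test.positions_aligned[i])
        S = engine.overlap_matrix(aligned).values
        p1 = purify(raw, S, 10)
        p2 = purify(p1, S, 10)
        assert np.abs(p2.values - p1.values).max() < 1e-10

    def test_exact_n_representability(self, water_model, water_test, engine,
                                      water_eq):
        for i in range(3):
            raw = unpack_symmetric(
                predict_gamma_features(water_model, water_test.features_v[i]))
            aligned = water_eq.with_positions(water_test.positions_aligned[i])
            S = engine.overlap_matrix(aligned).values
            out = purify(raw, S, 10)
            occ, _ = natural_occupations(out.values, S)
            # occupations in {0, 2}, summing to N
            assert np.all((np.abs(occ) < 1e-9) | (np.abs(occ - 2) < 1e-9))
            assert occ.sum() == pytest.approx(10.0, abs=1e-10)
            assert np.sum(out.values * S) == pytest.approx(10.0, abs=1e-10)
            g = out.values
            assert np.linalg.norm(g @ S @ g - 2 * g) < 1e-8

    def test_odd_electrons_rejected(self):
        with pytest.raises(InputError):
            purify(np.eye(2), np.eye(2), 3)


class TestDeltaModels:
    def test_refine_identity(self, rng):
        X = rng.standard_normal((30, 6))
        dm = fit_delta_refine(X, X)
        np.testing.assert_allclose(dm.predict(X), X, atol=1e-8)

    def test_refine_bias_recovery(self, rng):
        X = rng.standard_normal((30, 6))
        bias = rng.standard_normal(6)
        dm = fit_delta_refine(X, X + bias)
        np.testing.assert_allclose(dm.predict(X) - X,
                                   np.tile(bias, (30, 1)), atol=1e-8)

    def test_refine_fixes_constructed_linear_error(self, rng):
        # gamma model with a systematic linear error that refinement removes
        A = rng.standard_normal((6, 6)) * 0.1 + np.eye(6)
        truth = rng.standard_normal((60, 6))
        corrupted = truth @ A.T + 0.05
        dm = fit_delta_refine(corrupted[:40], truth[:40])
        before = np.sqrt(np.mean((corrupted[40:] - truth[40:]) ** 2))
        after = np.sqrt(np.mean((dm.predict(corrupted[40:]) - truth[40:]) ** 2))
        assert after < before / 10

    def test_refine_training_residual_never_worse(self, rng):
        X = rng.standard_normal((25, 5))
        Y = X + 0.1 * rng.standard_normal((25, 5))
        dm = fit_delta_refine(X, Y)
        before = np.mean((X - Y) ** 2)
        after = np.mean((dm.predict(X) - Y) ** 2)
        assert after <= before + 1e-12

    def test_properties_affine_energy_recovery(self, rng):
        # E = Tr[gamma h] + const is exactly affine in packed features
        dim = 4
        h = rng.standard_normal((dim, dim))
        h = 0.5 * (h + h.T)
        feats, es = [], []
        for _ in range(30):
            a = rng.standard_normal((dim, dim))
            g = 0.5 * (a + a.T)
            feats.append(pack_symmetric(g).values)
            es.append(np.sum(g * h) + 1.7)
        models = fit_delta_properties(np.array(feats), energies=np.array(es))
        pred = models["energy"].predict(np.array(feats))[:, 0]
        np.testing.assert_allclose(pred, es, atol=1e-9)

    def test_force_mean_property(self, rng):
        feats = rng.standard_normal((20, 8))
        forces = rng.standard_normal((20, 3, 3))
        models = fit_delta_properties(feats, forces=forces)
        pred = models["forces"].predict(feats).reshape(20, 3, 3)
        np.testing.assert_allclose(pred.mean(axis=0), forces.mean(axis=0),
                                   atol=1e-6)

    def test_row_mismatch(self, rng):
        with pytest.raises(InputError):
            fit_delta_refine(rng.standard_normal((5, 3)),
                             rng.standard_normal((4, 3)))


class TestPredictFull:
    def _context(self, engine, water_eq, water_test, i=0):
        aligned = water_eq.with_positions(water_test.positions_aligned[i])
        S = engine.overlap_matrix(aligned)
        return aligned, S

    def test_gamma_flavor_training_energy(self, water_stack, water_train,
                                          engine, water_eq):
        i = 0
        aligned = water_eq.with_positions(water_train.positions_aligned[i])
        S = engine.overlap_matrix(aligned)
        out = predict_full(water_stack, water_train.features_v[i], S, 10,
                           energy_evaluator=lambda g: engine.energy_from_dm(g, aligned))
        assert out["energy"] == pytest.approx(water_train.energies[i], abs=1e-7)

    def test_refined_flavor_never_worse_on_training(self, water_model,
                                                    water_train, engine,
                                                    water_eq):
        preds = []
        for i in range(water_train.n_samples):
            raw = unpack_symmetric(
                predict_gamma_features(water_model, water_train.features_v[i]))
            aligned = water_eq.with_positions(water_train.positions_aligned[i])
            S = engine.overlap_matrix(aligned).values
            preds.append(pack_symmetric(purify(raw, S, 10).values).values)
        preds = np.array(preds)
        refine = fit_delta_refine(preds, water_train.features_gamma)
        before = np.mean((preds - water_train.features_gamma) ** 2)
        after = np.mean((refine.predict(preds) - water_train.features_gamma) ** 2)
        assert after <= before + 1e-14

    def test_delta_flavor_no_fock_build(self, water_model, water_train,
                                        engine, water_eq):
        # wiring: the delta-learned flavor returns E/F without any Fock build
        preds = water_train.features_gamma  # stand-in purified features
        props = fit_delta_properties(preds, energies=water_train.energies,
                                     forces=water_train.forces)
        stack = ModelStack(gamma_model=water_model, flavor="delta_learned",
                           delta_energy=props["energy"],
                           delta_forces=props["forces"])
        i = 0
        aligned = water_eq.with_positions(water_train.positions_aligned[i])
        S = engine.overlap_matrix(aligned)
        count_before = engine.fock_call_count
        out = predict_full(stack, water_train.features_v[i], S, 10)
        assert engine.fock_call_count == count_before
        assert "energy" in out and "forces" in out
        assert "gamma" in out  # the 1-RDM remains available

    def test_missing_submodel_rejected(self, water_model):
        stack = ModelStack(gamma_model=water_model, flavor="delta_learned")
        with pytest.raises(ConfigurationError):
            stack.require()


class TestModelArchive:
    def test_round_trip_bit_exact(self, water_stack, water_train, tmp_path):
        from rdmlearn.io import load_model, save_model

        path = tmp_path / "model.h5"
        save_model(water_stack, path)
        back = load_model(path)
        assert np.array_equal(back.gamma_model.X, water_stack.gamma_model.X)
        assert np.array_equal(back.gamma_model.B, water_stack.gamma_model.B)
        v = water_train.features_v[0]
        np.testing.assert_array_equal(
            predict_gamma_features(back.gamma_model, v),
            predict_gamma_features(water_stack.gamma_model, v))

    def test_self_describing(self, water_stack, tmp_path):
        from rdmlearn.io import load_model, save_model

        path = tmp_path / "model.h5"
        save_model(water_stack, path)
        back = load_model(path)
        assert back.gamma_model.method.basis == "sto-3g"
        assert back.gamma_model.n_train == 27
        assert back.gamma_model.kernel.kind == "RBF"

    def test_metadata_mismatch_refused(self, water_stack, water_eq):
        from rdmlearn.io import check_model_compatibility

        with pytest.raises(InputError):
            check_model_compatibility(water_stack, MethodSpec(basis="6-31g"),
                                      water_eq)
        with pytest.raises(InputError):
            check_model_compatibility(
                water_stack, MethodSpec(basis="sto-3g"),
                Geometry([8, 8], [[0, 0, 0], [0, 0, 1.2]]))
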