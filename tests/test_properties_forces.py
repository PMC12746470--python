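import numpy as np
import pytest
from scipy.stats import spearmanr

from rdmlearn.exceptions import ConfigurationError, InputError
from rdmlearn.learning import ModelStack
from rdmlearn.properties_forces import (ForceContext, SurrogatePredictor,
                                        canonicalized_natural_orbitals,
                                        correction_term, fock_prime,
                                        homo_lumo_gap)
from rdmlearn.sampling import SamplerConfig, sample_normal_mode_geometries

HARTREE_TO_EV = 27.211386245988


@pytest.fixture(scope="module")
def predictor(water_train, engine):
    # a 15-sample model: the 27-sample alpha=0 kernel system has cond ~ 1e14,
    # and the resulting roundoff amplification would swamp the tight
    # derivative tolerances tested here without changing the physics
    from rdmlearn.learning import KernelSpec, fit_gamma

    model = fit_gamma(water_train.subset(np.arange(15)),
                      KernelSpec(kind="RBF", alpha=0.0))
    return SurrogatePredictor(ModelStack(model), engine,
                              force_mode="corrected")


@pytest.fixture(scope="module")
def displaced_water(water_eq, water_modes):
    return sample_normal_mode_geometries(
        water_eq, water_modes, SamplerConfig(temperature=300.0, n_samples=6,
                                             seed=909))


class TestHomoLumoGap:
    def test_converged_gamma_matches_engine(self, engine, water_eq):
        res = engine.run_scf(water_eq, with_forces=False)
        nocc = 5
        ref_gap = res.orbital_energies[nocc] - res.orbital_energies[nocc - 1]
        gap = homo_lumo_gap(res.gamma, water_eq, engine, return_ev=False)
        assert gap == pytest.approx(ref_gap, abs=1e-7)

    def test_rotation_invariance(self, predictor, water_eq):
        from scipy.spatial.transform import Rotation

        R = Rotation.from_euler("zyx", [25, -40, 65], degrees=True).as_matrix()
        g2 = water_eq.with_positions(water_eq.positions @ R.T + [1.0, -2.0, 0.5])
        gap1 = predictor.homo_lumo_gap(water_eq, return_ev=False)
        gap2 = predictor.homo_lumo_gap(g2, return_ev=False)
        assert gap1 == pytest.approx(gap2, abs=1e-6)

    def test_gap_accuracy_on_thermal_geometries(self, predictor, engine,
                                                displaced_water):
        for g in displaced_water[:3]:
            res = engine.run_scf(g, with_forces=False)
            ref = (res.orbital_energies[5] - res.orbital_energies[4]) * HARTREE_TO_EV
            ml = predictor.homo_lumo_gap(g)
            assert ml == pytest.approx(ref, abs=5e-3)

    def test_stretch_scan_error_grows_away_from_training(self, predictor,
                                                         engine, water_eq):
        # stretch one O-H bond progressively beyond the thermal training span
        direction = water_eq.positions[1] - water_eq.positions[0]
        direction /= np.linalg.norm(direction)
        stretches = np.array([0.0, 0.1, 0.25, 0.4, 0.6])
        errs = []
        for s in stretches:
            pos = water_eq.positions.copy()
            pos[1] += s * direction
            g = water_eq.with_positions(pos)
            res = engine.run_scf(g, with_forces=False)
            ref = (res.orbital_energies[5] - res.orbital_energies[4]) * HARTREE_TO_EV
            errs.append(abs(predictor.homo_lumo_gap(g) - ref))
        rho, _ = spearmanr(stretches, errs)
        assert rho > 0


class TestFockPrime:
    def test_converged_limit(self, engine, water_eq):
        res = engine.run_scf(water_eq, with_forces=False)
        F = engine.fock_build(res.gamma, water_eq)
        fp = fock_prime(F, res.gamma, res.overlap)
        assert np.linalg.norm(F.values - fp.values) < 1e-6

    def test_two_level_hand_computation(self):
        f = np.array([[-1.0, 0.2], [0.2, 1.0]])
        gamma = np.diag([2.0, 0.0])  # natural orbitals = coordinate axes
        fp = fock_prime(f, gamma, np.eye(2))
        np.testing.assert_allclose(fp.values, np.diag([-1.0, 1.0]), atol=1e-12)
        df = f - fp.values
        np.testing.assert_allclose(df, [[0.0, 0.2], [0.2, 0.0]], atol=1e-12)

    def test_df_diagonal_zero_in_natural_basis(self, predictor, displaced_water):
        ctx = predictor.force_context(displaced_water[0])
        df = ctx.fock.values - ctx.fock_prime.values
        C = ctx.natural_orbitals
        in_nat = C.T @ df @ C
        assert np.abs(np.diag(in_nat)).max() < 1e-9

    def test_dimension_mismatch(self):
        with pytest.raises(InputError):
            fock_prime(np.eye(3), np.eye(2), np.eye(2))


class TestCanonicalizedNaturalOrbitals:
    def test_matches_scf_at_convergence(self, engine, water_eq):
        res = engine.run_scf(water_eq, with_forces=False)
        F = engine.fock_build(res.gamma, water_eq).values
        occ, C, eps = canonicalized_natural_orbitals(res.gamma.values,
                                                     res.overlap.values, F)
        # occupied-block energies equal the SCF occupied orbital energies
        np.testing.assert_allclose(np.sort(eps[:5]),
                                   res.orbital_energies[:5], atol=1e-6)
        np.testing.assert_allclose(occ[:5], 2.0, atol=1e-7)


class TestGradGamma:
    def test_analytic_vs_fd_agreement(self, predictor, displaced_water):
        g = displaced_water[0]
        ga = predictor.grad_gamma(g, mode="analytic")
        gf = predictor.grad_gamma(g, mode="fd")
        assert np.abs(ga - gf).max() < 1e-5

    def test_secant_against_nearby_training_pair(self, predictor, water_eq,
                                                 water_modes):
        # leading-order prediction of the density change along a short
        # geometric displacement
        g = sample_normal_mode_geometries(
            water_eq, water_modes, SamplerConfig(temperature=300.0,
                                                 n_samples=1, seed=31))[0]
        d = np.zeros_like(g.positions)
        d[1, 1] = 5e-3
        g2 = g.with_positions(g.positions + d)
        grad = predictor.grad_gamma(g, mode="fd")
        pred_change = grad[1, 1] * 5e-3
        actual = (predictor.predict(g2)["gamma_lab"].values
                  - predictor.predict(g)["gamma_lab"].values)
        denom = np.abs(actual).max()
        assert np.abs(pred_change - actual).max() < 0.1 * denom

    def test_translation_sum_rule(self, predictor, displaced_water):
        # uniform translation leaves AO matrices unchanged, so the per-atom
        # derivatives must cancel
        grad = predictor.grad_gamma(displaced_water[1], mode="fd")
        assert np.abs(grad.sum(axis=0)).max() < 1e-5

    def test_translation_invariance_engine_oracle(self, predictor,
                                                  displaced_water):
        g = displaced_water[2]
        shifted = g.with_positions(g.positions + [0.7, -0.3, 0.2])
        g1 = predictor.predict(g)["gamma_lab"].values
        g2 = predictor.predict(shifted)["gamma_lab"].values
        assert np.abs(g1 - g2).max() < 1e-8

    def test_unknown_mode(self, predictor, displaced_water):
        with pytest.raises(ConfigurationError):
            predictor.grad_gamma(displaced_water[0], mode="exact")


class TestComputeForces:
    def test_variational_limit_matches_engine(self, engine, water_eq,
                                              water_bent):
        # with the converged density, HF+Pulay reproduces engine forces and
        # the correction vanishes
        res = engine.run_scf(water_bent)
        F = engine.fock_build(res.gamma, water_bent)
        occ, C, eps = canonicalized_natural_orbitals(
            res.gamma.values, res.overlap.values, F.values)
        W = C @ np.diag(eps * occ) @ C.T
        forces = engine.analytic_forces_from_dm(res.gamma, W, water_bent)
        assert np.abs(forces - res.forces).max() < 1e-6
        fp = fock_prime(F, res.gamma, res.overlap)
        ctx = ForceContext(gamma=res.gamma, fock=F, fock_prime=fp,
                           natural_orbitals=C, occupations=occ,
                           orbital_energies=eps, weighted_density=W,
                           grad_gamma=np.ones((3, 3, 7, 7)))
        assert np.abs(correction_term(ctx)).max() < 1e-6

    def test_energy_force_consistency_corrected(self, predictor,
                                                displaced_water):
        g = displaced_water[3]
        F = predictor.compute_forces(g, "corrected")
        h = 1e-3
        for (i, d) in ((0, 2), (1, 1), (2, 0)):
            pp = g.positions.copy()
            pp[i, d] += h
            pm = g.positions.copy()
            pm[i, d] -= h
            fd = -(predictor.energy(g.with_positions(pp))
                   - predictor.energy(g.with_positions(pm))) / (2 * h)
            assert F[i, d] == pytest.approx(fd, abs=1e-4)

    def test_corrected_beats_hellmann_feynman_paired(self, predictor,
                                                     displaced_water):
        # energy-force consistency must be strictly better with the
        # correction, geometry by geometry
        h = 1e-3
        for g in displaced_water:
            fd = np.zeros((3, 3))
            for i in range(3):
                for d in range(3):
                    pp = g.positions.copy()
                    pp[i, d] += h
                    pm = g.positions.copy()
                    pm[i, d] -= h
                    fd[i, d] = -(predictor.energy(g.with_positions(pp))
                                 - predictor.energy(g.with_positions(pm))) / (2 * h)
            err_hf = np.abs(predictor.compute_forces(g, "hellmann_feynman") - fd).max()
            err_corr = np.abs(predictor.compute_forces(g, "corrected") - fd).max()
            assert err_corr < err_hf

    def test_correction_vanishing_scan(self, predictor, engine, water_eq,
                                       displaced_water):
        # gamma_t = purify((1-t) gamma_pred + t gamma_scf): the corrected-force
        # deviation from engine analytic forces shrinks along the scan
        from rdmlearn.learning import purify

        g = displaced_water[4]
        res = engine.run_scf(g)
        pred_gamma = predictor.predict(g)["gamma_lab"].values
        S = res.overlap
        devs = []
        for t in (0.0, 0.5, 1.0):
            mix = (1 - t) * pred_gamma + t * res.gamma.values
            gam = purify(mix, S.values, 10)
            F = engine.fock_build(gam, g)
            occ, C, eps = canonicalized_natural_orbitals(gam.values, S.values,
                                                         F.values)
            W = C @ np.diag(eps * occ) @ C.T
            forces = engine.analytic_forces_from_dm(gam, W, g)
            devs.append(np.abs(forces - res.forces).max())
        assert devs[2] < 1e-6
        assert devs[2] <= devs[1] <= devs[0] + 1e-12

    def test_hf_mode_translational_sum_rule(self, predictor, displaced_water):
        F = predictor.compute_forces(displaced_water[0], "hellmann_feynman")
        assert np.abs(F.sum(axis=0)).max() < 1e-6

    def test_delta_learned_mode(self, water_model, water_train, engine):
        from rdmlearn.learning import fit_delta_properties

        props = fit_delta_properties(water_train.features_gamma,
                                     energies=water_train.energies,
                                     forces=water_train.forces)
        stack = ModelStack(gamma_model=water_model, flavor="delta_learned",
                           delta_energy=props["energy"],
                           delta_forces=props["forces"])
        pred = SurrogatePredictor(stack, engine, force_mode="delta_learned")
        g = water_model.reference.with_positions(water_train.positions_lab[0])
        F = pred.compute_forces(g, "delta_learned")
        assert F.shape == (3, 3)
        assert np.abs(F - water_train.forces[0]).max() < 5e-3

    def test_missing_force_model_rejected(self, predictor, displaced_water):
        with pytest.raises(ConfigurationError):
            predictor.compute_forces(displaced_water[0], "delta_learned")


class TestPredictor:
    def test_purified_energy_above_variational(self, predictor, engine,
                                               displaced_water):
        # variational bound: E[gamma_pred] >= E_scf for nearly every geometry
        above = 0
        for g in displaced_water:
            e_ml = predictor.energy(g)
            e_scf = engine.run_scf(g, with_forces=False).energy
            if e_ml >= e_scf - 1e-12:
                above += 1
        assert above >= int(0.95 * len(displaced_water))

    def test_energy_frame_invariance(self, predictor, water_eq):
        from scipy.spatial.transform import Rotation

        R = Rotation.from_euler("xyz", [10, 20, 30], degrees=True).as_matrix()
        g2 = water_eq.with_positions(water_eq.positions @ R.T + 3.0)
        assert predictor.energy(water_eq) == pytest.approx(
            predictor.energy(g2), abs=1e-9)
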