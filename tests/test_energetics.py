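"""Force field correctness and Langevin sampling properties."""
import math

import numpy as np
import pytest

from metadhs import (
    KB,
    COULOMB_K,
    EnergyModel,
    SimState,
    SingularityError,
    build_model,
    equilibrate,
    forces,
    langevin_step,
    langevin_steps,
    lj_energy,
    potential_energy,
    run_unbiased,
    screened_coulomb,
    com_displacement,
)


def make_model(n, masses=None, restraint_k=None, pairs=None, charges=None,
               eps=0.0, sigma=3.2, ridge_h=(0.0, 0.0), ridge_z=9.0,
               sphere_r=1e6, cyl_k=0.0, native=None):
    """Minimal hand-built EnergyModel for controlled scenarios."""
    masses = np.full(n, 14.0) if masses is None else np.asarray(masses, float)
    restraint_k = (np.zeros(n) if restraint_k is None
                   else np.asarray(restraint_k, float))
    if pairs is None:
        pi = pj = np.empty(0, dtype=np.int64)
    else:
        pi = np.array([p[0] for p in pairs], dtype=np.int64)
        pj = np.array([p[1] for p in pairs], dtype=np.int64)
    q = np.zeros(n) if charges is None else np.asarray(charges, float)
    return EnergyModel(
        n=n, masses=masses,
        nb_i=pi, nb_j=pj,
        nb_eps=np.full(len(pi), eps), nb_sig=np.full(len(pi), sigma),
        nb_qq=COULOMB_K * q[pi] * q[pj] / 20.0 if len(pi) else np.empty(0),
        debye=8.0,
        b_i=np.empty(0, dtype=np.int64), b_j=np.empty(0, dtype=np.int64),
        b_k=np.empty(0), b_r0=np.empty(0),
        restraint_k=restraint_k,
        native_pos=np.zeros((n, 3)) if native is None else np.asarray(native, float),
        lig_ids=np.arange(n, dtype=np.int64),
        lig_mfrac=masses / masses.sum(),
        ridge_z=np.array([ridge_z, -ridge_z]), ridge_h=np.asarray(ridge_h, float),
        ridge_w=1.5, sphere_r=sphere_r, sphere_k=100.0,
        cyl_r=4.0, cyl_k=cyl_k, cyl_z=7.5, cyl_s=0.5)


class TestPairPotentials:
    def test_lj_minimum_is_minus_epsilon(self):
        sigma, eps = 3.2, 0.7
        r_min = 2.0 ** (1.0 / 6.0) * sigma
        assert lj_energy(r_min, eps, sigma) == pytest.approx(-eps, rel=1e-12)

    def test_screened_coulomb_closed_form(self):
        # unit charges of opposite sign at 4 Å, eps_r = 20, lambda_D = 8 Å
        expected = COULOMB_K * (1.0) * (-1.0) / (20.0 * 4.0) * math.exp(-4.0 / 8.0)
        assert screened_coulomb(4.0, 1.0, -1.0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(-10.5334, abs=1e-3)

    def test_model_reproduces_pair_formulas(self):
        model = make_model(2, pairs=[(0, 1)], charges=[1.0, -1.0], eps=0.7)
        pos = np.array([[0.0, 0.0, 0.0], [4.0, 0.0, 0.0]])
        total, terms = potential_energy(model, pos)
        assert terms["lj"] == pytest.approx(lj_energy(4.0, 0.7, 3.2), rel=1e-10)
        assert terms["coulomb"] == pytest.approx(screened_coulomb(4.0, 1.0, -1.0),
                                                 rel=1e-10)
        assert total == pytest.approx(sum(terms.values()), rel=1e-12)

    def test_coincident_beads_raise_singularity(self):
        model = make_model(2, pairs=[(0, 1)], eps=0.5)
        with pytest.raises(SingularityError):
            potential_energy(model, np.zeros((2, 3)))


class TestForces:
    def test_restraint_zero_at_native(self, human_system, human_model):
        _, terms = potential_energy(human_model, human_system.native_positions)
        assert terms["restraint"] == 0.0

    def test_forces_match_finite_differences(self, human_system, human_model,
                                             rng):
        pos = human_system.native_positions + rng.normal(scale=0.05,
                                                         size=(human_model.n, 3))
        f = forces(human_model, pos)
        h = 1e-5
        for i, d in [(0, 0), (50, 1), (120, 2), (205, 0), (208, 2)]:
            p1, p2 = pos.copy(), pos.copy()
            p1[i, d] += h
            p2[i, d] -= h
            fd = -(potential_energy(human_model, p1)[0]
                   - potential_energy(human_model, p2)[0]) / (2 * h)
            assert f[i, d] == pytest.approx(fd, rel=1e-4, abs=1e-7)

    def test_isolated_bead_feels_no_force(self):
        model = make_model(1)
        assert np.allclose(forces(model, np.array([[1.0, 2.0, 3.0]])), 0.0)

    def test_newtons_third_law_for_unconfined_pairs(self, rng):
        # interacting free beads, no restraints/ridges/walls
        n = 10
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        model = make_model(n, pairs=pairs, eps=0.3,
                           charges=rng.choice([-1.0, 0.0, 1.0], size=n))
        pos = rng.normal(scale=6.0, size=(n, 3))
        assert np.abs(forces(model, pos).sum(axis=0)).max() < 1e-8


class TestLangevinSampling:
    def test_harmonic_well_equipartition(self):
        # single bead, k = 10 kJ/mol/Å², 300 K: var(x) = kB*T/k per coordinate
        model = make_model(1, masses=[50.0], restraint_k=[10.0])
        state = SimState(np.zeros((1, 3)), np.zeros((1, 3)), seed=4)
        frames = langevin_steps(model, state, 2_000_000, 0.01, 1.0, 300.0,
                                record_stride=20)
        var = frames[1000:].reshape(-1, 3).var(axis=0).mean()
        expected = KB * 300.0 / 10.0
        assert expected == pytest.approx(0.24943, abs=1e-4)
        assert var == pytest.approx(expected, rel=0.05)

    def test_boltzmann_moments_in_harmonic_well(self):
        model = make_model(1, masses=[50.0], restraint_k=[10.0])
        state = SimState(np.zeros((1, 3)), np.zeros((1, 3)), seed=9)
        frames = langevin_steps(model, state, 2_000_000, 0.01, 1.0, 300.0,
                                record_stride=20)
        x = frames[1000:].reshape(-1)
        sigma2 = KB * 300.0 / 10.0
        assert x.var() == pytest.approx(sigma2, rel=0.05)
        assert np.mean(x ** 4) == pytest.approx(3 * sigma2 ** 2, rel=0.1)

    def test_doubling_temperature_doubles_variance(self):
        model = make_model(1, masses=[50.0], restraint_k=[10.0])
        var = {}
        for T in (300.0, 600.0):
            state = SimState(np.zeros((1, 3)), np.zeros((1, 3)), seed=13)
            frames = langevin_steps(model, state, 1_000_000, 0.01, 1.0, T,
                                    record_stride=20)
            var[T] = frames[1000:].reshape(-1).var()
        assert var[600.0] / var[300.0] == pytest.approx(2.0, rel=0.07)

    def test_zero_temperature_zero_force_is_stationary(self):
        model = make_model(1)
        pos0 = np.array([[1.0, -2.0, 0.5]])
        state = SimState(pos0.copy(), np.zeros((1, 3)), seed=0)
        langevin_step(model, state, 0.01, 1.0, 0.0)
        assert np.allclose(state.positions, pos0)

    def test_same_seed_reproduces_trajectory(self, human_system, human_model,
                                             human_equil):
        frames = []
        for _ in range(2):
            state = human_equil.state.copy()
            state.seed, state.counter = 77, 0
            frames.append(langevin_steps(human_model, state, 500, 0.01, 0.25,
                                         300.0, record_stride=100))
        assert np.array_equal(frames[0], frames[1])

    def test_energy_conservation_in_verlet_limit(self, human_system,
                                                 human_model, human_equil):
        # friction -> 0, T = 0 reduces BAOAB to velocity Verlet; at dt = 2 fs
        # the total energy drifts by < 1e-3 kJ/mol per ps
        state = human_equil.state.copy()
        energies, times = [], []
        for chunk in range(40):
            e_pot, _ = potential_energy(human_model, state.positions)
            e_kin = 0.5 * float((human_model.masses[:, None]
                                 * state.velocities ** 2).sum())
            energies.append(e_pot + e_kin)
            times.append(chunk * 0.25)
            langevin_steps(human_model, state, 125, 0.002, 0.0, 0.0)
        slope = np.polyfit(times, energies, 1)[0]
        assert abs(slope) < 1e-3


class TestEquilibration:
    def test_ladder_must_be_non_increasing(self, human_system):
        with pytest.raises(ValueError, match="non-increasing"):
            equilibrate(human_system, ladder=[(5.0, 1.0), (20.0, 1.0)])

    def test_ladder_relaxation_and_ligand_retention(self, human_system,
                                                    human_equil):
        stages = human_equil.stages
        assert [k for k, _, _ in stages] == [20.0, 5.0, 2.0, 1.0, 0.5]
        assert stages[-1][2] < stages[0][2]  # ladder restraint energy relaxes
        drift = com_displacement(human_equil.state.positions,
                                 human_system.ligand_bead_ids,
                                 human_system.native_positions,
                                 human_system.masses())
        assert drift < 1.5

    def test_zero_duration_production_returns_single_frame(self, human_system,
                                                           human_equil):
        traj = run_unbiased(human_system, human_equil.state.copy(), duration=0.0)
        assert len(traj) == 1
        assert np.array_equal(traj.frames[0], human_equil.state.positions)


class TestUnbiasedProductions:
    def test_human_ligand_stays_bound(self, human_system, unbiased_campaigns):
        masses = human_system.masses()
        fracs = []
        for traj in unbiased_campaigns["human-like"]:
            drift = np.array([com_displacement(f, human_system.ligand_bead_ids,
                                               human_system.native_positions,
                                               masses)
                              for f in traj.frames])
            fracs.append(np.mean(drift < 3.0))
        assert np.mean(fracs) >= 0.8

    def test_archaeal_ligand_drifts_early(self, arch_system,
                                          unbiased_campaigns):
        masses = arch_system.masses()
        early = 0
        for traj in unbiased_campaigns["archaeal-like"]:
            drift = np.array([com_displacement(f, arch_system.ligand_bead_ids,
                                               arch_system.native_positions,
                                               masses)
                              for f in traj.frames])
            quarter = max(1, len(drift) // 4)
            early += bool((drift[:quarter] > 3.0).any())
        assert early > len(unbiased_campaigns["archaeal-like"]) / 2
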