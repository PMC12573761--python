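import numpy as np
import pytest

from kinmap.toy_dynamics import (IntegrationError, LangevinParams,
                                 boltzmann_density_2d, euler_maruyama_step,
                                 four_well_potential, harvest_ensemble,
                                 sample_long_trajectory)


class TestFourWellPotential:
    @pytest.mark.parametrize("point,expected", [
        ((-1.0, 1.0), -7.2),   # deepest corner
        ((1.0, -1.0), -2.8),
        ((-1.0, -1.0), 2.8),
        ((1.0, 1.0), 7.2),     # shallowest corner
    ])
    def test_corner_energies(self, four_well, point, expected):
        assert four_well.energy(np.array(point)) == pytest.approx(expected)

    def test_gradient_at_origin(self, four_well):
        np.testing.assert_allclose(four_well.gradient(np.zeros(2)), [2.2, 0.0])

    def test_gradient_matches_finite_differences(self, four_well):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-2, 2, size=(50, 2))
        h = 1e-6
        for p in pts:
            num = np.array([
                (four_well.energy(p + h * e) - four_well.energy(p - h * e)) / (2 * h)
                for e in np.eye(2)
            ])
            np.testing.assert_allclose(four_well.gradient(p), num, rtol=1e-5)

    def test_jit_gradient_agrees_with_vectorized(self, four_well):
        if four_well.jit_gradient is None:
            pytest.skip("numba gradient unavailable")
        rng = np.random.default_rng(1)
        out = np.empty(2)
        for p in rng.uniform(-2, 2, size=(20, 2)):
            four_well.jit_gradient(p, out)
            np.testing.assert_allclose(out, four_well.gradient(p), rtol=1e-12)


class TestLangevinParams:
    def test_derived_quantities(self, langevin_params):
        # kT = 8.314e-3 * 300 and D = kT/(m*gamma), both 2.49 kJ/mol resp. nm^2/ps
        assert langevin_params.kT == pytest.approx(2.49, abs=0.005)
        assert langevin_params.diffusion == pytest.approx(2.49, abs=0.005)
        assert langevin_params.beta == pytest.approx(1.0 / langevin_params.kT)

    @pytest.mark.parametrize("field", ["temperature", "mass", "friction", "timestep"])
    def test_rejects_nonpositive(self, field):
        with pytest.raises(ValueError):
            LangevinParams(**{field: 0.0})


class TestEulerMaruyama:
    def test_zero_noise_free_particle_unchanged(self, langevin_params):
        from kinmap.toy_dynamics import PotentialSpec

        free = PotentialSpec(energy=lambda x: np.zeros(x.shape[:-1]),
                             gradient=lambda x: np.zeros_like(x),
                             dimension=2, name="free")
        state = np.array([0.3, -0.7])
        np.testing.assert_array_equal(
            euler_maruyama_step(state, free, langevin_params, np.zeros(2)), state)

    def test_zero_noise_drift_at_origin(self, four_well, langevin_params):
        # at the origin only x feels the 2.2 tilt; beta*D = 1 mol/kJ * kJ/mol
        new = euler_maruyama_step(np.zeros(2), four_well, langevin_params,
                                  np.zeros(2))
        assert new[0] == pytest.approx(-0.0022, rel=1e-6)
        assert new[1] == 0.0

    def test_divergence_guard(self, four_well, langevin_params):
        with pytest.raises(IntegrationError):
            euler_maruyama_step(np.array([1e9, 0.0]), four_well,
                                LangevinParams(timestep=1.0), np.zeros(2))
        with pytest.raises(IntegrationError):
            euler_maruyama_step(np.array([np.nan, 0.0]), four_well,
                                langevin_params, np.zeros(2))

    def test_force_free_msd_matches_closed_form(self, langevin_params):
        """Displacement variance of a free particle after K steps is
        2*D*dt*K (independent Gaussian increments)."""
        from kinmap.toy_dynamics import PotentialSpec

        free = PotentialSpec(energy=lambda x: np.zeros(x.shape[:-1]),
                             gradient=lambda x: np.zeros_like(x),
                             dimension=1, name="free")
        rng = np.random.default_rng(42)
        k_steps = 10
        x = np.zeros((100_000, 1))
        for _ in range(k_steps):
            x = euler_maruyama_step(x, free, langevin_params,
                                    rng.standard_normal(x.shape))
        expected = 2 * langevin_params.diffusion * langevin_params.timestep * k_steps
        assert np.var(x) == pytest.approx(expected, rel=0.02)


class TestLongTrajectory:
    def test_single_step_length(self, four_well, langevin_params):
        traj = sample_long_trajectory(four_well, langevin_params, 1,
                                      np.array([-1.0, 1.0]), seed=0)
        assert len(traj) == 2

    def test_seed_determinism(self, four_well, langevin_params):
        a = sample_long_trajectory(four_well, langevin_params, 5000,
                                   np.array([-1.0, 1.0]), seed=9)
        b = sample_long_trajectory(four_well, langevin_params, 5000,
                                   np.array([-1.0, 1.0]), seed=9)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_small_diffusion_stays_in_basin(self, four_well):
        params = LangevinParams(temperature=1e-6)
        traj = sample_long_trajectory(four_well, params, 20_000,
                                      np.array([-1.0, 1.0]), seed=3)
        assert np.all(traj.positions[:, 0] < 0)
        assert np.all(traj.positions[:, 1] > 0)

    def test_occupancy_ordering_matches_boltzmann(self, medium_trajectory,
                                                  four_well, langevin_params):
        """Quadrant visit frequencies follow the well-depth ordering
        C1 > C4 > C3 > C2, as do the quadrature Boltzmann masses."""
        q = medium_trajectory.positions
        corners = [(-1, 1), (1, -1), (-1, -1), (1, 1)]
        occ = [np.mean((np.sign(q[:, 0]) == sx) & (np.sign(q[:, 1]) == sy))
               for sx, sy in corners]
        assert occ[0] > occ[1] > occ[2] > occ[3]
        _, _, dens = boltzmann_density_2d(four_well, langevin_params, grid=80)
        mids = np.linspace(-2, 2, 81)
        mids = 0.5 * (mids[:-1] + mids[1:])
        xx, yy = np.meshgrid(mids, mids, indexing="ij")
        mass = [dens[(np.sign(xx) == sx) & (np.sign(yy) == sy)].sum()
                for sx, sy in corners]
        assert mass[0] > mass[1] > mass[2] > mass[3]

    def test_histogram_converges_to_boltzmann(self, four_well, langevin_params,
                                              medium_trajectory):
        """Total-variation distance to exp(-beta V)/Z decreases with
        trajectory length (equilibrium consistency)."""
        edges_x, edges_y, dens = boltzmann_density_2d(four_well,
                                                      langevin_params, grid=50)

        def tv(positions):
            h, _, _ = np.histogram2d(positions[:, 0], positions[:, 1],
                                     bins=[edges_x, edges_y])
            h = h / h.sum()
            return 0.5 * np.abs(h - dens).sum()

        q = medium_trajectory.positions
        short, full = tv(q[: len(q) // 20]), tv(q)
        assert full < short
        assert full < 0.12


class TestHarvestEnsemble:
    def test_shapes_at_study_scale(self, medium_trajectory, four_well,
                                   langevin_params):
        ens = harvest_ensemble(medium_trajectory, 2000, 1000, 10, 10,
                               four_well, langevin_params, seed=0)
        assert ens.X0.shape == (2000, 2)
        assert ens.Xtau.shape == (2000, 10, 2)
        assert ens.lag == pytest.approx(10 * langevin_params.timestep)

    def test_zero_lag_identity(self, medium_trajectory, four_well,
                               langevin_params):
        ens = harvest_ensemble(medium_trajectory, 4, 100, 1, 0,
                               four_well, langevin_params, seed=0)
        np.testing.assert_array_equal(ens.Xtau[:, 0, :], ens.X0)

    def test_burst_seed_changes_only_endpoints(self, medium_trajectory,
                                               four_well, langevin_params):
        a = harvest_ensemble(medium_trajectory, 50, 1000, 3, 5,
                             four_well, langevin_params, seed=1)
        b = harvest_ensemble(medium_trajectory, 50, 1000, 3, 5,
                             four_well, langevin_params, seed=2)
        np.testing.assert_array_equal(a.X0, b.X0)
        assert not np.array_equal(a.Xtau, b.Xtau)

    def test_insufficient_trajectory_rejected(self, four_well, langevin_params):
        traj = sample_long_trajectory(four_well, langevin_params, 100,
                                      np.array([-1.0, 1.0]), seed=0)
        with pytest.raises(ValueError, match="too short"):
            harvest_ensemble(traj, 10, 100, 1, 1, four_well,
                             langevin_params, seed=0)

    def test_roundtrip_container(self, small_ensemble, tmp_path):
        path = tmp_path / "ens.npz"
        small_ensemble.save(path)
        loaded = type(small_ensemble).load(path)
        np.testing.assert_array_equal(loaded.X0, small_ensemble.X0)
        np.testing.assert_array_equal(loaded.Xtau, small_ensemble.Xtau)
        assert loaded.lag == small_ensemble.lag
        assert (tmp_path / "ens.csv").exists()
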