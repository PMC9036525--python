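import math

import numpy as np
import pytest
from scipy import stats

import neqswitch as ns
from neqswitch.toy_system import KB, chi_marginal, sample_boltzmann


def random_surface(rng, n_bath=0, coupling=False):
    terms = tuple((rng.uniform(0.5, 6.0), int(rng.integers(1, 4)), rng.uniform(-180, 180))
                  for _ in range(rng.integers(1, 4)))
    bath = tuple(rng.uniform(0.002, 0.05) for _ in range(n_bath))
    coup = tuple(rng.uniform(-0.002, 0.002) for _ in range(n_bath)) if coupling else ()
    return ns.PotentialSurface(dihedral_terms=terms, bath_stiffness=bath,
                               offset=rng.uniform(-2, 2), coupling=coup)


class TestEnergy:
    def test_constant_surface(self):
        s = ns.PotentialSurface(offset=2.5)
        assert ns.energy(s, [0.0]) == 2.5

    def test_cosine_minimum(self):
        s = ns.PotentialSurface(dihedral_terms=((1.0, 1, 0.0),))
        assert ns.energy(s, [180.0]) == pytest.approx(0.0, abs=1e-14)

    def test_matches_independent_formula(self):
        # re-evaluate the analytic form from scratch for random surfaces
        rng = np.random.default_rng(3)
        for _ in range(20):
            s = random_surface(rng, n_bath=2, coupling=True)
            x = np.concatenate([[rng.uniform(-180, 180)], rng.normal(0, 10, 2)])
            expected = s.offset
            for a, n, p in s.dihedral_terms:
                expected += a * (1 + math.cos(math.radians(n * x[0] - p)))
            for i, k in enumerate(s.bath_stiffness):
                expected += 0.5 * k * x[1 + i] ** 2 + s.coupling[i] * x[0] * x[1 + i]
            assert ns.energy(s, x) == pytest.approx(expected, abs=1e-12)

    def test_dimension_mismatch_names_dims(self):
        s = ns.PotentialSurface(bath_stiffness=(0.01,))
        with pytest.raises(ValueError, match="dimensionality 1.*expects 2"):
            ns.energy(s, [0.0])

    def test_periodicity(self):
        rng = np.random.default_rng(4)
        s = random_surface(rng)
        chi = rng.uniform(-180, 180, 50)
        np.testing.assert_allclose(ns.energy(s, chi[:, None]),
                                   ns.energy(s, chi[:, None] + 360.0), rtol=1e-12)


class TestGradient:
    def test_central_difference(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            s = random_surface(rng, n_bath=1, coupling=True)
            x = np.array([rng.uniform(-180, 180), rng.normal(0, 5)])
            g = ns.gradient(s, x)
            h = 1e-5
            for d in range(2):
                xp, xm = x.copy(), x.copy()
                xp[d] += h
                xm[d] -= h
                num = (ns.energy(s, xp) - ns.energy(s, xm)) / (2 * h)
                assert g[d] == pytest.approx(num, rel=1e-6, abs=1e-9)


class TestMixedHamiltonian:
    def test_endpoints(self, default_pair):
        low, high, mixed = default_pair
        x = np.array([33.0])
        assert mixed.energy(x, 0.0) == ns.energy(low, x)
        assert mixed.energy(x, 1.0) == ns.energy(high, x)

    def test_linearity_exact(self, default_pair):
        _, _, mixed = default_pair
        rng = np.random.default_rng(5)
        x = rng.uniform(-180, 180, (40, 1))
        for lam in (0.125, 0.5, 0.625):
            lhs = mixed.energy(x, lam) - mixed.energy(x, 0.0)
            rhs = lam * (mixed.energy(x, 1.0) - mixed.energy(x, 0.0))
            np.testing.assert_array_almost_equal(lhs, rhs, decimal=12)

    def test_lambda_bounds(self, default_pair):
        low, high, _ = default_pair
        with pytest.raises(ValueError, match="lambda"):
            ns.MixedHamiltonian(low, high, lam=1.5)


class TestExactDeltaA:
    def test_identical_surfaces_zero(self, default_pair):
        low, _, _ = default_pair
        assert ns.exact_delta_a(low, low) == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_bath_closed_form(self):
        k0, k1 = 0.004, 0.036
        low = ns.PotentialSurface(bath_stiffness=(k0,))
        high = ns.PotentialSurface(bath_stiffness=(k1,))
        expected = 0.5 * KB * 300.0 * math.log(k1 / k0)
        assert ns.exact_delta_a(low, high, 300.0) == pytest.approx(expected, abs=1e-12)

    def test_double_well_fixture_vs_fine_grid_oracle(self):
        # frozen value from a separate fine-grid trapezoid computation
        # (2e6- and 4e6-point grids agreed to 1e-15)
        low = ns.PotentialSurface(dihedral_terms=((3.0, 1, 0.0),),
                                  bath_stiffness=(0.005,), offset=0.25)
        high = ns.PotentialSurface(dihedral_terms=((2.0, 2, 90.0), (1.5, 1, 30.0)),
                                   bath_stiffness=(0.02,), offset=-0.4)
        assert ns.exact_delta_a(low, high, 300.0) == pytest.approx(
            0.8798995671335742, abs=1e-6)

    def test_antisymmetry(self, default_pair):
        low, high, _ = default_pair
        assert ns.exact_delta_a(low, high) == pytest.approx(
            -ns.exact_delta_a(high, low), abs=1e-10)

    def test_offset_shifts_delta_a(self, default_pair):
        low, high, _ = default_pair
        import dataclasses

        shifted = dataclasses.replace(high, offset=high.offset + 3.0)
        assert ns.exact_delta_a(low, shifted) == pytest.approx(
            ns.exact_delta_a(low, high) + 3.0, abs=1e-9)


class TestLangevin:
    def test_free_particle_uniform_motion(self):
        s = ns.PotentialSurface()          # flat in chi, no bath
        p = ns.LangevinParams(friction=0.0, n_steps=100, seed=1)
        start = ns.Snapshot(np.array([10.0]), np.array([0.5]))
        traj = ns.run_langevin(s, p, start)
        assert traj.final.velocities[0] == pytest.approx(0.5, abs=1e-12)
        assert traj.final.coords[0] == pytest.approx(10.0 + 0.5 * 100, abs=1e-9)

    def test_equipartition_harmonic(self):
        k = 0.02
        s = ns.PotentialSurface(bath_stiffness=(k,))
        p = ns.LangevinParams(friction=50.0, n_steps=20000, seed=8)
        n_rep = 200
        start = ns.Snapshot(np.zeros((n_rep, 2)), np.zeros((n_rep, 2)))
        traj = ns.run_langevin(s, p, start, store_stride=100)
        q = traj.coords[50:, :, 1].ravel()    # discard burn-in
        expected = KB * 300.0 / k
        se = expected * math.sqrt(2.0 / 400)  # conservative: ~400 indep samples
        assert abs(q.var() - expected) < 3 * se

    def test_determinism(self, default_pair):
        low, _, _ = default_pair
        p = ns.LangevinParams(n_steps=500, seed=123)
        start = ns.Snapshot(np.array([170.0]), np.array([0.0]))
        t1 = ns.run_langevin(low, p, start)
        t2 = ns.run_langevin(low, p, start)
        assert np.array_equal(t1.final.coords, t2.final.coords)
        assert np.array_equal(t1.coords, t2.coords)

    def test_energy_overflow_suggests_smaller_timestep(self):
        s = ns.PotentialSurface(bath_stiffness=(10.0,))   # very stiff, dt=1 unstable
        p = ns.LangevinParams(n_steps=2000, seed=1)
        start = ns.Snapshot(np.array([0.0, 5.0]), np.array([0.0, 0.0]))
        with pytest.raises(RuntimeError, match="smaller timestep"):
            ns.run_langevin(s, p, start)

    def test_boltzmann_marginal_chi_squared(self, default_pair):
        """Equilibrium sampling reproduces the quadrature chi marginal."""
        low, _, _ = default_pair
        n_rep, n_samp, lag = 1000, 100, 200
        rng = np.random.default_rng(77)
        coords = sample_boltzmann(low, 300.0, n_rep, rng)
        vels = math.sqrt(KB * 300.0) * rng.standard_normal((n_rep, 1))
        p = ns.LangevinParams(friction=50.0, n_steps=n_samp * lag, seed=78)
        traj = ns.run_langevin(low, p, ns.Snapshot(coords, vels), store_stride=lag)
        samples = ns.wrap_angle(traj.coords[..., 0].ravel())
        edges = np.linspace(100.0, 260.0, 17)     # +/-4 sigma around the minimum
        folded = np.where(samples < -90, samples + 360.0, samples)
        counts, _ = np.histogram(folded, bins=edges)
        grid, pmf = chi_marginal(low, 300.0, n_grid=14400)
        gfold = np.where(grid < -90, grid + 360.0, grid)
        probs = np.array([pmf[(gfold >= a) & (gfold < b)].sum()
                          for a, b in zip(edges[:-1], edges[1:])])
        n = samples.size
        assert n >= 1e5
        expected = probs * n / probs.sum()
        chi2 = ((counts - expected) ** 2 / expected).sum()
        p_value = stats.chi2.sf(chi2, df=len(counts) - 1)
        assert p_value > 0.01


class TestRestartPool:
    def test_snapshot_counts(self, default_pair):
        low, _, _ = default_pair
        pool = ns.build_restart_pool(low, ns.LangevinParams(seed=3), level="low",
                                     run_length=100, save_stride=20)
        assert pool.n_blocks == 8
        assert pool.snapshots_per_block == 5
        assert pool.size == 40

    def test_single_snapshot_per_block(self, default_pair):
        low, _, _ = default_pair
        pool = ns.build_restart_pool(low, ns.LangevinParams(seed=3), level="low",
                                     run_length=1000, save_stride=1000,
                                     start_distribution="uniform")
        assert pool.snapshots_per_block == 1

    @pytest.mark.parametrize("run_length,stride", [(120, 40), (200, 50), (60, 20)])
    def test_count_formula(self, default_pair, run_length, stride):
        low, _, _ = default_pair
        pool = ns.build_restart_pool(low, ns.LangevinParams(seed=5), level="low",
                                     run_length=run_length, save_stride=stride,
                                     start_distribution="uniform")
        assert all(len(b) == run_length // stride for b in pool.blocks)

    def test_divisibility_error(self, default_pair):
        low, _, _ = default_pair
        with pytest.raises(ValueError, match="divisible"):
            ns.build_restart_pool(low, ns.LangevinParams(seed=1), level="low",
                                  run_length=101, save_stride=20)

    def test_determinism(self, default_pair):
        low, _, _ = default_pair
        pools = [ns.build_restart_pool(low, ns.LangevinParams(seed=99), level="low",
                                       run_length=200, save_stride=20)
                 for _ in range(2)]
        for b1, b2 in zip(pools[0].blocks, pools[1].blocks):
            for s1, s2 in zip(b1, b2):
                assert np.array_equal(s1.coords, s2.coords)
                assert np.array_equal(s1.velocities, s2.velocities)


class TestScanSurface:
    def test_constant_all_zero(self):
        df = ns.scan_surface(ns.PotentialSurface(offset=5.0))
        assert np.allclose(df["energy_kcal_mol"], 0.0)

    def test_two_fold_span(self):
        s = ns.PotentialSurface(dihedral_terms=((3.0, 2, 0.0),))
        df = ns.scan_surface(s)
        assert df["energy_kcal_mol"].max() == pytest.approx(6.0, abs=1e-9)
        assert df["energy_kcal_mol"].min() == pytest.approx(0.0, abs=1e-12)

    def test_midpoint_scan_is_mean_of_endpoints(self, default_pair):
        low, high, mixed = default_pair
        grid = np.linspace(-180, 180, 73)
        s_low = ns.scan_surface(mixed.at(0.0), grid, shift_min=False)
        s_high = ns.scan_surface(mixed.at(1.0), grid, shift_min=False)
        s_mid = ns.scan_surface(mixed.at(0.5), grid, shift_min=False)
        np.testing.assert_allclose(
            s_mid["energy_kcal_mol"],
            0.5 * (s_low["energy_kcal_mol"] + s_high["energy_kcal_mol"]), atol=1e-12)
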