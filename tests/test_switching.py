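import dataclasses
import math

import numpy as np
import pytest

import neqswitch as ns
from neqswitch.toy_system import KB, Snapshot, RestartPool, sample_boltzmann


def iid_pool(surface, n_per_block, seed, temperature=300.0):
    """Pool of independent Boltzmann snapshots (no dynamics), for oracles."""
    rng = np.random.default_rng(seed)
    n = 8 * n_per_block
    coords = sample_boltzmann(surface, temperature, n, rng)
    vels = math.sqrt(KB * temperature) * rng.standard_normal(coords.shape)
    blocks = [[Snapshot(coords[b * n_per_block + j], vels[b * n_per_block + j])
               for j in range(n_per_block)] for b in range(8)]
    return RestartPool(blocks=blocks, save_stride=1, level="low")


class TestMakeProtocol:
    # published fixed-budget grid: name, length (fs), replicates, blocksize, t_total (ns)
    @pytest.mark.parametrize("name,n_switch,n_rep,blocksize,stride,t_total", [
        ("NSWI200", 200, 8000, 1000, 10, 1.6),
        ("NSWI500", 500, 3200, 400, 25, 1.6),
        ("NSWI1000", 1000, 1600, 200, 50, 1.6),
        ("NSWI2000", 2000, 800, 100, 100, 1.6),
        ("NSWI2000red", 2000, 200, 25, 400, 0.4),
    ])
    def test_published_grid(self, name, n_switch, n_rep, blocksize, stride, t_total):
        p = ns.make_protocol(name, n_switch, n_rep, 80_000)
        assert p.blocksize == blocksize
        assert p.stride == stride
        assert p.t_total == pytest.approx(t_total, abs=1e-12)

    def test_trivial(self):
        p = ns.make_protocol("X", 1, 8, 8)
        assert (p.blocksize, p.stride) == (1, 1)
        assert p.t_total == pytest.approx(8e-6)

    def test_divisibility_errors(self):
        with pytest.raises(ValueError, match="divisible by 8"):
            ns.make_protocol("X", 10, 12, 120)
        with pytest.raises(ValueError, match="divisible by n_replicate"):
            ns.make_protocol("X", 10, 16, 100)


class TestRunSwitch:
    def test_constant_offset_work_exact(self, default_pair):
        low, _, _ = default_pair
        shifted = dataclasses.replace(low, offset=low.offset + 3.7)
        mixed = ns.MixedHamiltonian(low, shifted)
        start = ns.Snapshot(np.array([160.0]), np.array([0.3]))
        for seed in (1, 2):
            rec = ns.run_switch(mixed, start, 17, "forward",
                                ns.LangevinParams(seed=seed))
            assert rec.work == pytest.approx(3.7, abs=1e-12)

    def test_identity_switch_zero_work(self, default_pair):
        low, _, _ = default_pair
        mixed = ns.MixedHamiltonian(low, low)
        rec = ns.run_switch(mixed, ns.Snapshot(np.array([150.0]), np.array([0.0])),
                            25, "forward", ns.LangevinParams(seed=4))
        assert rec.work == 0.0

    def test_backward_offset_negates(self, default_pair):
        low, _, _ = default_pair
        shifted = dataclasses.replace(low, offset=low.offset + 2.2)
        mixed = ns.MixedHamiltonian(low, shifted)
        rec = ns.run_switch(mixed, ns.Snapshot(np.array([170.0]), np.array([0.0])),
                            13, "backward", ns.LangevinParams(seed=5))
        assert rec.work == pytest.approx(-2.2, abs=1e-12)

    def test_nsteps_validation(self, default_pair):
        _, _, mixed = default_pair
        with pytest.raises(ValueError, match="n_steps"):
            ns.run_switch(mixed, ns.Snapshot(np.array([0.0]), np.array([0.0])),
                          0, "forward", ns.LangevinParams(seed=1))

    def test_quasi_static_harmonic_closed_form(self):
        """Slow switches of a harmonic stiffness recover (kBT/2) ln(k1/k0)."""
        k0, k1 = 0.004, 0.016
        low = ns.PotentialSurface(bath_stiffness=(k0,))
        high = ns.PotentialSurface(bath_stiffness=(k1,))
        mixed = ns.MixedHamiltonian(low, high)
        rng = np.random.default_rng(21)
        n = 300
        coords = np.column_stack([rng.uniform(-180, 180, n),
                                  math.sqrt(KB * 300 / k0) * rng.standard_normal(n)])
        vels = math.sqrt(KB * 300) * rng.standard_normal((n, 2))
        from neqswitch.switching import _batched_switches

        w, _, _ = _batched_switches(mixed, coords, vels, 4000, "forward",
                                    ns.LangevinParams(seed=22),
                                    np.random.default_rng(22))
        closed = 0.5 * KB * 300 * math.log(k1 / k0)
        assert abs(w.mean() - closed) < 3 * w.std() / math.sqrt(n)


class TestRunProtocol:
    def test_small_pool_one_switch_per_snapshot(self, default_pair):
        low, _, mixed = default_pair
        pool = iid_pool(low, 1, seed=1)
        proto = ns.make_protocol("T", 5, 8, 8)
        ws = ns.run_protocol(pool, proto, mixed, "forward", ns.LangevinParams(seed=2))
        assert len(ws) == 8
        assert [r.block for r in ws.records] == list(range(1, 9))
        assert all(r.within_index == 1 for r in ws.records)

    @pytest.mark.parametrize("n_per_block,n_rep", [(4, 16), (6, 24), (8, 16)])
    def test_index_bijection_vs_enumeration(self, default_pair, n_per_block, n_rep):
        low, _, mixed = default_pair
        pool = iid_pool(low, n_per_block, seed=n_rep)
        proto = ns.make_protocol("T", 3, n_rep, pool.size)
        ws = ns.run_protocol(pool, proto, mixed, "forward", ns.LangevinParams(seed=3))
        blocksize = n_rep // 8
        expected = [((b - 1) * blocksize + w, b, w)
                    for b in range(1, 9) for w in range(1, blocksize + 1)]
        got = [(r.global_index, r.block, r.within_index) for r in ws.records]
        assert got == expected
        assert len({g for g, _, _ in got}) == n_rep     # bijection

    def test_stride_mismatch_reports_expected(self, default_pair):
        low, _, mixed = default_pair
        pool = iid_pool(low, 4, seed=6)     # 32 snapshots
        bad = ns.ProtocolSpec(name="B", n_switch=3, n_replicate=16, blocksize=2,
                              stride=3, t_total=1.0)
        with pytest.raises(ValueError, match="expected stride 2"):
            ns.run_protocol(pool, bad, mixed, "forward", ns.LangevinParams(seed=1))

    def test_determinism(self, default_pair):
        low, _, mixed = default_pair
        pool = iid_pool(low, 4, seed=6)
        proto = ns.make_protocol("T", 10, 32, pool.size)
        w1 = ns.run_protocol(pool, proto, mixed, "forward", ns.LangevinParams(seed=9))
        w2 = ns.run_protocol(pool, proto, mixed, "forward", ns.LangevinParams(seed=9))
        assert np.array_equal(w1.works, w2.works)

    def test_offset_invariance(self, default_pair):
        """U_high + c shifts every forward work by +c and backward by -c."""
        low, high, _ = default_pair
        c = 1.9
        shifted = dataclasses.replace(high, offset=high.offset + c)
        pool = iid_pool(low, 4, seed=13)
        proto = ns.make_protocol("T", 12, 32, pool.size)
        for direction, sign in (("forward", +1.0), ("backward", -1.0)):
            w0 = ns.run_protocol(pool, proto, ns.MixedHamiltonian(low, high),
                                 direction, ns.LangevinParams(seed=14)).works
            w1 = ns.run_protocol(pool, proto, ns.MixedHamiltonian(low, shifted),
                                 direction, ns.LangevinParams(seed=14)).works
            np.testing.assert_allclose(w1 - w0, sign * c, atol=1e-10)

    def test_second_law_mean_work(self, default_pair):
        """<W_forward> + 3 SE >= exact Delta A over >= 500 switches."""
        low, high, mixed = default_pair
        pool = iid_pool(low, 80, seed=31)      # 640 snapshots
        proto = ns.make_protocol("T", 25, 640, pool.size)
        ws = ns.run_protocol(pool, proto, mixed, "forward", ns.LangevinParams(seed=32))
        exact = ns.exact_delta_a(low, high)
        assert len(ws) >= 500
        se = ws.works.std(ddof=1) / math.sqrt(len(ws))
        assert ws.works.mean() + 3 * se >= exact


class TestSubsampleReduced:
    def _workset(self, blocksize=100):
        proto = ns.ProtocolSpec(name="N", n_switch=10, n_replicate=8 * blocksize,
                                blocksize=blocksize, stride=1, t_total=1.0)
        recs = [ns.SwitchRecord(work=float(g), direction="forward", block=b,
                                within_index=w, global_index=g, chi_pre=(0.0,),
                                chi_post=(0.0,), seed=0)
                for b in range(1, 9) for w in range(1, blocksize + 1)
                for g in [(b - 1) * blocksize + w]]
        return ns.WorkSet(records=recs, direction="forward", temperature=300.0,
                          protocol=proto)

    def test_quarter_keeps_stride_four(self):
        ws = self._workset(100)
        red = ns.subsample_reduced(ws, 25)
        assert len(red) == 200
        within = sorted({r.within_index for r in red.records})
        assert within == list(range(1, 98, 4))
        # original global indices preserved
        assert red.records[0].global_index == 1

    def test_identity(self):
        ws = self._workset(10)
        red = ns.subsample_reduced(ws, 10)
        assert [r.global_index for r in red.records] == \
            [r.global_index for r in ws.records]

    def test_keep_one_first_of_each_block(self):
        ws = self._workset(10)
        red = ns.subsample_reduced(ws, 1)
        assert [r.within_index for r in red.records] == [1] * 8
        assert len(red) == 8

    def test_non_divisible_error(self):
        with pytest.raises(ValueError, match="not divisible"):
            ns.subsample_reduced(self._workset(10), 3)
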