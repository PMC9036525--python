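import numpy as np
import pytest

import neqswitch as ns


@pytest.fixture(scope="session")
def default_pair():
    low = ns.default_low_surface()
    high = ns.default_high_surface()
    return low, high, ns.MixedHamiltonian(low, high)


@pytest.fixture(scope="session")
def planted_workset(default_pair):
    """Forward work set with four cis-start switches planted in the pool.

    The bulk of the pool sits in the low level's trans basin; four snapshots
    are moved to the high level's cis basin (chi ~ -55 deg), emulating
    under-equilibrated restart files that carry a flipped dihedral.  Short
    (20-step) switches trap those starts in the cis well, producing strongly
    negative work values with chi_post near -55 deg.
    """
    low, high, mixed = default_pair
    pool = ns.build_restart_pool(
        low, ns.LangevinParams(seed=42), level="low", run_length=500,
        save_stride=20, start_distribution="boltzmann")
    rng = np.random.default_rng(9)
    planted = [(2, 5), (4, 3), (6, 20), (7, 11)]
    for b, j in planted:
        pool.blocks[b - 1][j - 1].coords[0] = -55.0 + rng.normal(0, 5)
    proto = ns.make_protocol("P20", 20, 200, pool.size)
    ws = ns.run_protocol(pool, proto, mixed, "forward", ns.LangevinParams(seed=17))
    expected = sorted((b - 1) * 25 + j for b, j in planted)
    return ws, expected
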