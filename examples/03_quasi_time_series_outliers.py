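"""Diagnose work outliers with the quasi-time-series representation.

An under-equilibrated restart pool (uniform random starting dihedrals, no
burn-in) leaves early snapshots of some blocks stranded in unrepresentative
conformations; switches launched from them produce work values far below
Wbar - 3 sigma.  Plotting the works in block-then-save order shows the
outliers clustering at block starts, and removing them shifts the Jarzynski
estimate to more positive values.
"""

import neqswitch as ns

low, high = ns.default_low_surface(), ns.default_high_surface()
mixed = ns.MixedHamiltonian(low, high)

pool = ns.build_restart_pool(low, ns.LangevinParams(seed=3), level="low",
                             run_length=1000, save_stride=20, burn_in=0,
                             start_distribution="uniform")
proto = ns.make_protocol("U50", n_switch=50, n_replicate=400,
                         pool_size=pool.size)
ws = ns.run_protocol(pool, proto, mixed, "forward", ns.LangevinParams(seed=904))

qts = ns.build_quasi_time_series(ws)
print(f"W mean = {qts.mean:+.3f} kcal/mol, sigma = {qts.sigma:.3f}")
print(f"outliers (W < mean - 3 sigma): {list(qts.outlier_indices)}")
blocksize = proto.blocksize
pos = [float((g - 1) % blocksize) / blocksize for g in qts.outlier_indices]
print(f"normalised within-block positions: {[round(p, 2) for p in pos]}")
print("(values near 0 mean the outliers come from snapshots saved early")
print(" in a block -- the signature of insufficient equilibration)")

imp = ns.outlier_impact(ws)
print(f"\nJarzynski with outliers    : {imp.with_outliers.value:+.4f} kcal/mol")
print(f"Jarzynski without outliers : {imp.without_outliers.value:+.4f} kcal/mol")
print("Removing dominant negative works always raises the estimate; a large")
print("shift warns that the raw result hinged on a few suspect switches.")
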